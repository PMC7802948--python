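# diaus

Quantitative diaphragm ultrasound and ex vivo muscle-force analysis for
preclinical muscular-dystrophy studies.

In the *mdx* mouse (the dystrophin-deficient model of Duchenne muscular
dystrophy) the diaphragm is the muscle that most faithfully tracks disease
progression, and ultrasonography offers a non-invasive window onto it:
**diaphragm movement amplitude** (baseline-to-peak excursion on an M-mode
trace, mm) and **echodensity** (mean grayscale intensity of an outlined
B-mode region, a proxy for fibrosis) both change as the muscle degenerates.
`diaus` implements the full quantitative toolchain such a study needs:

- **Echodensity** — grayscale histogram and mean pixel intensity (0–255) of
  a supplied ROI, the per-animal mean over the four frames of an
  acquisition, and group percent differences.
- **Abdominal-wall (AW) attenuation analysis** — the control experiment for
  echodensity. Each frame is normalised to its own maximum, Gaussian-blurred
  and run through Canny edge detection; every pixel column is scanned
  top-down for the shallowest pair of consecutive edge rows separated by
  more than 5 and fewer than 50 pixels (the hyperechoic AW band). Per column
  the analysis records the band thickness *t*, the mean band intensity
  (AW P.I.), and the mean of the 50 pixels beneath it (Below-AW P.I.), pools
  all columns of all frames, and fits

  *ratio* = Below-AW P.I. / AW P.I. against *t* (Pearson *r*, OLS *R²*).

  A near-zero *r* means the superficial band does not shadow the deeper
  tissue, so echodensity differences are not an attenuation artifact.
- **M-mode amplitude** — inspiration detection on a position-vs-time trace
  (peak prominence ≥ 0.2 mm, separation ≥ 0.2 s, light pre-smoothing) and
  per-breath baseline-to-peak amplitude averaged over 3–5 breaths, with
  optional body-weight normalisation (mm/g).
- **Ex vivo physiology** — specific force *sP = P·Lf·D / Mass* (kN/m², with
  muscle density D = 1.06 g/cm³ and fiber length Lf = L₀ for diaphragm
  strips), eccentric force decay at the 5th/10th pulse relative to the 1st,
  post-protocol recovery at 4/30 min, a stretch-stiffness index (mN/mm³),
  and longitudinal percent changes.
- **Statistics** — one-way ANOVA with Bonferroni-corrected pairwise
  comparisons, pooled-variance unpaired t-test, a Fisher variance-ratio
  check of inter-operator agreement, and Pearson correlation with R².
- **Synthetic data** — generators for B-mode-like frames (bright AW band,
  configurable attenuation law, multiplicative speckle), breathing traces
  (half-sine deflections plus noise) and correlated cohort tables, each with
  exact ground truth, so every analysis has a recovery test.

## Worked example

```python
from diaus.experiments import attenuation_image_set, fit_attenuation_strided

frames = attenuation_image_set(slope=-0.008, seed=7)   # synthetic, known truth
print(fit_attenuation_strided(frames).summary())
```

```
Abdominal-wall attenuation analysis
------------------------------------------
columns analysed      496
columns rejected      16
pixels analysed       38669
Pearson r             -0.9927
R-squared              0.98551
OLS slope             -0.008083 ratio/px
OLS intercept          0.5040
```

The frames were generated with a true attenuation slope of −0.008 per pixel
of band thickness; the fitted OLS slope recovers it (−0.0081), and the
strongly negative *r* shows the analysis detects shadowing when it is
genuinely present. On sets generated with slope 0 the same fit returns
|r| ≈ 0.03 on ~500 columns — no spurious attenuation.

```python
from diaus.echodensity import group_percent_difference
group_percent_difference(88.40, 112.82)   # wt vs mdx mean echodensity
# 27.6

from diaus.synthetic import MModeGroundTruth, gen_mmode
from diaus.mmode import extract_amplitude
trace = gen_mmode(MModeGroundTruth(amplitude_mm=0.9, noise_sd_mm=0.05, seed=3),
                  sample_rate=1000.0, duration=3.0)
extract_amplitude(trace).mean_amplitude
# 0.899  (true amplitude 0.9 mm)
```

A `diaus` console command wraps the same functions
(`diaus simulate|echodensity|attenuation|amplitude|physiology|report`); see
`diaus --help`.

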