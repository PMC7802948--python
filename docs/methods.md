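# Methods

This note records the models, conventions and numerical choices behind
`diaus`, and what the synthetic-data experiments do and do not establish.

## Image conventions

Frames are 2-D intensity grids, 0-based and row-major; row 0 is the
shallowest depth. All row/column ranges are half-open. Two intensity scales
exist and are tracked explicitly: the raw 8-bit export scale (0–255), on
which echodensity is defined, and a per-frame normalised scale on which the
attenuation analysis operates. Normalisation divides by the frame's own
maximum (so the brightest pixel becomes exactly 1), not by the theoretical
255; with per-frame normalisation the Below-AW/AW intensity *ratio* is
unaffected by the choice, since numerator and denominator scale together.
RGB(A) inputs are collapsed with BT.709 luminance weights
(0.2126, 0.7152, 0.0722), rounding half away from zero; ultrasound exports
are gray-on-gray, so any constant weighting gives identical values there —
the weight set is a named constant, not a config knob.

## Echodensity

Echodensity is the arithmetic mean of the ROI pixels on the 0–255 scale,
with a 256-bin integer-width histogram. The per-animal value is the
unweighted mean of the per-frame means (frames of one acquisition reuse one
outline, so their ROI sizes differ only slightly; a pixel-weighted mean
would change nothing material and would couple the readout to outline
drift). The nominal outline size is 4514 px; deviations beyond ±2 % are
logged rather than fatal, because hand-drawn outlines vary. Group
differences are percent of the reference-group mean, reported to one
decimal with half-away-from-zero rounding (plain `round()` banker-rounds the
nearest binary float and occasionally differs from the hand-rounded value).

## Abdominal-wall attenuation analysis

Pipeline per frame: normalise → Gaussian blur (σ = 2 px, reflect boundary)
→ Canny (σ = 2 px, hysteresis thresholds 0.1/0.2 on normalised intensity)
→ per-column band detection → per-column metrics; then pool all columns of
all frames and fit ratio on thickness by OLS (R² = r² in this simple linear
case, asserted to 1e−12).

**Band detection.** Each column is scanned top-down; the first pair of
consecutive edge rows whose separation is strictly greater than 5 and
strictly less than 50 px is the AW band. The band is the most superficial
bright layer, so deeper qualifying pairs are ignored. Columns with no
qualifying pair, or without a full below-window beneath the band, are
excluded and counted in the report.

**Thickness convention.** Thickness = bottom edge row − top edge row.
Together with the strict 5/50 bounds this fixes the boundary behaviour
(gaps of exactly 5 or 50 never qualify).

**Partial-volume handling.** Canny localises each boundary to the nearest
pixel row of a sub-pixel transition, so a detected edge row is a mixed
(transition) pixel roughly half the time. Including edge rows in the
intensity windows mixes cross-boundary signal into the means with weight
∝ 1/thickness for the band — a systematic that masquerades as attenuation
(thin bands look darker, biasing r). The default therefore averages the AW
band over the interior rows [top+1, bottom) and starts the 50-px below
window at bottom+1; `exclude_edge_rows=False` restores the inclusive
windows. Either choice moves the means by less than one pixel-row of
signal.

**Validity domain.** Bands thinner than roughly three times the effective
smoothing scale (blur σ combined with the Canny σ, ≈ 2.8 px) suffer edge
merging and sub-band splits from speckle; the synthetic validation
experiments therefore use thicknesses 14–42 px.

**Column independence.** Gaussian smoothing correlates neighbouring
columns, so adjacent columns are not independent observations. The
validation experiments sample every 3rd column — beyond the smoothing
correlation length — so that the column count is an effective sample size,
which the null-experiment bound |r| < 0.1 at n ≈ 500 presupposes. The
production pipeline itself scans every column; the stride is an
experiment-design choice, not a pipeline parameter.

## M-mode amplitude

Inspirations are local maxima of the position trace with prominence
≥ 0.2 mm and separation ≥ 0.2 s (anaesthetised-mouse breathing runs at
roughly 2–4 Hz; both are config keys). Detection runs on a boxcar-smoothed
copy (default 50 ms window) because locating extrema on the raw trace
latches onto noise spikes; amplitudes are then read off the *raw* trace at
the detected indices, which keeps the noise-free case exact and the noisy
case unbiased. The onset of each breath is the minimum of the smoothed
trace between the previous peak and the current one (a per-breath baseline
is robust to slow drift; a global-median baseline is available by config).
When more than five breaths are detected, the five following the first full
cycle are used; fewer than three triggers a warning. Body-weight
normalisation is a plain division (mm/g).

## Ex vivo physiology

Cross-sectional area uses the standard wet-mass estimate
CSA = Mass / (Lf · D) with D = 1.06 g/cm³ and Lf = L₀ × length-to-fiber
ratio (1 for diaphragm strips); specific force is sP = P / CSA with the
N/cm² → kN/m² factor of 10. The compact notation sP = P/(Mass/Lf·D) is
operator-ambiguous; the reading implemented is the only one that yields an
area in the denominator with correct units. Twitch tension is the mean of
five twitches. Eccentric decay at pulse k is 100·(F₁ − F_k)/F₁ for
k ∈ {5, 10}; recovery at 4/30 min is 100·F_t/F_pre. The stiffness index
divides the force change across one imposed stretch by a caller-supplied
reference volume — no published convention pins down that volume, so the
natural default (strip volume = mass/density, in mm³) is provided but not
forced. Longitudinal deltas are computed from group means by default; a
per-animal mode (mean of per-animal percent changes) is available because
the two genuinely differ whenever reference values vary across animals.

## Statistics

Classical fixed-effects one-way ANOVA (between/within mean squares,
(k−1, N−k) df). Pairwise post-hoc tests use the pooled within-group mean
square of the full ANOVA with N−k df (Bonferroni-protected comparisons);
a per-pair-variance variant is available by flag. Bonferroni adjustment is
min(1, p·m) over all m = k(k−1)/2 pairs. The t-test is pooled-variance and
two-sided; Welch is off by default. Inter-operator agreement is a Fisher
variance-ratio F (larger over smaller variance, two-sided p) followed by an
unpaired t on the means; agreement requires both p > α. Degenerate inputs
are handled explicitly: all-identical groups give F = 0, p = 1; a zero
pooled variance with unequal means gives p = 0.

## Synthetic data: what it emulates, what it does not

The B-mode generator produces a dark background, a bright superficial band
of configurable thickness/intensity, and a deeper region whose expected
intensity is `below_base + slope · thickness · band_intensity` (clamped to
[0, 1]), all under multiplicative Gaussian speckle `(1 + cv·z)` clamped to
[0, 1]. Speckle in real ultrasound is Rayleigh-like and spatially
correlated, the attenuation law is not linear in wall thickness, and no
anatomy is rendered — so passing recovery tests establishes that the
*algorithm* measures what it defines, not that real mouse images satisfy
its assumptions. The breathing-trace generator uses half-sine inspiratory
deflections centred in each cycle (the estimator must be shape-agnostic, so
the exact waveform is immaterial; centring gives every breath a baseline
segment on both sides) plus white Gaussian noise. Cohort tables are
multivariate Gaussian with a common pairwise correlation (ρ = 1 handled by
a shared latent draw; equicorrelation matrices with ρ ≤ −1/(k−1) rejected);
no attempt is made to match real animal-level distributions. All generators
are bit-reproducible under a fixed seed, and their zero-noise settings
reproduce ground truth exactly.

## Validation experiment sizes

The standard self-checks (shared by the test suite and
`scripts/acceptance.py`) use: 20 replicate image sets of 8 frames
(≈ 500 strided columns each) for the attenuation null and slope-recovery
experiments; 20 synthetic traces (amplitude 0.9 mm, noise SD 0.05 mm,
1 kHz, 3 s) for amplitude recovery; and 1000 null simulations (4 groups of
10) for the type-I-error calibration of ANOVA and t-test. These sizes give
each check comfortable statistical resolution while keeping a full run in
seconds.

## Known limitations

- The attenuation analysis assumes one dominant superficial bright band;
  multiple stacked hyperechoic layers would be segmented at the shallowest
  qualifying pair only.
- Canny thresholds and blur σ are fixed config values; frames whose
  contrast differs grossly from the defaults' working range need re-tuning,
  and the analysis reports rejected-column counts to make that visible.
- M-mode strip images are not traced automatically; the amplitude module
  consumes a digitised position-vs-time CSV.
- The per-column records within a frame are correlated (smoothing), so the
  pooled Pearson r's nominal p-value would overstate certainty; the package
  reports r and R² and leaves clustered inference to the user.
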