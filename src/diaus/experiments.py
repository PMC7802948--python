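"""Validation experiments on synthetic data with known ground truth.

These are the package's standard self-checks: each experiment generates
inputs from :mod:`diaus.synthetic`, runs the corresponding analysis, and
summarises how well the known truth is recovered.  The same functions back
the test suite and the acceptance script, so the reported numbers always
come from a fresh computation.

Design notes
------------
* The attenuation experiments use band thicknesses 14–42 px.  Bands thinner
  than about three times the effective smoothing scale (blur σ combined with
  Canny σ, ≈ 2.8 px each side) suffer partial-volume distortion of the
  per-column windows and sit outside the analysis' validity domain.
* Columns are sampled with a stride of 3 px.  Gaussian smoothing correlates
  neighbouring columns, so adjacent columns are not independent draws; the
  stride exceeds the smoothing correlation length and makes the column count
  an effective sample size, which is what the |r| bound of the null
  experiment assumes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from diaus.attenuation import AttenuationConfig, AttenuationModel, consolidate
from diaus.mmode import extract_amplitude
from diaus.stats import one_way_anova, unpaired_t
from diaus.synthetic import BModeGroundTruth, MModeGroundTruth, gen_bmode, gen_mmode

#: standard synthetic B-mode conditions for the attenuation experiments
BMODE_AW_TOP_ROW = 15
BMODE_AW_INTENSITY = 0.9
BMODE_BELOW_BASE = 0.45
BMODE_SPECKLE_CV = 0.1
BMODE_THICKNESSES = tuple(range(14, 46, 4))  # 8 levels, 14..42 px
BMODE_FRAME_WIDTH = 189
COLUMN_STRIDE = 3


def attenuation_image_set(
    slope: float, seed: int, width: int = BMODE_FRAME_WIDTH
) -> list:
    """One multi-thickness synthetic frame set for a given attenuation slope."""
    frames = []
    for i, t in enumerate(BMODE_THICKNESSES):
        truth = BModeGroundTruth(
            aw_top_row=BMODE_AW_TOP_ROW,
            aw_thickness=t,
            aw_intensity=BMODE_AW_INTENSITY,
            below_base_intensity=BMODE_BELOW_BASE,
            attenuation_slope=slope,
            speckle_cv=BMODE_SPECKLE_CV,
            seed=seed + i,
        )
        frames.append(gen_bmode(truth, height=BMODE_AW_TOP_ROW + t + 62, width=width))
    return frames


def fit_attenuation_strided(
    frames, config: AttenuationConfig | None = None, stride: int = COLUMN_STRIDE
):
    """Fit the attenuation model on every ``stride``-th column."""
    model = AttenuationModel(frames, config=config)
    records = []
    rejected = 0
    for frame in frames:
        recs, rej = model.segment_frame(frame)
        records.extend(r for r in recs if r.column % stride == 0)
        rejected += rej
    return consolidate(records, model.config, n_rejected=rejected)


def attenuation_slope_recovery(
    slope: float, n_replicates: int = 20, seed: int = 1
) -> dict:
    """Fitted r across replicate synthetic image sets at one true slope.

    Returns the per-replicate Pearson r values plus summary fractions used
    by the null (slope = 0) and recovery (slope < 0) checks.
    """
    rng = np.random.default_rng(seed)
    base_seeds = rng.integers(0, 2**31 - 10**4, size=n_replicates)
    rs = []
    n_cols = []
    for rep in range(n_replicates):
        res = fit_attenuation_strided(
            attenuation_image_set(slope, int(base_seeds[rep]))
        )
        rs.append(res.r)
        n_cols.append(res.n_columns)
    rs = np.asarray(rs)
    return {
        "slope": slope,
        "r_values": rs,
        "mean_n_columns": float(np.mean(n_cols)),
        "frac_abs_r_below_0.1": float(np.mean(np.abs(rs) < 0.1)),
        "frac_r_negative": float(np.mean(rs < 0)),
        "mean_abs_r": float(np.mean(np.abs(rs))),
    }


def amplitude_recovery(
    n_seeds: int = 20,
    amplitude_mm: float = 0.9,
    noise_sd_mm: float = 0.05,
    seed: int = 1,
) -> dict:
    """Mean absolute error of amplitude recovery on synthetic breathing traces."""
    rng = np.random.default_rng(seed)
    trace_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    errors = []
    for s in trace_seeds:
        truth = MModeGroundTruth(
            amplitude_mm=amplitude_mm, noise_sd_mm=noise_sd_mm, seed=int(s)
        )
        trace = gen_mmode(truth, sample_rate=1000.0, duration=3.0)
        res = extract_amplitude(trace)
        errors.append(abs(res.mean_amplitude - amplitude_mm))
    errors = np.asarray(errors)
    return {
        "true_amplitude_mm": amplitude_mm,
        "noise_sd_mm": noise_sd_mm,
        "mae_mm": float(errors.mean()),
        "max_abs_error_mm": float(errors.max()),
        "n_seeds": n_seeds,
    }


def type_i_error(
    n_sims: int = 1000,
    n_groups: int = 4,
    n_per_group: int = 10,
    alpha: float = 0.05,
    seed: int = 1,
) -> dict:
    """Empirical type-I error of the ANOVA and the unpaired t-test.

    Simulates ``n_sims`` null datasets (all groups drawn from the same
    normal distribution) and reports the fraction rejected at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    anova_rej = 0
    t_rej = 0
    for _ in range(n_sims):
        groups = [rng.standard_normal(n_per_group) for _ in range(n_groups)]
        if one_way_anova(groups).p_anova < alpha:
            anova_rej += 1
        _, p = unpaired_t(groups[0], groups[1])
        if p < alpha:
            t_rej += 1
    return {
        "n_sims": n_sims,
        "alpha": alpha,
        "anova_type_i": anova_rej / n_sims,
        "t_type_i": t_rej / n_sims,
    }
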