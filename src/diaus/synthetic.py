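"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`gen_bmode` — B-mode-like frames: a bright superficial band (the
  abdominal wall) over a deeper region whose brightness follows a
  configurable attenuation law, everything under multiplicative speckle;
* :func:`gen_mmode` — breathing traces: baseline plus periodic half-sine
  inspiratory deflections plus Gaussian noise;
* :func:`gen_cohort` — two-genotype × two-timepoint cohort tables with
  configurable group means/SDs and cross-readout correlation.

Every generator is deterministic under a fixed seed, and the zero-noise
settings reproduce their ground truth exactly, so each downstream analysis
has a recovery test against known truth.  No attempt is made at physically
realistic beam simulation: speckle is multiplicative Gaussian, not Rayleigh,
and the attenuation law is linear in band thickness by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from diaus.imaging import Scale, UltrasoundFrame

#: readouts a cohort row carries, with the units used throughout the package
COHORT_READOUTS = (
    "body_weight_g",
    "fmax_kgf",
    "distance_m",
    "amplitude_mm",
    "echodensity_pi",
)


@dataclass(frozen=True)
class BModeGroundTruth:
    """Ground truth of one synthetic B-mode frame.

    The expected below-band intensity is
    ``below_base_intensity + attenuation_slope · aw_thickness · aw_intensity``
    (clamped to [0, 1]); a negative slope makes thicker walls shadow the
    tissue underneath.  ``speckle_cv`` is the coefficient of variation of the
    multiplicative speckle, applied everywhere.
    """

    aw_top_row: int
    aw_thickness: int
    aw_intensity: float
    below_base_intensity: float
    attenuation_slope: float = 0.0
    speckle_cv: float = 0.0
    background_intensity: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aw_thickness < 1:
            raise ValueError("aw_thickness must be >= 1")
        for name in ("aw_intensity", "below_base_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.speckle_cv < 0:
            raise ValueError("speckle_cv must be >= 0")
        if self.aw_top_row < 0:
            raise ValueError("aw_top_row must be >= 0")

    @property
    def expected_below_intensity(self) -> float:
        raw = (self.below_base_intensity
               + self.attenuation_slope * self.aw_thickness * self.aw_intensity)
        return float(np.clip(raw, 0.0, 1.0))


@dataclass(frozen=True)
class MModeGroundTruth:
    """Ground truth of one synthetic breathing trace."""

    baseline_mm: float = 2.0
    amplitude_mm: float = 0.9
    breaths_per_min: float = 150.0
    noise_sd_mm: float = 0.05
    n_breaths: int = 6
    seed: int = 0
    #: fraction of each cycle occupied by the inspiratory deflection
    inspiratory_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0:
            raise ValueError("amplitude_mm must be >= 0")
        if self.n_breaths < 3:
            raise ValueError("n_breaths must be >= 3")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")
        if not 0 < self.inspiratory_fraction < 1:
            raise ValueError("inspiratory_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort cell: sample size plus per-readout mean and SD."""

    n: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must name the same readouts")
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A multi-group cohort design (e.g. wt/mdx × M3/M6).

    ``correlation`` is the common pairwise correlation between readouts
    within an animal; it must keep the equicorrelation matrix positive
    semi-definite (rho > −1/(k−1) for k readouts, or exactly 1).
    """

    groups: dict[str, GroupSpec]
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        if abs(self.correlation) > 1:
            raise ValueError("|correlation| must be <= 1")


def gen_bmode(
    truth: BModeGroundTruth, height: int, width: int,
    min_below_rows: int = 50,
) -> UltrasoundFrame:
    """One synthetic B-mode frame on the normalised 0–1 scale.

    Requires at least ``min_below_rows`` rows below the band (default 50, the
    standard Below-AW window of the attenuation analysis) so the downstream
    per-column metrics fit.
    """
    band_bottom = truth.aw_top_row + truth.aw_thickness
    if height <= band_bottom + min_below_rows:
        raise ValueError(
            f"height {height} leaves < {min_below_rows} rows below the band "
            f"ending at row {band_bottom}"
        )
    img = np.full((height, width), truth.background_intensity, dtype=float)
    img[truth.aw_top_row:band_bottom, :] = truth.aw_intensity
    img[band_bottom:, :] = truth.expected_below_intensity
    if truth.speckle_cv > 0:
        rng = np.random.default_rng(truth.seed)
        img = img * (1.0 + truth.speckle_cv * rng.standard_normal(img.shape))
    img = np.clip(img, 0.0, 1.0)
    return UltrasoundFrame(
        img,
        scale=Scale.NORMALIZED_0_1,
        source_id=f"synthetic_bmode_seed{truth.seed}",
    )


def gen_mmode(
    truth: MModeGroundTruth, sample_rate: float, duration: float
) -> "MModeTrace":
    """A synthetic breathing trace: baseline + half-sine breaths + noise."""
    from diaus.mmode import MModeTrace

    period = 60.0 / truth.breaths_per_min
    if duration < truth.n_breaths * period:
        raise ValueError(
            f"duration {duration}s covers fewer than n_breaths={truth.n_breaths} "
            f"cycles of {period:.3f}s"
        )
    if sample_rate * period < 10:
        raise ValueError("sample_rate resolves < 10 samples per breath")
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    pos = np.full_like(t, truth.baseline_mm)
    insp_len = truth.inspiratory_fraction * period
    # deflection centred in each cycle, so every breath has a baseline
    # segment on both sides (as a breathing trace does)
    start = (period - insp_len) / 2.0
    cycle = np.mod(t, period)
    breath_idx = np.floor(t / period)
    inspiring = (
        (cycle >= start) & (cycle < start + insp_len)
        & (breath_idx < truth.n_breaths)
    )
    pos[inspiring] += truth.amplitude_mm * np.sin(
        np.pi * (cycle[inspiring] - start) / insp_len
    )
    if truth.noise_sd_mm > 0:
        rng = np.random.default_rng(truth.seed)
        pos = pos + truth.noise_sd_mm * rng.standard_normal(pos.shape)
    return MModeTrace(time=t, position=pos, sample_rate=sample_rate)


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """A cohort table: one row per animal, correlated Gaussian readouts.

    Readouts within an animal share the common pairwise correlation of the
    spec; group means and SDs hold in expectation (exactly when SD = 0).
    """
    readouts = list(next(iter(spec.groups.values())).means)
    k = len(readouts)
    rho = spec.correlation
    if rho == 1.0:
        chol = None  # one shared latent draw per animal
    else:
        if k > 1 and rho <= -1.0 / (k - 1):
            raise ValueError(
                f"correlation {rho} makes a {k}x{k} equicorrelation matrix "
                "non-positive-definite"
            )
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(spec.seed)
    rows = []
    animal = 0
    for label, g in spec.groups.items():
        if list(g.means) != readouts:
            raise ValueError("all groups must define the same readouts")
        for _ in range(g.n):
            if chol is None:
                z = np.full(k, rng.standard_normal())
            else:
                z = chol @ rng.standard_normal(k)
            row = {"animal_id": f"a{animal:03d}", "group": label}
            for j, name in enumerate(readouts):
                row[name] = g.means[name] + g.sds[name] * z[j]
            rows.append(row)
            animal += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file writers (frames as 8-bit PNG, tables as CSV, ground truth as JSON)

def write_bmode_png(frame: UltrasoundFrame, path: str | Path) -> None:
    """Write a normalised synthetic frame as 8-bit grayscale PNG."""
    px = frame.pixels
    if frame.scale is Scale.NORMALIZED_0_1:
        px = np.floor(px * 255.0 + 0.5)
    Image.fromarray(px.astype(np.uint8), mode="L").save(Path(path))


def write_ground_truth(truth, path: str | Path) -> None:
    """Ground-truth sidecar as JSON."""
    Path(path).write_text(json.dumps(asdict(truth), indent=2) + "\n")


def write_trace_csv(trace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "position_mm": trace.position}
    ).to_csv(Path(path), index=False)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(Path(path), index=False)
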