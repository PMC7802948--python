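"""Abdominal-wall (AW) attenuation analysis.

The superficial abdominal wall shows up as a hyperechoic band above the
diaphragm in B-mode frames.  If that band attenuated the beam, echo
intensity below it would fall as the band thickens, which would confound
deep-tissue echodensity readings.  The analysis here tests this directly:

1. normalise each frame to its own maximum,
2. Gaussian-blur and run Canny edge detection,
3. for each pixel column, pair the shallowest two consecutive edge rows
   whose separation is strictly above 5 and below 50 pixels (the AW band),
4. record per column the band thickness, the band's mean normalised pixel
   intensity (AW P.I.), and the mean intensity of the 50 pixels immediately
   below (Below-AW P.I.),
5. pool all columns from all frames and correlate the Below-AW/AW intensity
   ratio against band thickness (Pearson r, OLS R²).

A near-zero correlation says the band does not meaningfully attenuate the
deeper signal.  The model/results pair mirrors the usual fit API: build an
:class:`AttenuationModel` from frames, call :meth:`~AttenuationModel.fit`,
inspect the returned :class:`AttenuationResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import feature, filters

from diaus.imaging import Scale, UltrasoundFrame, load_frame, normalize

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttenuationConfig:
    """Tunables of the attenuation analysis.

    All intensity thresholds refer to the normalised 0–1 scale.  The
    thickness bounds are strict (a qualifying band is thicker than
    ``min_thickness`` and thinner than ``max_thickness`` pixels).
    """

    blur_sigma: float = 2.0
    canny_sigma: float = 2.0
    canny_low: float = 0.1
    canny_high: float = 0.2
    min_thickness: int = 5
    max_thickness: int = 50
    below_window: int = 50
    #: if True (default) the detected edge rows themselves are excluded from
    #: both intensity windows: the AW mean averages the interior rows
    #: [top+1, bottom) and the below window starts one row under the bottom
    #: edge, [bottom+1, bottom+1+below_window).  Edge pixels sit on the
    #: boundary transition, so including them mixes cross-boundary signal
    #: into the windows with a weight that depends on band thickness — a
    #: partial-volume artifact that masquerades as attenuation.  If False,
    #: the windows are [top, bottom) and [bottom, bottom+below_window).
    #: Either way the difference is under one pixel-row of signal.
    exclude_edge_rows: bool = True

    def __post_init__(self) -> None:
        if self.blur_sigma <= 0 or self.canny_sigma <= 0:
            raise ValueError("sigmas must be positive")
        if not (0 <= self.canny_low < self.canny_high <= 1):
            raise ValueError("need 0 <= low < high <= 1 for Canny thresholds")
        if not (0 < self.min_thickness < self.max_thickness):
            raise ValueError("need 0 < min_thickness < max_thickness")
        if self.below_window < 1:
            raise ValueError("below_window must be >= 1")


@dataclass(frozen=True)
class ColumnEdgeRecord:
    """One column's AW segmentation: edge pair, thickness, intensities."""

    image_id: str
    column: int
    top_edge_row: int
    bottom_edge_row: int
    aw_thickness: int
    aw_mean_pi: float
    below_aw_pi: float
    ratio: float


def blur(frame: UltrasoundFrame, sigma: float) -> UltrasoundFrame:
    """Gaussian blur with reflect boundary handling (normalised frames)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if frame.scale is not Scale.NORMALIZED_0_1:
        raise ValueError("blur expects a normalised frame")
    smoothed = filters.gaussian(frame.pixels, sigma=sigma, mode="reflect",
                                preserve_range=True)
    from dataclasses import replace
    return replace(frame, pixels=np.clip(smoothed, 0.0, 1.0))


def canny(frame: UltrasoundFrame, sigma: float, low: float, high: float) -> np.ndarray:
    """Canny edge map of a normalised frame.

    Gradient magnitude on the Gaussian-smoothed image, non-maximum
    suppression along the gradient, and double-threshold hysteresis linking
    — the classical contract, delegated to scikit-image.
    """
    if not (0 <= low < high <= 1):
        raise ValueError("need 0 <= low < high <= 1")
    if frame.scale is not Scale.NORMALIZED_0_1:
        raise ValueError("canny expects a normalised frame")
    return feature.canny(frame.pixels, sigma=sigma, low_threshold=low,
                         high_threshold=high)


def detect_aw_band(
    edges: np.ndarray,
    column: int,
    min_thickness: int = 5,
    max_thickness: int = 50,
) -> tuple[int, int] | None:
    """Shallowest qualifying edge pair in one column, or ``None``.

    Scans the column top-down and returns the first pair of *consecutive*
    edge rows whose separation is strictly greater than ``min_thickness``
    and strictly less than ``max_thickness`` pixels.  The AW is the most
    superficial bright layer, so deeper qualifying pairs are ignored.
    """
    if not (0 <= column < edges.shape[1]):
        raise ValueError(f"column {column} outside grid")
    rows = np.flatnonzero(edges[:, column])
    for top, bottom in zip(rows[:-1], rows[1:]):
        gap = int(bottom - top)
        if min_thickness < gap < max_thickness:
            return int(top), int(bottom)
    return None


def column_metrics(
    frame: UltrasoundFrame,
    column: int,
    band: tuple[int, int],
    below_window: int = 50,
    exclude_edge_rows: bool = True,
) -> ColumnEdgeRecord:
    """Thickness and intensity metrics for one column's detected band.

    By default the detected edge rows are excluded from both windows: the AW
    mean averages the interior range ``[top+1, bottom)`` and Below-AW
    averages ``below_window`` rows starting at ``bottom+1`` (edge rows sit
    on the boundary transition; see :class:`AttenuationConfig`).  With
    ``exclude_edge_rows=False`` the windows are ``[top, bottom)`` and
    ``[bottom, bottom+below_window)``.  Thickness is ``bottom − top``
    either way.
    """
    if frame.scale is not Scale.NORMALIZED_0_1:
        raise ValueError("column metrics are defined on the normalised scale")
    top, bottom = band
    if not (0 <= top < bottom):
        raise ValueError("band rows must satisfy 0 <= top < bottom")
    aw_start = top + 1 if exclude_edge_rows else top
    below_start = bottom + 1 if exclude_edge_rows else bottom
    if below_start + below_window > frame.shape[0]:
        raise ValueError(
            f"fewer than {below_window} pixels below band at column {column}"
        )
    col = frame.pixels[:, column]
    if aw_start >= bottom:
        raise ValueError("band too thin for interior averaging")
    aw_mean = float(col[aw_start:bottom].mean())
    below_mean = float(col[below_start:below_start + below_window].mean())
    if aw_mean <= 0:
        raise ValueError("AW mean intensity is zero; ratio undefined")
    return ColumnEdgeRecord(
        image_id=frame.source_id,
        column=int(column),
        top_edge_row=int(top),
        bottom_edge_row=int(bottom),
        aw_thickness=int(bottom - top),
        aw_mean_pi=aw_mean,
        below_aw_pi=below_mean,
        ratio=below_mean / aw_mean,
    )


@dataclass(frozen=True)
class AttenuationResults:
    """Consolidated per-column records plus the ratio-vs-thickness fit."""

    records: pd.DataFrame
    r: float
    r_squared: float
    slope: float
    intercept: float
    n_columns: int
    n_pixels_analyzed: int
    n_columns_rejected: int
    config: AttenuationConfig

    def summary(self) -> str:
        lines = [
            "Abdominal-wall attenuation analysis",
            "-" * 42,
            f"columns analysed      {self.n_columns}",
            f"columns rejected      {self.n_columns_rejected}",
            f"pixels analysed       {self.n_pixels_analyzed}",
            f"Pearson r             {self.r: .4f}",
            f"R-squared             {self.r_squared: .5f}",
            f"OLS slope             {self.slope: .6f} ratio/px",
            f"OLS intercept         {self.intercept: .4f}",
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "n_columns": self.n_columns,
            "n_columns_rejected": self.n_columns_rejected,
            "n_pixels_analyzed": self.n_pixels_analyzed,
            "r": self.r,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "config": asdict(self.config),
        }

    def plot(self, ax=None):
        """Scatter of ratio vs thickness with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.records["aw_thickness"].to_numpy()
        ax.scatter(t, self.records["ratio"], s=4, alpha=0.3, label="columns")
        xs = np.linspace(t.min(), t.max(), 50)
        ax.plot(xs, self.intercept + self.slope * xs, "r-",
                label=f"fit (R²={self.r_squared:.3f})")
        ax.set_xlabel("AW thickness (px)")
        ax.set_ylabel("Below-AW P.I. / AW P.I.")
        ax.legend()
        return ax


def consolidate(
    records: Iterable[ColumnEdgeRecord],
    config: AttenuationConfig | None = None,
    n_rejected: int = 0,
) -> AttenuationResults:
    """Pool per-image records and fit ratio against thickness.

    Pearson r of (thickness, ratio); R² and the line from the ordinary
    least-squares fit of ratio on thickness (identical to r² in this simple
    linear case).
    """
    config = config or AttenuationConfig()
    recs = list(records)
    if len(recs) < 2:
        raise ValueError("need at least 2 column records to correlate")
    df = pd.DataFrame([asdict(r) for r in recs])
    t = df["aw_thickness"].to_numpy(dtype=float)
    ratio = df["ratio"].to_numpy(dtype=float)
    if np.ptp(t) == 0 or np.ptp(ratio) == 0:
        raise ValueError("zero variance in thickness or ratio; r undefined")
    fit = sps.linregress(t, ratio)
    n_pixels = int((df["aw_thickness"] + config.below_window).sum())
    return AttenuationResults(
        records=df,
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_columns=len(df),
        n_pixels_analyzed=n_pixels,
        n_columns_rejected=int(n_rejected),
        config=config,
    )


class AttenuationModel:
    """Per-column AW segmentation over a set of frames.

    Parameters
    ----------
    frames : sequence of UltrasoundFrame
        Raw or already-normalised frames; each is normalised to its own
        maximum before edge detection.
    config : AttenuationConfig, optional

    Examples
    --------
    >>> model = AttenuationModel(frames)          # doctest: +SKIP
    >>> res = model.fit()                         # doctest: +SKIP
    >>> print(res.summary())                      # doctest: +SKIP
    """

    def __init__(
        self,
        frames: Sequence[UltrasoundFrame],
        config: AttenuationConfig | None = None,
    ) -> None:
        if len(frames) == 0:
            raise ValueError("need at least one frame")
        self.frames = list(frames)
        self.config = config or AttenuationConfig()

    @classmethod
    def from_paths(
        cls, paths: Iterable[str | Path], config: AttenuationConfig | None = None
    ) -> "AttenuationModel":
        return cls([load_frame(p) for p in paths], config=config)

    def segment_frame(
        self, frame: UltrasoundFrame
    ) -> tuple[list[ColumnEdgeRecord], int]:
        """Per-column records for one frame plus the rejected-column count."""
        cfg = self.config
        norm = normalize(frame)
        edges = canny(blur(norm, cfg.blur_sigma), cfg.canny_sigma,
                      cfg.canny_low, cfg.canny_high)
        records: list[ColumnEdgeRecord] = []
        rejected = 0
        for col in range(norm.shape[1]):
            band = detect_aw_band(edges, col, cfg.min_thickness, cfg.max_thickness)
            if band is None:
                rejected += 1
                continue
            below_start = band[1] + (1 if cfg.exclude_edge_rows else 0)
            if below_start + cfg.below_window > norm.shape[0]:
                rejected += 1
                continue
            records.append(
                column_metrics(norm, col, band, cfg.below_window,
                               cfg.exclude_edge_rows)
            )
        return records, rejected

    def fit(self) -> AttenuationResults:
        all_records: list[ColumnEdgeRecord] = []
        rejected = 0
        for frame in self.frames:
            recs, rej = self.segment_frame(frame)
            all_records.extend(recs)
            rejected += rej
        if not all_records:
            raise ValueError(
                "no column in any frame produced a qualifying AW band; "
                "check thresholds and frame geometry"
            )
        log.info("attenuation fit: %d columns kept, %d rejected",
                 len(all_records), rejected)
        return consolidate(all_records, self.config, n_rejected=rejected)


def run_attenuation_analysis(
    image_paths: Sequence[str | Path],
    config: AttenuationConfig | None = None,
) -> AttenuationResults:
    """Full pipeline over a list of image files.

    normalise -> blur -> Canny -> per-column band detection/metrics ->
    consolidation and correlation.
    """
    if len(image_paths) == 0:
        raise ValueError("empty image list")
    return AttenuationModel.from_paths(image_paths, config=config).fit()


def moving_average(values: np.ndarray, window: int = 10) -> np.ndarray:
    """Trailing moving average, a diagnostic for column intensity profiles.

    Plays no role in the metrics; mirrors the smoothed per-column trace shown
    alongside the raw profile when inspecting a scan cursor.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    v = np.asarray(values, dtype=float)
    kernel = np.ones(window) / window
    return np.convolve(v, kernel, mode="valid")
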