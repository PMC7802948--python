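"""Diaphragm echodensity: grayscale statistics inside an outlined ROI.

Echodensity (echo intensity) is the mean grayscale value of the pixels in an
outlined diaphragm section of a B-mode frame; higher values flag more
echogenic — typically fibrotic or fatty — tissue.  It is computed on the raw
0–255 export scale, per frame, then averaged over the (nominally four) frames
of one acquisition to give the per-animal value.  Group differences are
expressed as percent of the reference group's mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from diaus.imaging import ROI, Scale, UltrasoundFrame
from diaus._utils import round_half_away

log = logging.getLogger(__name__)

#: nominal outlined-ROI pixel count; acquisitions are expected to reuse the
#: same outline, so large deviations usually mean an ROI drawing mistake.
DEFAULT_TARGET_ROI_PIXELS = 4514
ROI_SIZE_TOLERANCE = 0.02  # fractional deviation that triggers a warning


@dataclass(frozen=True)
class EchodensityResult:
    """Grayscale summary of one frame's ROI.

    ``histogram`` has 256 integer-width bins; ``mean_pi`` is the arithmetic
    mean of the ROI pixel intensities (equivalently the histogram's weighted
    mean when intensities are integers).
    """

    mean_pi: float
    histogram: np.ndarray
    pixel_count: int
    frame_id: str = ""

    def __post_init__(self) -> None:
        if self.histogram.shape != (256,):
            raise ValueError("histogram must have 256 bins")
        if int(self.histogram.sum()) != self.pixel_count:
            raise ValueError("histogram counts must sum to pixel_count")


def roi_echodensity(
    frame: UltrasoundFrame,
    roi: ROI,
    target_pixels: int | None = DEFAULT_TARGET_ROI_PIXELS,
) -> EchodensityResult:
    """Histogram and mean pixel intensity over the ROI of one frame.

    Parameters
    ----------
    frame : UltrasoundFrame
        Raw-scale (0–255) frame.
    roi : ROI
        Mask congruent with the frame.
    target_pixels : int, optional
        Expected outline size; deviations beyond ±2% are logged, not fatal
        (hand-drawn outlines vary slightly). Pass ``None`` to skip the check.
    """
    if frame.scale is not Scale.RAW_0_255:
        raise ValueError("echodensity is defined on the raw 0-255 scale")
    if roi.mask.shape != frame.shape:
        raise ValueError("ROI mask not congruent with frame")
    if target_pixels is not None:
        dev = abs(roi.pixel_count - target_pixels) / target_pixels
        if dev > ROI_SIZE_TOLERANCE:
            log.warning(
                "ROI of %d px deviates %.1f%% from target %d px (frame %s)",
                roi.pixel_count, 100 * dev, target_pixels, frame.source_id,
            )
    values = frame.pixels[roi.mask]
    hist, _ = np.histogram(values, bins=256, range=(-0.5, 255.5))
    return EchodensityResult(
        mean_pi=float(values.mean()),
        histogram=hist,
        pixel_count=roi.pixel_count,
        frame_id=frame.source_id,
    )


def animal_echodensity(results: Sequence[EchodensityResult]) -> float:
    """Per-animal echodensity: unweighted mean of per-frame means.

    Four frames of the same acquisition are expected; fewer or more is
    allowed with a warning.  The mean is unweighted even if ROI sizes differ
    slightly, matching an analysis that averages frame values.
    """
    if len(results) == 0:
        raise ValueError("need at least one frame result")
    if len(results) != 4:
        log.warning("expected 4 frames per acquisition, got %d", len(results))
    return float(np.mean([r.mean_pi for r in results]))


def group_percent_difference(mean_a: float, mean_b: float) -> float:
    """Percent difference of group b relative to reference group a.

    Returns ``100 * (mean_b - mean_a) / mean_a`` rounded to one decimal,
    the precision percent summaries are reported at.
    """
    if mean_a <= 0:
        raise ValueError("reference group mean must be positive")
    return round_half_away(100.0 * (mean_b - mean_a) / mean_a, 1)
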