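"""Frame I/O and preprocessing shared by the B-mode analyses.

An :class:`UltrasoundFrame` is a 2-D intensity grid plus scale metadata.
Coordinates are 0-based and row-major; row 0 is the shallowest depth (top of
the image); all row/column ranges are half-open.  Frames exist on one of two
scales: the raw 8-bit export scale (``raw_0_255``) used for echodensity, and
a per-frame-maximum normalised scale (``normalized_0_1``) used by the
attenuation analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

# BT.709 luminance weights for RGB -> gray collapse.  Ultrasound exports are
# gray-on-gray, so any constant weighting gives identical results there; the
# weight set is kept as a module constant for transparency.
GRAY_WEIGHTS = (0.2126, 0.7152, 0.0722)


class Scale(enum.Enum):
    """Intensity scale a frame is expressed on."""

    RAW_0_255 = "raw_0_255"
    NORMALIZED_0_1 = "normalized_0_1"


@dataclass(frozen=True)
class UltrasoundFrame:
    """A single B-mode (or cropped M-mode strip) frame.

    Parameters
    ----------
    pixels : ndarray, shape (rows, cols)
        Intensity grid. ``float64`` on either scale.
    scale : Scale
        Which range the intensities live on.
    mm_per_pixel : float, optional
        Physical pixel pitch if known.
    source_id : str
        Identifier (usually the file stem) carried through the analyses.
    """

    pixels: np.ndarray
    scale: Scale = Scale.RAW_0_255
    mm_per_pixel: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("frame must be a non-empty 2-D grid")
        object.__setattr__(self, "pixels", px)
        lo, hi = (0.0, 255.0) if self.scale is Scale.RAW_0_255 else (0.0, 1.0)
        if px.min() < lo - 1e-9 or px.max() > hi + 1e-9:
            raise ValueError(
                f"intensities outside declared scale {self.scale.value}: "
                f"range [{px.min():g}, {px.max():g}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROI:
    """Boolean mask congruent with a frame; True marks pixels inside."""

    mask: np.ndarray
    pixel_count: int = field(init=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        n = int(mask.sum())
        if n == 0:
            raise ValueError("ROI is empty")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "pixel_count", n)


def _collapse_to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to one channel with BT.709 weights.

    Rounding is half-away-from-zero to match the usual 8-bit convention.
    """
    if arr.ndim == 2:
        return arr.astype(float)
    rgb = arr[..., :3].astype(float)  # alpha discarded
    lum = rgb @ np.asarray(GRAY_WEIGHTS)
    return np.floor(lum + 0.5)


def load_frame(path: str | Path, mm_per_pixel: float | None = None) -> UltrasoundFrame:
    """Load a PNG/TIFF still as a raw-scale frame.

    RGBA/RGB inputs are collapsed to a single channel; 8-bit grayscale
    round-trips identically.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("I;16", "I"):
                raise ValueError(f"unsupported bit depth ({im.mode}) in {path}")
            if im.mode not in ("L", "RGB", "RGBA"):
                im = im.convert("RGBA")
            arr = np.asarray(im)
    except (OSError, SyntaxError) as exc:
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    gray = _collapse_to_gray(arr)
    return UltrasoundFrame(
        np.clip(gray, 0, 255),
        scale=Scale.RAW_0_255,
        mm_per_pixel=mm_per_pixel,
        source_id=path.stem,
    )


def save_frame(frame: UltrasoundFrame, path: str | Path) -> None:
    """Write a frame as 8-bit grayscale PNG (raw scale required)."""
    if frame.scale is not Scale.RAW_0_255:
        raise ValueError("only raw 0-255 frames are written to PNG")
    Image.fromarray(frame.pixels.astype(np.uint8), mode="L").save(Path(path))


def normalize(frame: UltrasoundFrame) -> UltrasoundFrame:
    """Divide by the frame's own maximum so the maximum becomes 1.

    The per-frame maximum (not the theoretical 255) is used; the choice is
    recorded in the frame's scale metadata. Idempotent.
    """
    if frame.scale is Scale.NORMALIZED_0_1:
        return frame
    peak = frame.pixels.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero frame")
    return replace(frame, pixels=frame.pixels / peak, scale=Scale.NORMALIZED_0_1)


def crop(
    frame: UltrasoundFrame, top: int, bottom: int, left: int, right: int
) -> UltrasoundFrame:
    """Return the half-open sub-grid ``[top:bottom, left:right]``."""
    rows, cols = frame.shape
    if not (0 <= top < bottom <= rows and 0 <= left < right <= cols):
        raise ValueError(
            f"crop bounds [{top}:{bottom}, {left}:{right}] invalid for {rows}x{cols} frame"
        )
    return replace(frame, pixels=frame.pixels[top:bottom, left:right].copy())


def roi_from_png(path: str | Path) -> ROI:
    """Read an ROI mask from a PNG; nonzero pixels are inside."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    return ROI(arr > 0)


def roi_from_polygon(
    vertices: np.ndarray, shape: tuple[int, int]
) -> ROI:
    """Rasterize a polygon given as (row, col) vertices with even-odd fill."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    img = Image.new("1", (shape[1], shape[0]), 0)
    xy = [(c, r) for r, c in verts]  # PIL wants (x, y)
    ImageDraw.Draw(img).polygon(xy, fill=1)
    return ROI(np.asarray(img, dtype=bool))


def roi_from_polygon_csv(path: str | Path, shape: tuple[int, int]) -> ROI:
    """Load polygon vertices from a two-column CSV (row,col) and rasterize."""
    verts = np.loadtxt(Path(path), delimiter=",", skiprows=1, ndmin=2)
    return roi_from_polygon(verts, shape)
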