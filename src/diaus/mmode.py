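"""Diaphragm movement amplitude from an M-mode position trace.

The trace is diaphragm position versus time, oriented so that inspiration is
a positive deflection.  Each breath's amplitude is the baseline-to-peak
distance in mm, where the baseline is (by default) the pre-inspiratory local
minimum of that breath; the per-animal value is the mean over 3–5 breaths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

#: default peak-detection parameters for anaesthetised-mouse breathing
#: (~2-4 Hz): a deflection must rise at least 0.2 mm above its surroundings
#: and peaks must be at least 0.2 s apart.
DEFAULT_MIN_PROMINENCE_MM = 0.2
DEFAULT_MIN_SEPARATION_S = 0.2
#: boxcar window for the detection-only pre-smoothing; locating extrema on a
#: raw noisy trace latches onto noise spikes, a ~50 ms average suppresses
#: that without flattening a breath that lasts >= 100 ms.
DEFAULT_SMOOTH_WINDOW_S = 0.05


@dataclass(frozen=True)
class MModeTrace:
    """Diaphragm position vs time (inspiration positive)."""

    time: np.ndarray
    position: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.position, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("time and position must be equal-length 1-D arrays")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "position", p)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MModeTrace":
        """Load a digitized trace CSV with columns time_s, position_mm."""
        df = pd.read_csv(path, comment="#")
        t = df["time_s"].to_numpy(dtype=float)
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return cls(t, df["position_mm"].to_numpy(dtype=float), rate)


@dataclass(frozen=True)
class AmplitudeResult:
    """Per-breath baseline-to-peak amplitudes and their mean (mm)."""

    per_breath_amplitudes: tuple[float, ...]
    mean_amplitude: float
    n_used: int


def _smooth(position: np.ndarray, sample_rate: float, window_s: float) -> np.ndarray:
    n = max(1, int(round(window_s * sample_rate)))
    if n <= 1:
        return position
    kernel = np.ones(n) / n
    # reflect-pad so the ends are averaged over a full window
    padded = np.pad(position, (n // 2, n - 1 - n // 2), mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def detect_inspirations(
    trace: MModeTrace,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_MM,
    min_separation: float = DEFAULT_MIN_SEPARATION_S,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> list[tuple[int, int]]:
    """Find (onset index, peak index) pairs for each inspiration.

    Peaks are local maxima with at least ``min_prominence`` mm prominence,
    separated by at least ``min_separation`` s; each onset is the last local
    minimum preceding its peak.  Detection runs on a lightly smoothed copy of
    the trace (set ``smooth_window_s=0`` to disable).
    """
    if len(trace.position) < 3:
        raise ValueError("trace too short for peak detection")
    pos = _smooth(trace.position, trace.sample_rate, smooth_window_s)
    distance = max(1, int(round(min_separation * trace.sample_rate)))
    peaks, _ = signal.find_peaks(pos, prominence=min_prominence, distance=distance)
    pairs: list[tuple[int, int]] = []
    prev = 0
    for pk in peaks:
        # pre-inspiratory minimum: lowest point between the previous peak
        # (or trace start) and this peak
        onset = prev + int(np.argmin(pos[prev: pk + 1]))
        pairs.append((int(onset), int(pk)))
        prev = int(pk)
    return pairs


def amplitude(
    trace: MModeTrace,
    pairs: Sequence[tuple[int, int]],
    baseline: Literal["per_breath", "global_median"] = "per_breath",
) -> AmplitudeResult:
    """Baseline-to-peak amplitude per breath, averaged over up to 5 breaths.

    Amplitudes are read off the raw trace at the detected indices (detection
    may have run on a smoothed copy; measurement does not re-smooth).
    ``per_breath`` measures each amplitude from that breath's own
    pre-inspiratory minimum (robust to slow drift); ``global_median`` uses
    the trace median as a common baseline.  When more than five breaths are
    detected, the five following the first full cycle are used; fewer than
    three available breaths triggers a warning.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (onset, peak) pair")
    pos = trace.position
    use = list(pairs[1:6]) if len(pairs) > 5 else list(pairs)
    if len(use) < 3:
        log.warning("only %d breaths available; 3-5 preferred", len(use))
    if baseline == "per_breath":
        amps = [float(pos[pk] - pos[on]) for on, pk in use]
    elif baseline == "global_median":
        base = float(np.median(pos))
        amps = [float(pos[pk] - base) for _, pk in use]
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return AmplitudeResult(
        per_breath_amplitudes=tuple(amps),
        mean_amplitude=float(np.mean(amps)),
        n_used=len(amps),
    )


def extract_amplitude(
    trace: MModeTrace,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_MM,
    min_separation: float = DEFAULT_MIN_SEPARATION_S,
    baseline: Literal["per_breath", "global_median"] = "per_breath",
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> AmplitudeResult:
    """Detect inspirations and measure amplitudes in one call."""
    pairs = detect_inspirations(trace, min_prominence, min_separation,
                                smooth_window_s)
    if not pairs:
        raise ValueError("no inspirations detected")
    return amplitude(trace, pairs, baseline=baseline)


def normalize_amplitude(mean_amplitude: float, body_weight: float) -> float:
    """Body-weight-normalised amplitude, mm/g."""
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    return mean_amplitude / body_weight
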