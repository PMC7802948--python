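"""Ex vivo diaphragm-strip force computations.

Covers the standard normalisation of absolute twitch (Ptw) and tetanic (P0)
force to estimated muscle cross-sectional area (specific force, kN/m²), the
eccentric-contraction force-decay protocol (force at the 5th and 10th pulse
relative to the 1st), post-protocol recovery, a stretch-stiffness index, and
longitudinal percent-change summaries.

Cross-sectional area follows the standard wet-mass estimate

    CSA = Mass / (Lf · D),   Lf = L0 · (length-to-fiber ratio),

with muscle density D = 1.06 g/cm³ and a length-to-fiber ratio of 1 for
diaphragm strips, so sP = P / CSA = P · Lf · D / Mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from diaus._utils import round_half_away

log = logging.getLogger(__name__)

MUSCLE_DENSITY_G_CM3 = 1.06  # skeletal-muscle density
DIAPHRAGM_LENGTH_TO_FIBER_RATIO = 1.0


@dataclass(frozen=True)
class MusclePrep:
    """Geometry of one ex vivo preparation.

    mass in g, optimal length ``l0`` in cm; ``length_to_fiber_ratio`` maps
    L0 to fiber length Lf (1 for diaphragm strips).
    """

    mass: float
    l0: float
    length_to_fiber_ratio: float = DIAPHRAGM_LENGTH_TO_FIBER_RATIO
    density: float = MUSCLE_DENSITY_G_CM3

    def __post_init__(self) -> None:
        for name in ("mass", "l0", "length_to_fiber_ratio", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def fiber_length(self) -> float:
        """Lf = L0 × length-to-fiber ratio, cm."""
        return self.l0 * self.length_to_fiber_ratio


@dataclass(frozen=True)
class ForceSeries:
    """A labelled force recording summary (absolute force, declared units)."""

    label: str  # twitch | tetanus | eccentric_pulse
    absolute_force: float
    frequency: float | None = None
    pulse_index: int | None = None

    def __post_init__(self) -> None:
        if self.absolute_force < 0:
            raise ValueError("force must be non-negative")
        if self.label == "eccentric_pulse" and not (
            self.pulse_index is not None and 1 <= self.pulse_index <= 10
        ):
            raise ValueError("eccentric pulses are indexed 1..10")


def cross_sectional_area(prep: MusclePrep) -> float:
    """Estimated CSA in cm²: mass / (Lf · density)."""
    return prep.mass / (prep.fiber_length * prep.density)


def specific_force(p_absolute: float, csa: float) -> float:
    """Specific force sP in kN/m² from absolute force (N) and CSA (cm²).

    N/cm² = 10 kN/m², hence the factor 10.
    """
    if csa <= 0:
        raise ValueError("CSA must be positive")
    if p_absolute < 0:
        raise ValueError("force must be non-negative")
    return 10.0 * p_absolute / csa


def mean_twitch(forces: Sequence[float]) -> float:
    """Maximal twitch tension: mean of (nominally five) twitches."""
    if len(forces) == 0:
        raise ValueError("need at least one twitch")
    if len(forces) != 5:
        log.warning("expected 5 twitches, got %d", len(forces))
    return float(np.mean(forces))


def eccentric_decay(pulse_forces: Mapping[int, float]) -> tuple[float, float]:
    """Force decay at the 5th and 10th eccentric pulse, percent of pulse 1.

    decay_k = 100 · (F1 − Fk) / F1 for k in {5, 10}.
    """
    for k in (1, 5, 10):
        if k not in pulse_forces:
            raise ValueError(f"missing eccentric pulse {k}")
    f1 = pulse_forces[1]
    if f1 <= 0:
        raise ValueError("force at pulse 1 must be positive")
    return tuple(100.0 * (f1 - pulse_forces[k]) / f1 for k in (5, 10))


def recovery(
    pre_protocol_tetanus: float, at_4min: float, at_30min: float
) -> tuple[float, float]:
    """Post-protocol tetanic force at 4 and 30 min, percent of pre-protocol."""
    if pre_protocol_tetanus <= 0:
        raise ValueError("pre-protocol tetanic force must be positive")
    return (
        100.0 * at_4min / pre_protocol_tetanus,
        100.0 * at_30min / pre_protocol_tetanus,
    )


def stiffness(
    force_after_stretch: float,
    force_before_stretch: float,
    reference_volume: float,
) -> float:
    """Stretch-stiffness index, mN/mm³.

    Force difference across one imposed stretch, normalised to a
    caller-supplied reference volume (mass/density is the natural default
    for a strip; see :func:`muscle_volume_mm3`).
    """
    if reference_volume <= 0:
        raise ValueError("reference volume must be positive")
    return (force_after_stretch - force_before_stretch) / reference_volume


def muscle_volume_mm3(prep: MusclePrep) -> float:
    """Strip volume from wet mass and density, in mm³ (1 cm³ = 1000 mm³)."""
    return 1000.0 * prep.mass / prep.density


def percent_change(value_ref: float, value_new: float) -> float:
    """Percent change of a later value versus a reference, one decimal.

    100 · (new − ref) / ref, used for longitudinal M6-vs-M3 deltas.
    """
    if value_ref == 0:
        raise ValueError("reference value must be nonzero")
    return round_half_away(100.0 * (value_new - value_ref) / value_ref, 1)


def percent_change_per_animal(
    values_ref: Sequence[float], values_new: Sequence[float]
) -> float:
    """Mean of per-animal percent changes (paired animals), one decimal.

    Alternative delta mode: each animal's own percent change is computed
    first, then averaged.  Differs from :func:`percent_change` on group means
    whenever the reference values vary across animals.
    """
    ref = np.asarray(values_ref, dtype=float)
    new = np.asarray(values_new, dtype=float)
    if ref.shape != new.shape or ref.size == 0:
        raise ValueError("paired value arrays required")
    if np.any(ref == 0):
        raise ValueError("reference values must be nonzero")
    return round_half_away(float(np.mean(100.0 * (new - ref) / ref)), 1)
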