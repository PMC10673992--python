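"""Per-phase healing metrics, affected/healthy ratios, and classification.

Three phases of one examination are compared: the *basic* phase is the
contralateral healthy limb, the *target* phase the affected limb with
internal fixation in place, and the *simulated* phase the affected limb
after computational removal of the fixation.  Each phase yields a
median wall thickness (mm), a mean CT value (HU) and their product, the
healing index HI (HU*mm).  The diagnostic ratios are simulated/basic
quotients:

    R2 = median wall thickness ratio
    R4 = mean CT value ratio
    R5 = healing index ratio  (algebraically R2 * R4)

R2 is thresholded at 0.84 (healing attained) and 0.74 (nonunion below);
between the two lies poor healing.  Target-phase metrics are recorded
for completeness but enter no ratio.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "Phase",
    "HealingStatus",
    "Trend",
    "PhaseMetrics",
    "HealingRatios",
    "Cutoffs",
    "compute_phase_metrics",
    "compute_ratios",
    "classify",
    "assess_trend",
    "round2",
]


class Phase(str, enum.Enum):
    BASIC = "basic"
    TARGET = "target"
    SIMULATED = "simulated"


class HealingStatus(str, enum.Enum):
    HEALED = "healed"
    POOR = "poor"
    NONUNION = "nonunion"


class Trend(str, enum.Enum):
    PROGRESSING = "progressing"
    PLATEAU = "plateau"


@dataclass(frozen=True)
class PhaseMetrics:
    """Summary of one reconstruction phase."""

    phase: Phase
    median_wall_thickness: float  # mm
    mean_ct: float  # HU

    def __post_init__(self) -> None:
        if self.median_wall_thickness <= 0:
            raise ValueError("median wall thickness must be > 0")

    @property
    def healing_index(self) -> float:
        """HI = mean CT value * median wall thickness (HU*mm)."""
        return self.mean_ct * self.median_wall_thickness


@dataclass(frozen=True)
class HealingRatios:
    """Simulated-to-basic ratios; r5 == r2 * r4 by construction."""

    r2: float
    r4: float
    r5: float

    def __post_init__(self) -> None:
        if min(self.r2, self.r4, self.r5) <= 0:
            raise ValueError("ratios must be > 0")
        if abs(self.r5 - self.r2 * self.r4) > 1e-12 * abs(self.r5):
            raise ValueError("r5 must equal r2 * r4")


@dataclass(frozen=True)
class Cutoffs:
    """R2 decision thresholds.

    ``heal_threshold``: healing attained at or above this ratio.
    ``nonunion_threshold``: nonunion strictly below this ratio.
    """

    heal_threshold: float = 0.84
    nonunion_threshold: float = 0.74

    def __post_init__(self) -> None:
        if not 0 < self.nonunion_threshold < self.heal_threshold:
            raise ValueError("require 0 < nonunion_threshold < heal_threshold")


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compute_phase_metrics(volume, mask, mesh, phase: Phase) -> PhaseMetrics:
    """Assemble the phase summary from its volume, mask and surface mesh."""
    from .segmentation import mean_ct_value
    from .wall_thickness import compute_wall_thickness, median_thickness

    dist = compute_wall_thickness(mesh)
    return PhaseMetrics(
        phase=Phase(phase),
        median_wall_thickness=median_thickness(dist),
        mean_ct=mean_ct_value(volume, mask),
    )


def compute_ratios(simulated: PhaseMetrics, basic: PhaseMetrics) -> HealingRatios:
    """R2, R4 and R5 as simulated/basic quotients."""
    if basic.median_wall_thickness <= 0 or basic.mean_ct <= 0:
        raise ValueError("basic-phase metrics must be strictly positive")
    r2 = simulated.median_wall_thickness / basic.median_wall_thickness
    r4 = simulated.mean_ct / basic.mean_ct
    r5 = simulated.healing_index / basic.healing_index
    return HealingRatios(r2=r2, r4=r4, r5=r5)


def classify(r2: float, cutoffs: Cutoffs = Cutoffs()) -> HealingStatus:
    """Healing status from the wall-thickness ratio.

    Healing is attained when R2 *reaches* the upper cutoff (>= 0.84);
    nonunion requires R2 strictly below the lower cutoff (< 0.74); the
    band between is poor healing.
    """
    if r2 <= 0:
        raise ValueError("r2 must be > 0")
    if r2 >= cutoffs.heal_threshold:
        return HealingStatus.HEALED
    if r2 < cutoffs.nonunion_threshold:
        return HealingStatus.NONUNION
    return HealingStatus.POOR


#: Minimum R2 slope (per month) regarded as active healing progress.
TREND_SLOPE_PER_MONTH = 0.01


def assess_trend(
    series: list[tuple[float, float]],
    slope_threshold: float = TREND_SLOPE_PER_MONTH,
    cutoffs: Cutoffs = Cutoffs(),
) -> Trend:
    """Judge whether serial R2 measurements show active healing progress.

    Uses the most recent three follow-ups.  Attaining the healing cutoff
    with a net rise over the window counts as progress regardless of
    slope.  Otherwise the recent slope must reach ``slope_threshold``
    per month, taken conservatively as the smaller of the Theil-Sen
    estimate over the three points and the slope of the final interval —
    a late flattening (grafting candidate) is then not masked by one
    earlier jump.
    """
    if len(series) < 3:
        raise ValueError("insufficient follow-up: need at least 3 time points")
    times = np.asarray([t for t, _ in series], dtype=float)
    r2s = np.asarray([r for _, r in series], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("time points must be strictly increasing")
    t3, r3 = times[-3:], r2s[-3:]
    if r3[-1] >= cutoffs.heal_threshold and r3[-1] > r3[0]:
        return Trend.PROGRESSING
    ts_slope = stats.theilslopes(r3, t3).slope
    last_slope = (r3[-1] - r3[-2]) / (t3[-1] - t3[-2])
    if min(ts_slope, last_slope) >= slope_threshold:
        return Trend.PROGRESSING
    return Trend.PLATEAU
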