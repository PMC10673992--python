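"""Per-case and longitudinal orchestration.

One *case* is a pair of CT volumes (healthy and affected limb) examined
at one time point.  Both limbs are segmented under the same HU window —
the comparison is only meaningful under identical threshold conditions —
and three phases are reconstructed: basic (healthy), target (affected,
fixation in place) and simulated (affected, fixation computationally
removed).  Ratios and classification come from simulated/basic; the
target phase is reported but enters no ratio.

Reports are plain JSON-serializable dicts with full parameter
provenance, written with sorted keys so that identical configurations
produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .healing_metrics import (
    Cutoffs,
    Phase,
    PhaseMetrics,
    assess_trend,
    classify,
    compute_ratios,
    round2,
)
from .meshing import extract_surface, remesh_to_edge_length
from .phantom import CTVolume
from .segmentation import (
    DEFAULT_BONE_WINDOW,
    DEFAULT_METAL_HU,
    mean_ct_value,
    remove_hardware,
    threshold_segment,
)
from .wall_thickness import DEFAULT_CAP_MM, compute_wall_thickness, median_thickness

__all__ = ["RunConfig", "run_case", "run_longitudinal", "report_json"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a case run."""

    hu_low: float = DEFAULT_BONE_WINDOW[0]
    hu_high: float = DEFAULT_BONE_WINDOW[1]
    metal_hu: float = DEFAULT_METAL_HU
    remesh_edge: float = 1.0
    thickness_cap: float = DEFAULT_CAP_MM
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError("require hu_low < hu_high")
        if self.remesh_edge <= 0 or self.thickness_cap <= 0:
            raise ValueError("remesh_edge and thickness_cap must be > 0")


def _phase_metrics(volume, mask, config: RunConfig, phase: Phase):
    mesh = extract_surface(mask)
    mesh = remesh_to_edge_length(mesh, config.remesh_edge)
    dist = compute_wall_thickness(mesh, cap=config.thickness_cap)
    metrics = PhaseMetrics(
        phase=phase,
        median_wall_thickness=median_thickness(dist),
        mean_ct=mean_ct_value(volume, mask),
    )
    detail = {
        "phase": phase.value,
        "median_wall_thickness_mm": metrics.median_wall_thickness,
        "mean_ct_hu": metrics.mean_ct,
        "healing_index": metrics.healing_index,
        "n_triangles": int(len(mesh.faces)),
        "n_thickness_samples": int(len(dist)),
        "n_capped_rays": dist.n_capped,
    }
    return metrics, detail


def run_case(
    healthy: CTVolume, affected: CTVolume, config: RunConfig | None = None
) -> dict:
    """Run the full three-phase analysis of one healthy/affected pair."""
    config = config or RunConfig()
    if tuple(healthy.spacing) != tuple(affected.spacing):
        raise ValueError(
            "healthy and affected volumes have different voxel spacing; "
            "they must come from the same calibrated protocol"
        )

    basic_mask = threshold_segment(healthy, config.hu_low, config.hu_high, "healthy")
    target_mask = threshold_segment(affected, config.hu_low, config.hu_high, "affected")
    if basic_mask.hu_window != target_mask.hu_window:
        raise ValueError("phases were segmented under different threshold conditions")
    simulated_mask = remove_hardware(target_mask, affected, config.metal_hu)

    basic, basic_detail = _phase_metrics(healthy, basic_mask, config, Phase.BASIC)
    _, target_detail = _phase_metrics(affected, target_mask, config, Phase.TARGET)
    simulated, sim_detail = _phase_metrics(
        affected, simulated_mask, config, Phase.SIMULATED
    )

    ratios = compute_ratios(simulated, basic)
    status = classify(ratios.r2, config.cutoffs)
    return {
        "phases": {
            "basic": basic_detail,
            "target": target_detail,
            "simulated": sim_detail,
        },
        "ratios": {
            "r2": ratios.r2,
            "r4": ratios.r4,
            "r5": ratios.r5,
            "r2_2dp": round2(ratios.r2),
            "r4_2dp": round2(ratios.r4),
            "r5_2dp": round2(ratios.r5),
        },
        "status": status.value,
        "provenance": {
            "software": "ossiratio",
            "version": __version__,
            "hu_window": [config.hu_low, config.hu_high],
            "metal_hu": config.metal_hu,
            "remesh_edge_mm": config.remesh_edge,
            "thickness_cap_mm": config.thickness_cap,
            "cutoffs": asdict(config.cutoffs),
            "seed": config.seed,
        },
    }


def run_longitudinal(cases: list[tuple[float, dict]], cutoffs: Cutoffs = Cutoffs()) -> dict:
    """Longitudinal trend over case reports ordered by follow-up time.

    ``cases`` is a list of (time in months, case report).  Returns the
    (time, r2, r4, r5) table, the final status, and — when at least
    three time points exist — the trend assessment.
    """
    if not cases:
        raise ValueError("need at least one case report")
    times = np.asarray([t for t, _ in cases], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("case times must be strictly increasing")
    table = [
        {
            "time_months": float(t),
            "r2": rep["ratios"]["r2"],
            "r4": rep["ratios"]["r4"],
            "r5": rep["ratios"]["r5"],
        }
        for t, rep in cases
    ]
    out = {
        "table": table,
        "final_status": cases[-1][1]["status"],
    }
    if len(cases) >= 3:
        series = [(row["time_months"], row["r2"]) for row in table]
        out["trend"] = assess_trend(series, cutoffs=cutoffs).value
    return out


def report_json(report: dict) -> str:
    """Canonical JSON serialization (sorted keys, stable float repr)."""
    return json.dumps(report, sort_keys=True, indent=2)
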