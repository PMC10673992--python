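"""Threshold-based bone segmentation and simulated hardware removal.

The method compares both limbs reconstructed *under the same threshold
conditions*, so the HU window is a required, recorded parameter: the
mask carries the window it was produced with, and the pipeline refuses
to form ratios between masks segmented with different windows.

"Simulated removal of the internal fixation" is implemented as
thresholding out very-high-attenuation voxels (metal) together with a
one-voxel halo, which strips the partial-volume rim that would otherwise
survive as spurious bone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phantom import CTVolume

__all__ = [
    "BoneMask",
    "SegmentationError",
    "threshold_segment",
    "remove_hardware",
    "mean_ct_value",
    "DEFAULT_BONE_WINDOW",
    "DEFAULT_METAL_HU",
]

#: De-facto adult-bone preset of clinical segmentation software (HU).
DEFAULT_BONE_WINDOW = (226.0, 3070.0)
#: Attenuation above which a voxel is treated as implant metal (HU).
DEFAULT_METAL_HU = 2500.0
#: Connected components below this fraction of the foreground are dropped.
MIN_COMPONENT_FRACTION = 0.005

# 26-connectivity structuring element.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    """Raised when segmentation produces no usable bone mask."""


@dataclass(frozen=True)
class BoneMask:
    """Binary bone mask aligned to its source :class:`CTVolume`.

    Carries provenance: the HU window it was segmented with and whether
    hardware has been removed, so the pipeline can enforce that paired
    limbs were processed under identical threshold conditions.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    hu_window: tuple[float, float]
    source_id: str = ""
    hardware_removed: bool = False

    def __post_init__(self) -> None:
        if self.voxels.dtype != bool:
            raise ValueError("mask voxels must be boolean")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.spacing))


def _filter_components(mask: np.ndarray) -> np.ndarray:
    """Keep 26-connected components holding >= 0.5% of the foreground.

    Keeping *all* sufficiently large components (not just the largest)
    matters for nonunion, where the bone splits into two major fragments.
    """
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())[1:]
    total = counts.sum()
    keep = np.flatnonzero(counts >= MIN_COMPONENT_FRACTION * total) + 1
    return np.isin(labels, keep)


def threshold_segment(
    volume: CTVolume,
    hu_low: float = DEFAULT_BONE_WINDOW[0],
    hu_high: float = DEFAULT_BONE_WINDOW[1],
    source_id: str = "",
) -> BoneMask:
    """Segment bone as voxels with hu_low <= HU <= hu_high.

    Small connected components (noise specks) are removed; all
    components with at least 0.5% of the foreground are kept.

    Raises
    ------
    SegmentationError
        If the window selects no voxels (after component filtering).
    """
    if not hu_low < hu_high:
        raise ValueError(f"require hu_low < hu_high, got [{hu_low}, {hu_high}]")
    raw = (volume.voxels >= hu_low) & (volume.voxels <= hu_high)
    filtered = _filter_components(raw)
    if not filtered.any():
        raise SegmentationError(
            f"no bone found in threshold window [{hu_low}, {hu_high}]"
        )
    return BoneMask(
        voxels=filtered,
        spacing=volume.spacing,
        hu_window=(float(hu_low), float(hu_high)),
        source_id=source_id,
    )


def remove_hardware(
    mask: BoneMask, volume: CTVolume, metal_hu: float = DEFAULT_METAL_HU
) -> BoneMask:
    """Remove internal-fixation metal (and its one-voxel halo) from a mask.

    Voxels with HU >= ``metal_hu``, dilated by one voxel, are excluded.
    With no metal present the mask is returned unchanged (idempotent).
    """
    if mask.shape != volume.shape:
        raise ValueError("mask and volume grids are not aligned")
    metal = volume.voxels >= metal_hu
    if not metal.any():
        return replace(mask, hardware_removed=True)
    halo = ndimage.binary_dilation(metal, structure=_STRUCT_26)
    cleaned = mask.voxels & ~halo
    return replace(mask, voxels=cleaned, hardware_removed=True)


def mean_ct_value(volume: CTVolume, mask: BoneMask) -> float:
    """Arithmetic mean HU over the mask voxels."""
    if mask.shape != volume.shape:
        raise ValueError("mask and volume grids are not aligned")
    if not mask.voxels.any():
        raise SegmentationError("cannot compute mean CT value of an empty mask")
    return float(volume.voxels[mask.voxels].mean())
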