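"""Synthetic CT phantoms of a long-bone segment.

Paired healthy/affected volumes of a diaphyseal segment: a dense cortical
shell (hollow cylinder) around low-attenuation marrow, embedded in soft
tissue, with an optional transverse fracture gap partially bridged by
callus and optional internal fixation hardware (intramedullary rod or
lateral plate).  Every geometric quantity of the phantom is known in
closed form, so each downstream stage (segmentation, meshing, wall
thickness, ratios) can be validated against an analytic oracle.

Voxels take the Hounsfield value of the material at their *center*; no
partial-volume averaging is applied.  This keeps noiseless phantoms
exactly piecewise constant and makes voxel-counting oracles exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhantomSpec",
    "CTVolume",
    "generate_limb",
    "analytic_thickness",
    "HU_MIN",
    "HU_MAX",
]

# Calibrated CT attenuation range retained by the volume container.
HU_MIN = -1024.0
HU_MAX = 4096.0

HARDWARE_KINDS = ("none", "rod", "plate")


@dataclass(frozen=True)
class CTVolume:
    """A 3D scalar grid of Hounsfield units with physical spacing.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Attenuation in HU, axis order (x, y, z).
    spacing : tuple of float
        Per-axis voxel edge length in mm.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and attenuation of a synthetic long-bone segment.

    Lengths in mm, attenuation in HU.  ``healing_fraction`` is the
    fraction of the fracture-gap shell cross-section (a contiguous
    angular sector) bridged by callus; the rest of the gap shell is
    replaced by soft tissue.  ``segment_length`` spans the whole grid in
    z, emulating a diaphyseal scan window, so the cortical tube is open
    at the scan boundaries like a clinical segment reconstruction.
    """

    segment_length: float = 50.0
    outer_radius: float = 12.0
    cortical_thickness: float = 4.0
    hu_cortical: float = 1400.0
    hu_callus: float = 700.0
    hu_marrow: float = 100.0
    hu_soft_tissue: float = 40.0
    hu_metal: float = 3200.0
    hu_background: float = -1000.0
    gap_width: float = 0.0
    healing_fraction: float = 1.0
    hardware: str = "none"
    noise_sd: float = 0.0
    voxel_spacing: tuple[float, float, float] = (0.625, 0.625, 0.625)
    grid_shape_xy: tuple[int, int] = (128, 128)
    soft_tissue_radius: float | None = None
    rod_radius: float | None = None
    plate_thickness: float = 4.0
    plate_half_width: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cortical_thickness < self.outer_radius:
            raise ValueError(
                "require 0 < cortical_thickness < outer_radius, got "
                f"{self.cortical_thickness} vs {self.outer_radius}"
            )
        # Callus may equal cortical HU (fully remodeled bridge); all other
        # levels must be strictly ordered.
        if not (
            self.hu_metal > self.hu_cortical >= self.hu_callus
            > self.hu_marrow >= self.hu_soft_tissue
        ):
            raise ValueError(
                "require hu_metal > hu_cortical >= hu_callus > hu_marrow >= hu_soft_tissue"
            )
        if self.gap_width < 0:
            raise ValueError("gap_width must be >= 0")
        if not 0.0 <= self.healing_fraction <= 1.0:
            raise ValueError("healing_fraction must be in [0, 1]")
        if self.hardware not in HARDWARE_KINDS:
            raise ValueError(f"hardware must be one of {HARDWARE_KINDS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing components must be > 0")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be > 0")

    @property
    def inner_radius(self) -> float:
        """Radius of the medullary canal (mm)."""
        return self.outer_radius - self.cortical_thickness

    def effective_soft_tissue_radius(self) -> float:
        """Soft-tissue cuff radius: 12 mm beyond the cortex by default,
        shrunk to fit the transverse field of view when that is small."""
        if self.soft_tissue_radius is not None:
            return self.soft_tissue_radius
        half_fov = min(
            self.grid_shape_xy[0] * self.voxel_spacing[0],
            self.grid_shape_xy[1] * self.voxel_spacing[1],
        ) / 2.0
        return max(min(self.outer_radius + 12.0, 0.95 * half_fov), self.outer_radius)

    def effective_rod_radius(self) -> float:
        if self.rod_radius is not None:
            return self.rod_radius
        return 0.5 * self.inner_radius

    def grid_shape(self) -> tuple[int, int, int]:
        nz = int(round(self.segment_length / self.voxel_spacing[2]))
        return (self.grid_shape_xy[0], self.grid_shape_xy[1], max(nz, 1))


def _material_masks(spec: PhantomSpec, affected: bool):
    """Boolean masks for each material region, on the voxel-center grid."""
    nx, ny, nz = spec.grid_shape()
    sx, sy, sz = spec.voxel_spacing

    # x/y centered on the bone axis; z from 0 to segment_length.
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    z = (np.arange(nz) + 0.5) * sz
    X, Y = np.meshgrid(x, y, indexing="ij")
    r = np.sqrt(X**2 + Y**2)

    half_extent_x = nx * sx / 2.0
    half_extent_y = ny * sy / 2.0
    needed = spec.effective_soft_tissue_radius()
    if affected and spec.hardware == "plate":
        needed = max(needed, spec.outer_radius + spec.plate_thickness)
    for name, half in (("x", half_extent_x), ("y", half_extent_y)):
        if needed > half:
            raise ValueError(
                f"phantom does not fit in the grid along {name}: needs "
                f"{needed:.2f} mm half-extent, grid provides {half:.2f} mm"
            )

    shell2d = (r >= spec.inner_radius) & (r <= spec.outer_radius)
    marrow2d = r < spec.inner_radius
    soft2d = r <= spec.effective_soft_tissue_radius()

    shell = np.repeat(shell2d[:, :, None], nz, axis=2)
    marrow = np.repeat(marrow2d[:, :, None], nz, axis=2)
    soft = np.repeat(soft2d[:, :, None], nz, axis=2)

    gap = np.zeros((nx, ny, nz), dtype=bool)
    callus = np.zeros((nx, ny, nz), dtype=bool)
    metal = np.zeros((nx, ny, nz), dtype=bool)

    if affected and spec.gap_width > 0:
        z_mid = spec.segment_length / 2.0
        in_gap_z = np.abs(z - z_mid) <= spec.gap_width / 2.0
        gap[:, :, in_gap_z] = shell[:, :, in_gap_z]
        # Contiguous angular sector bridged by callus, starting at theta=0.
        theta = np.mod(np.arctan2(Y, X), 2 * np.pi)
        bridged2d = shell2d & (theta <= 2 * np.pi * spec.healing_fraction)
        if spec.healing_fraction >= 1.0:
            bridged2d = shell2d
        callus[:, :, in_gap_z] = np.repeat(
            bridged2d[:, :, None], int(in_gap_z.sum()), axis=2
        )
        callus &= gap

    if affected and spec.hardware == "rod":
        rod2d = r <= spec.effective_rod_radius()
        metal |= np.repeat(rod2d[:, :, None], nz, axis=2)
    elif affected and spec.hardware == "plate":
        plate2d = (
            (X > spec.outer_radius)
            & (X <= spec.outer_radius + spec.plate_thickness)
            & (np.abs(Y) <= spec.plate_half_width)
        )
        metal |= np.repeat(plate2d[:, :, None], nz, axis=2)

    return shell, marrow, soft, gap, callus, metal


def generate_limb(spec: PhantomSpec, affected: bool = False) -> CTVolume:
    """Generate one limb of a phantom pair.

    Parameters
    ----------
    spec : PhantomSpec
        Geometry and attenuation levels.
    affected : bool
        If True, apply the fracture gap, callus bridging and hardware of
        ``spec``; if False those fields are ignored and an intact limb is
        produced.

    Returns
    -------
    CTVolume
        Axis order (x, y, z); the bone axis is z.
    """
    shell, marrow, soft, gap, callus, metal = _material_masks(spec, affected)

    vox = np.full(shell.shape, spec.hu_background, dtype=np.float32)
    vox[soft] = spec.hu_soft_tissue
    vox[marrow] = spec.hu_marrow
    vox[shell] = spec.hu_cortical
    if affected:
        vox[gap] = spec.hu_soft_tissue
        vox[callus] = spec.hu_callus
        vox[metal] = spec.hu_metal

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vox = vox + rng.normal(0.0, spec.noise_sd, vox.shape).astype(np.float32)
    vox = np.clip(vox, HU_MIN, HU_MAX)

    return CTVolume(voxels=vox, spacing=spec.voxel_spacing)


def analytic_thickness(spec: PhantomSpec) -> float:
    """Exact cortical wall thickness of the intact shell (mm).

    The oracle every ray-cast thickness estimate is compared against:
    a hollow circular cylinder has wall thickness R_outer - R_inner
    everywhere on both walls.
    """
    return float(spec.cortical_thickness)


def analytic_shell_volume(spec: PhantomSpec) -> float:
    """Analytic volume of the intact cortical shell, pi*(R^2 - r^2)*L in mm^3."""
    R, r = spec.outer_radius, spec.inner_radius
    return float(np.pi * (R**2 - r**2) * spec.segment_length)


def analytic_rod_volume(spec: PhantomSpec) -> float:
    """Analytic volume of the intramedullary rod in mm^3."""
    return float(np.pi * spec.effective_rod_radius() ** 2 * spec.segment_length)
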