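"""Ray-cast wall-thickness analysis of a triangle surface.

For every triangle a single ray is cast from the centroid along the
inward normal (into the material); the wall thickness at that element
is the distance to the nearest intersection with the surface.  Samples
are weighted by triangle area, which makes the summary statistics
invariant to remeshing density.  Rays that miss (open meshes) or exceed
the distance cap are excluded from the distribution and counted, rather
than clamped, so the median stays finite on non-watertight inputs.

The default cap of 10,000 mm is far beyond any skeletal dimension; it
exists to bound the search, not to censor real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from ._geometry import ray_first_hit

__all__ = [
    "ThicknessDistribution",
    "WallThicknessError",
    "compute_wall_thickness",
    "median_thickness",
    "thickness_histogram",
    "DEFAULT_CAP_MM",
]

DEFAULT_CAP_MM = 10_000.0
#: Rays start this far inside the surface to avoid hitting their own triangle.
ORIGIN_OFFSET_MM = 1e-4
#: Intersections closer than this are discarded as numerical self-hits.
SELF_HIT_EPS_MM = 1e-3


class WallThicknessError(ValueError):
    """Raised when no thickness can be measured."""


@dataclass(frozen=True)
class ThicknessDistribution:
    """Area-weighted wall-thickness samples from one surface.

    Attributes
    ----------
    thickness : ndarray (mm)
        One retained sample per triangle whose ray hit the opposite wall
        within the cap.
    weight : ndarray (mm^2)
        Area of the sample's triangle.
    triangle_index : ndarray
        Index of the source triangle in the analyzed mesh.
    cap : float (mm)
        Maximum accepted thickness.
    n_capped : int
        Rays excluded because they missed or exceeded the cap.
    """

    thickness: np.ndarray
    weight: np.ndarray
    triangle_index: np.ndarray
    cap: float
    n_capped: int

    def __post_init__(self) -> None:
        if np.any(self.thickness <= 0) or np.any(self.thickness > self.cap):
            raise ValueError("thickness samples must lie in (0, cap]")
        if np.any(self.weight <= 0):
            raise ValueError("sample weights must be > 0")

    def __len__(self) -> int:
        return len(self.thickness)

    def total_weight(self) -> float:
        return float(self.weight.sum())


def compute_wall_thickness(
    mesh: trimesh.Trimesh, cap: float = DEFAULT_CAP_MM
) -> ThicknessDistribution:
    """Per-triangle inward-normal ray-cast thickness of a surface.

    Requires outward-oriented normals (out of the material); the ray
    direction is their negation.
    """
    if len(mesh.faces) == 0:
        raise WallThicknessError("mesh has no triangles")
    if cap <= 0:
        raise ValueError("cap must be > 0")
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    centroids = np.asarray(mesh.triangles_center, dtype=np.float64)
    normals = np.asarray(mesh.face_normals, dtype=np.float64)
    areas = np.asarray(mesh.area_faces, dtype=np.float64)

    directions = -normals
    origins = centroids + ORIGIN_OFFSET_MM * directions
    exclude = np.arange(len(faces), dtype=np.int64)
    t = ray_first_hit(vertices, faces, origins, directions, exclude, SELF_HIT_EPS_MM)
    thickness = t + ORIGIN_OFFSET_MM  # distance from the true centroid

    valid = np.isfinite(t) & (thickness <= cap) & (areas > 0)
    n_capped = int(len(faces) - valid.sum())
    return ThicknessDistribution(
        thickness=thickness[valid],
        weight=areas[valid],
        triangle_index=np.flatnonzero(valid),
        cap=float(cap),
        n_capped=n_capped,
    )


def median_thickness(dist: ThicknessDistribution, weighted: bool = True) -> float:
    """Median wall thickness in mm.

    By default the area-weighted median: the smallest sample t such that
    the cumulative area of samples <= t reaches half the total area.
    ``weighted=False`` gives the plain per-triangle median for
    sensitivity analysis against tools whose weighting is unknown.
    """
    if len(dist) == 0:
        raise WallThicknessError("no finite thickness measured")
    order = np.argsort(dist.thickness, kind="stable")
    t = dist.thickness[order]
    if not weighted:
        return float(np.median(t))
    w = dist.weight[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(t[idx])


def thickness_histogram(
    dist: ThicknessDistribution, bin_width: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted histogram of the thickness distribution.

    Returns (bin_edges, weights) over [0, max sample]; the weights sum
    to the total sample area.
    """
    if len(dist) == 0:
        raise WallThicknessError("no finite thickness measured")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    tmax = float(dist.thickness.max())
    n_bins = max(int(np.ceil(tmax / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] < tmax:  # guard against float round-off at the top edge
        edges = np.append(edges, edges[-1] + bin_width)
    weights, edges = np.histogram(dist.thickness, bins=edges, weights=dist.weight)
    return edges, weights


def thickness_table(mesh: trimesh.Trimesh, dist: ThicknessDistribution):
    """Per-triangle results as a DataFrame (index, centroid, thickness, area)."""
    import pandas as pd

    centroids = np.asarray(mesh.triangles_center)[dist.triangle_index]
    return pd.DataFrame(
        {
            "triangle": dist.triangle_index,
            "cx": centroids[:, 0],
            "cy": centroids[:, 1],
            "cz": centroids[:, 2],
            "thickness_mm": dist.thickness,
            "area_mm2": dist.weight,
        }
    )


def color_mesh_by_thickness(
    mesh: trimesh.Trimesh, dist: ThicknessDistribution
) -> trimesh.Trimesh:
    """Color triangles green (thin) to red (thick) for qualitative review."""
    import matplotlib
    from matplotlib import colors

    out = mesh.copy()
    lo, hi = float(dist.thickness.min()), float(dist.thickness.max())
    norm = colors.Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1.0)
    rgba = np.full((len(mesh.faces), 4), [128, 128, 128, 255], dtype=np.uint8)
    mapped = matplotlib.colormaps["RdYlGn_r"](norm(dist.thickness))
    rgba[dist.triangle_index] = (mapped * 255).astype(np.uint8)
    out.visual.face_colors = rgba
    return out
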