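"""Shared fixtures: small phantoms and analytic meshes.

Phantoms here are deliberately smaller than clinical scans; every
geometric quantity is known in closed form so tests compare against
analytic oracles, not snapshots.
"""

import numpy as np
import pytest
import trimesh

from ossiratio.phantom import PhantomSpec, generate_limb


@pytest.fixture(scope="session")
def small_spec():
    """Intact noiseless phantom small enough for fast end-to-end runs."""
    return PhantomSpec(
        segment_length=30.0,
        outer_radius=8.0,
        cortical_thickness=3.0,
        grid_shape_xy=(64, 64),
        voxel_spacing=(0.625, 0.625, 0.625),
    )


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return generate_limb(small_spec, affected=False)


@pytest.fixture(scope="session")
def small_mask(small_spec, small_volume):
    from ossiratio.segmentation import threshold_segment

    return threshold_segment(small_volume)


@pytest.fixture(scope="session")
def small_mesh(small_mask):
    from ossiratio.meshing import extract_surface

    return extract_surface(small_mask)


@pytest.fixture(scope="session")
def slab_mesh():
    """Closed 10 x 10 x 1 mm slab: thickness 1 mm on the two large faces."""
    m = trimesh.creation.box(extents=(10.0, 10.0, 1.0))
    return m.subdivide().subdivide()


@pytest.fixture(scope="session")
def cylinder_shell_mesh():
    """Open-ended hollow cylinder, outer r=10, inner r=7: wall 3 mm."""
    def tube(radius, z0, z1, sections, inward):
        theta = np.linspace(0, 2 * np.pi, sections, endpoint=False)
        zs = np.linspace(z0, z1, 30)
        verts, faces = [], []
        for z in zs:
            for t in theta:
                verts.append([radius * np.cos(t), radius * np.sin(t), z])
        n = sections
        for i in range(len(zs) - 1):
            for j in range(n):
                a = i * n + j
                b = i * n + (j + 1) % n
                c = (i + 1) * n + j
                d = (i + 1) * n + (j + 1) % n
                if inward:
                    faces += [[a, c, b], [b, c, d]]
                else:
                    faces += [[a, b, c], [b, d, c]]
        return np.asarray(verts), np.asarray(faces)

    v1, f1 = tube(10.0, 0.0, 20.0, 96, inward=False)  # outer wall, normals out
    v2, f2 = tube(7.0, 0.0, 20.0, 96, inward=True)  # inner wall, normals toward axis
    mesh = trimesh.Trimesh(
        vertices=np.vstack([v1, v2]), faces=np.vstack([f1, f2 + len(v1)]), process=True
    )
    return mesh


@pytest.fixture(scope="session")
def sphere_shell_mesh():
    """Concentric sphere shell, outer r=10, inner r=8: wall 2 mm."""
    outer = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    inner = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
    inner.invert()  # normals toward the center: out of the shell material
    return trimesh.util.concatenate([outer, inner])
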