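"""Segmentation: threshold windows, hardware removal, mean CT value."""

import numpy as np
import pytest

from ossiratio.phantom import (
    PhantomSpec,
    analytic_rod_volume,
    analytic_shell_volume,
    generate_limb,
)
from ossiratio.segmentation import (
    BoneMask,
    SegmentationError,
    mean_ct_value,
    remove_hardware,
    threshold_segment,
)


@pytest.fixture(scope="module")
def rod_spec():
    return PhantomSpec(hardware="rod", grid_shape_xy=(64, 64), outer_radius=8.0,
                       cortical_thickness=3.0, segment_length=20.0)


@pytest.fixture(scope="module")
def fine_rod_spec():
    """Finer grid keeps voxelization dither of the analytic count below 1%."""
    return PhantomSpec(hardware="rod", grid_shape_xy=(128, 128), outer_radius=8.0,
                       cortical_thickness=3.0, segment_length=20.0,
                       voxel_spacing=(0.3125, 0.3125, 0.3125))


def test_bone_window_selects_exactly_the_cortical_shell(small_volume, small_spec):
    mask = threshold_segment(small_volume, 226.0, 3070.0)
    np.testing.assert_array_equal(
        mask.voxels, small_volume.voxels == small_spec.hu_cortical
    )
    assert mask.hu_window == (226.0, 3070.0)


def test_window_above_all_tissue_raises(small_volume):
    with pytest.raises(SegmentationError, match="no bone found"):
        threshold_segment(small_volume, 3500.0, 4000.0)


def test_rod_phantom_mask_counts_shell_plus_rod(rod_spec, fine_rod_spec):
    vol = generate_limb(rod_spec, affected=True)
    mask = threshold_segment(vol, 226.0, 3070.0)
    # Piecewise-constant phantom: the window holds exactly the cortical
    # voxels; the rod (3200 HU) is above it.
    assert mask.count() == int((vol.voxels == rod_spec.hu_cortical).sum())
    fine = generate_limb(fine_rod_spec, affected=True)
    wide = threshold_segment(fine, 226.0, 3500.0)
    expected = (
        analytic_shell_volume(fine_rod_spec) + analytic_rod_volume(fine_rod_spec)
    ) / fine.voxel_volume()
    assert abs(wide.count() - expected) / expected < 0.01


def test_hardware_removal_recovers_hardware_free_mask(rod_spec):
    vol_rod = generate_limb(rod_spec, affected=True)
    vol_clean = generate_limb(rod_spec, affected=False)
    mask_rod = threshold_segment(vol_rod, 226.0, 3500.0)
    simulated = remove_hardware(mask_rod, vol_rod, metal_hu=2500.0)
    clean = threshold_segment(vol_clean, 226.0, 3500.0)
    np.testing.assert_array_equal(simulated.voxels, clean.voxels)
    assert simulated.hardware_removed


def test_hardware_removal_is_identity_without_metal_and_idempotent(small_volume):
    mask = threshold_segment(small_volume)
    once = remove_hardware(mask, small_volume)
    np.testing.assert_array_equal(once.voxels, mask.voxels)
    twice = remove_hardware(once, small_volume)
    np.testing.assert_array_equal(twice.voxels, once.voxels)


def test_plate_removal_keeps_shell_within_two_percent():
    spec = PhantomSpec(hardware="plate", grid_shape_xy=(80, 80), outer_radius=10.0,
                       cortical_thickness=4.0, segment_length=25.0)
    vol = generate_limb(spec, affected=True)
    mask = threshold_segment(vol, 226.0, 3500.0)
    simulated = remove_hardware(mask, vol, metal_hu=2500.0)
    expected = analytic_shell_volume(spec) / vol.voxel_volume()
    # The one-voxel halo shaves the tangent strip where the plate abuts
    # the cortex, so the count comes in slightly under the analytic shell.
    assert abs(simulated.count() - expected) / expected < 0.02


def test_mean_ct_value_exact_on_noiseless_phantom(small_volume, small_spec, small_mask):
    assert mean_ct_value(small_volume, small_mask) == small_spec.hu_cortical


def test_mean_ct_value_two_level_mix():
    vox = np.full((10, 10, 2), 40.0, dtype=np.float32)
    vox[:5] = 1400.0
    vox[5:] = 700.0
    from ossiratio.phantom import CTVolume

    vol = CTVolume(voxels=vox, spacing=(1.0, 1.0, 1.0))
    mask = BoneMask(voxels=np.ones_like(vox, dtype=bool), spacing=(1.0, 1.0, 1.0),
                    hu_window=(0.0, 4000.0))
    assert mean_ct_value(vol, mask) == pytest.approx(1050.0)


def test_mean_ct_value_noisy_within_clt_bound(small_spec, small_volume):
    # Mean of sd-50 noise over the true cortical mask: 3-sigma CLT bound.
    spec = PhantomSpec(**{**small_spec.__dict__, "noise_sd": 50.0, "seed": 3})
    vol = generate_limb(spec, affected=False)
    mask = threshold_segment(small_volume, 226.0, 3070.0)  # noiseless twin
    n = mask.count()
    assert abs(mean_ct_value(vol, mask) - spec.hu_cortical) < 3 * 50.0 / np.sqrt(n)


def test_mean_ct_value_invariant_under_grid_permutation(small_volume, small_mask):
    from ossiratio.phantom import CTVolume

    rng = np.random.default_rng(0)
    perm = rng.permutation(small_volume.voxels.size)
    vox = small_volume.voxels.ravel()[perm].reshape(small_volume.shape)
    msk = small_mask.voxels.ravel()[perm].reshape(small_mask.shape)
    vol_p = CTVolume(voxels=vox, spacing=small_volume.spacing)
    mask_p = BoneMask(voxels=msk, spacing=small_mask.spacing, hu_window=(226.0, 3070.0))
    assert mean_ct_value(vol_p, mask_p) == pytest.approx(
        mean_ct_value(small_volume, small_mask), rel=1e-12
    )


def test_mean_ct_value_empty_mask_raises(small_volume):
    empty = BoneMask(voxels=np.zeros(small_volume.shape, dtype=bool),
                     spacing=small_volume.spacing, hu_window=(226.0, 3070.0))
    with pytest.raises(SegmentationError):
        mean_ct_value(small_volume, empty)


def test_segmentation_is_deterministic(small_volume):
    a = threshold_segment(small_volume)
    b = threshold_segment(small_volume)
    np.testing.assert_array_equal(a.voxels, b.voxels)


def test_component_filter_drops_specks_keeps_fragments():
    vox = np.full((40, 40, 40), 40.0, dtype=np.float32)
    vox[5:15, 5:15, 5:15] = 1400.0   # fragment 1 (1000 voxels)
    vox[25:35, 25:35, 25:35] = 1400.0  # fragment 2 (1000 voxels)
    vox[20, 2, 2] = 1400.0           # isolated speck
    from ossiratio.phantom import CTVolume

    vol = CTVolume(voxels=vox, spacing=(1.0, 1.0, 1.0))
    mask = threshold_segment(vol, 226.0, 3070.0)
    assert mask.count() == 2000  # both fragments kept, speck dropped
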