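"""Maximal-sphere local thickness, LV-wall restriction and zone partition."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from cardiomorph import (
    classify_thickness,
    local_thickness,
    lv_wall_mask,
    principal_axes,
    thin_wall_volume,
    zone_partition,
)


def _blob(shape, spacing, seed, smooth=3.0, quantile=0.72):
    rng = np.random.default_rng(seed)
    field = ndi.gaussian_filter(rng.normal(size=shape), smooth)
    mask = field > np.quantile(field, quantile)
    # keep largest component only, so the mask is one connected body
    lab, n = ndi.label(mask)
    if n > 1:
        mask = lab == (np.argmax(np.bincount(lab.ravel())[1:]) + 1)
    return mask


def test_slab_reads_its_thickness_at_interior_voxels():
    m = np.zeros((60, 80, 80), bool)
    m[15:45] = True  # 30 voxels x 10 um = 300 um
    th = local_thickness(m, (10, 10, 10))
    interior = np.zeros_like(m)
    interior[15:45, 20:60, 20:60] = True
    assert np.all(np.abs(th[interior] - 300.0) <= 10.0)


def test_solid_sphere_is_its_own_maximal_sphere():
    zz, yy, xx = np.ogrid[:60, :60, :60]
    m = ((zz - 30) ** 2 + (yy - 30) ** 2 + (xx - 30) ** 2) * 100 <= 250**2
    th = local_thickness(m, (10, 10, 10))
    assert np.all(np.abs(th[m] - 500.0) <= 10.0)


def test_wedge_matches_exhaustive_oracle_exactly(thickness_oracle):
    # thickness ramps 100 -> 300 um across the mask
    nz, ny, nx = 40, 32, 32
    m = np.zeros((nz, ny, nx), bool)
    y = np.arange(ny)
    t_vox = np.round((100.0 + 200.0 * y / (ny - 1)) / 10.0).astype(int)
    for j, t in zip(y, t_vox):
        m[2 : 2 + t, j, :] = True
    th = local_thickness(m, (10, 10, 10))
    oracle = thickness_oracle(m, (10, 10, 10))
    assert np.array_equal(th, oracle)


@pytest.mark.parametrize("seed,spacing", [(0, (10, 6, 6)), (1, (8, 8, 8))])
def test_random_blobs_match_oracle_exactly(thickness_oracle, seed, spacing):
    m = _blob((40, 40, 40), spacing, seed)
    th = local_thickness(m, spacing)
    oracle = thickness_oracle(m, spacing)
    assert np.array_equal(th, oracle)


def test_anisotropic_slab_thickness_independent_of_normal_axis():
    # 300 um slab, normal along the coarse (10 um) axis ...
    a = np.zeros((50, 40, 40), bool)
    a[10:40] = True
    th_a = local_thickness(a, (10, 2, 2))
    # ... and along a fine (2 um) axis of the same grid
    b = np.zeros((50, 160, 40), bool)
    b[:, 5:155, :] = True
    th_b = local_thickness(b, (10, 2, 2))
    va = th_a[25, 20, 20]
    vb = th_b[25, 80, 20]
    assert abs(va - vb) <= 10.0  # within one voxel of the coarser spacing


def test_dilation_never_decreases_thickness():
    m = _blob((36, 36, 36), (8, 8, 8), seed=3)
    th1 = local_thickness(m, (8, 8, 8))
    dil = ndi.binary_dilation(m, iterations=2)
    th2 = local_thickness(dil, (8, 8, 8))
    assert np.all(th2[m] >= th1[m] - 1e-9)


def test_empty_mask_gives_zero_map():
    assert not local_thickness(np.zeros((8, 8, 8), bool), (1, 1, 1)).any()


class TestLVWallMask:
    def test_septum_sector_excluded(self, infarct_heart):
        spec, bundle, _ = infarct_heart
        frame = principal_axes(bundle.truth_chamber, spec.voxel_spacing_um)
        wall = lv_wall_mask(
            bundle.truth_tissue,
            bundle.truth_chamber,
            spec.voxel_spacing_um,
            frame=frame,
            septal_direction=(0.0, -1.0, 0.0),
            exclude_half_angle_deg=65.0,
        )
        septum = bundle.truth_septum
        assert septum is not None and septum.any()
        assert (wall & septum).sum() / septum.sum() <= 0.01

    def test_full_sector_equals_tissue_within_distance(self, infarct_heart):
        spec, bundle, _ = infarct_heart
        wall = lv_wall_mask(
            bundle.truth_tissue,
            bundle.truth_chamber,
            spec.voxel_spacing_um,
            max_distance_um=1e9,
        )
        assert np.array_equal(wall, bundle.truth_tissue)

    def test_user_mask_passes_through_unchanged(self, infarct_heart):
        spec, bundle, _ = infarct_heart
        user = bundle.truth_lv_wall
        wall = lv_wall_mask(
            bundle.truth_tissue, bundle.truth_chamber, spec.voxel_spacing_um,
            user_mask=user,
        )
        assert np.array_equal(wall, user)
        assert wall is not user  # defensive copy


class TestThinWallVolume:
    def test_uniform_600um_wall_has_no_thin_volume(self):
        m = np.zeros((80, 60, 60), bool)
        m[10:70] = True  # 600 um at 10 um spacing
        th = local_thickness(m, (10, 10, 10))
        assert thin_wall_volume(th, m, (10, 10, 10), 400.0) == 0.0

    def test_uniform_300um_wall_counts_every_voxel(self):
        m = np.zeros((50, 40, 40), bool)
        m[10:40] = True
        th = local_thickness(m, (10, 10, 10))
        expected = m.sum() * 1000.0 / 1e9
        assert thin_wall_volume(th, m, (10, 10, 10), 400.0) == pytest.approx(expected)

    def test_infarct_sector_volume_recovered_within_5pct(self, infarct_heart):
        spec, bundle, thick = infarct_heart
        wall = bundle.truth_lv_wall
        designed = (
            (bundle.truth_thickness > 0) & (bundle.truth_thickness < 400.0) & wall
        ).sum() * np.prod(spec.voxel_spacing_um) / 1e9
        measured = thin_wall_volume(thick, wall, spec.voxel_spacing_um, 400.0)
        assert measured == pytest.approx(designed, rel=0.05)


class TestZonePartition:
    def test_three_slab_phantom_zone_volumes_within_5pct(self):
        # three adjacent wall bands of 250 / 400 / 600 um sharing a base
        # plane (the wall-patch geometry); bands are wide relative to the
        # step boundaries between them
        from cardiomorph import WallBand, WallPatchSpec, generate_wall_patch

        spec = WallPatchSpec(
            bands=[WallBand(250.0, 800.0), WallBand(400.0, 800.0), WallBand(600.0, 800.0)],
            voxel_spacing_um=(10.0, 10.0, 10.0),
            depth_um=800.0,
            margin_um=50.0,
            seed=0,
        )
        b = generate_wall_patch(spec)
        th = local_thickness(b.truth_tissue, spec.voxel_spacing_um)
        zones = zone_partition(th, b.truth_tissue)
        voxvol = np.prod(spec.voxel_spacing_um) / 1e9
        for label in (1, 2, 3):
            designed = (b.truth_zones == label).sum() * voxvol
            measured = (zones == label).sum() * voxvol
            assert measured == pytest.approx(designed, rel=0.05)

    def test_zone_volumes_partition_the_wall_exactly(self, infarct_heart):
        spec, bundle, thick = infarct_heart
        zones = zone_partition(thick, bundle.truth_lv_wall)
        assert (zones > 0).sum() == bundle.truth_lv_wall.sum()
        assert not (zones > 0)[~bundle.truth_lv_wall].any()

    def test_boundary_thickness_assigned_to_border_zone(self):
        t = np.array([299.999, 300.0, 400.0, 500.0, 500.001])
        labels = classify_thickness(t)
        assert labels.tolist() == [1, 2, 2, 2, 3]
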