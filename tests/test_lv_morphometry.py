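"""Chamber morphometry: axes, silhouette, conicity, apex volume, curvature."""

import numpy as np
import pytest
import trimesh

from cardiomorph import (
    PhantomSpec,
    apex_volume_mm3,
    apical_curvature_histogram,
    chamber_mesh,
    chamber_volume_mm3,
    conicity_index,
    generate_chamber_solid,
    mean_curvature,
    principal_axes,
    project_silhouette,
)
from cardiomorph.lv_morphometry import Projection2D, _vertex_areas
from cardiomorph.phantom import rotation_matrix


def _ellipsoid_mask(semi_um, spacing=40.0, rot=(0.0, 0.0, 0.0)):
    margin = 4 * spacing
    half = max(semi_um) + margin if any(rot) else None
    shape = tuple(
        int(np.ceil(2 * ((half or (s + margin))) / spacing)) for s in semi_um
    )
    spec = PhantomSpec(
        grid_shape=shape,
        voxel_spacing_um=(spacing,) * 3,
        chamber_shape="prolate_ellipsoid",
        chamber_semi_axes_um=semi_um,
        rotation_deg=rot,
    )
    return generate_chamber_solid(spec), (spacing,) * 3


def _sphere_mask(r_um, spacing=40.0):
    n = int(np.ceil(2 * (r_um + 4 * spacing) / spacing))
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    m = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * spacing**2 <= r_um**2
    return m, (spacing,) * 3


class TestPrincipalAxes:
    def test_axis_aligned_ellipsoid_long_axis_within_1_degree(self):
        mask, sp = _ellipsoid_mask((3000.0, 1500.0, 1200.0))
        frame = principal_axes(mask, sp)
        ang = np.degrees(np.arccos(abs(frame.axes[0] @ np.array([1.0, 0, 0]))))
        assert ang < 1.0
        assert np.allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0)

    def test_known_rotation_recovered_within_2_degrees(self):
        rot = (0.0, 25.0, 10.0)
        mask, sp = _ellipsoid_mask((3000.0, 1500.0, 1200.0), rot=rot)
        frame = principal_axes(mask, sp)
        true_long = rotation_matrix(rot) @ np.array([1.0, 0, 0])
        ang = np.degrees(np.arccos(abs(frame.axes[0] @ true_long)))
        assert ang < 2.0

    def test_sphere_eigenvalue_tie_breaks_to_grid_axes(self):
        mask, sp = _sphere_mask(1000.0)
        frame = principal_axes(mask, sp)
        # degenerate covariance: each axis must coincide with a grid axis
        assert np.allclose(np.abs(frame.axes), np.eye(3)[::-1], atol=1e-6)
        # and a repeated call is bit-identical
        frame2 = principal_axes(mask, sp)
        assert np.array_equal(frame.axes, frame2.axes)

    def test_single_voxel_mask_rejected(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        with pytest.raises(ValueError, match="degenerate"):
            principal_axes(m, (1, 1, 1))


class TestSilhouette:
    def test_cylinder_projects_to_rectangle(self):
        m = np.zeros((80, 40, 40), bool)
        yy, xx = np.ogrid[:40, :40]
        m[10:70] = ((yy - 19.5) ** 2 + (xx - 19.5) ** 2) * 40**2 <= 600**2
        frame = principal_axes(m, (40, 40, 40))
        proj = project_silhouette(m, (40, 40, 40), frame)
        sil = proj.silhouette
        rows = np.nonzero(sil.any(axis=1))[0]
        widths = sil[rows].sum(axis=1)
        assert widths.std() / widths.mean() < 0.05  # near-constant width

    def test_sphere_projects_to_disc_of_same_radius(self):
        mask, sp = _sphere_mask(1000.0)
        frame = principal_axes(mask, sp)
        proj = project_silhouette(mask, sp, frame)
        area = proj.silhouette.sum() * proj.pixel_um**2
        r_eff = np.sqrt(area / np.pi)
        assert abs(r_eff - 1000.0) <= 1.5 * proj.pixel_um

    def test_projection_area_not_below_any_single_slice(self):
        mask, sp = _ellipsoid_mask((1500.0, 750.0, 600.0))
        frame = principal_axes(mask, sp)
        proj = project_silhouette(mask, sp, frame)
        # axis 3 is closest to the grid x axis here: compare against x slices
        max_slice = max(mask[:, :, k].sum() for k in range(mask.shape[2]))
        assert proj.silhouette.sum() * proj.pixel_um**2 >= max_slice * sp[0] * sp[1] * 0.999


class TestConicity:
    def test_voxelized_cone_chamber_reads_one(self):
        spec = PhantomSpec(
            grid_shape=(180, 170, 170),
            voxel_spacing_um=(40.0, 40.0, 40.0),
            chamber_shape="cone",
            chamber_semi_axes_um=(3000.0, 3000.0, 3000.0),
        )
        cone = generate_chamber_solid(spec)
        frame = principal_axes(cone, spec.voxel_spacing_um)
        proj = project_silhouette(cone, spec.voxel_spacing_um, frame)
        assert conicity_index(proj) == pytest.approx(1.0, abs=0.02)

    def test_semicircular_apex_reads_pi_over_2(self):
        # synthetic silhouette: half-disc of radius r above the base line,
        # rectangle below so the silhouette crosses the line
        r = 100
        n = 2 * r + 41
        sil = np.zeros((n, n), bool)
        base_row = 120.0
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        u = ii - base_row
        v = jj - (n - 1) / 2
        sil[(u > 0) & (u**2 + v**2 <= r**2)] = True
        sil[(u <= 0) & (u > -20) & (np.abs(v) <= r)] = True
        proj = Projection2D(sil, 10.0, base_row)
        assert conicity_index(proj) == pytest.approx(np.pi / 2, abs=0.02)

    def test_apical_bulge_strictly_increases_conicity(self):
        spec = PhantomSpec(
            grid_shape=(150, 120, 120),
            voxel_spacing_um=(40.0, 40.0, 40.0),
            chamber_shape="cone",
            chamber_semi_axes_um=(2200.0, 2200.0, 2200.0),
        )
        cone = generate_chamber_solid(spec)
        sp = spec.voxel_spacing_um
        frame = principal_axes(cone, sp)
        base_ci = conicity_index(project_silhouette(cone, sp, frame))
        # add a lateral bulge two-thirds of the way toward the apex
        idx = np.argwhere(cone)
        apexward = idx[np.argsort(idx[:, 0])[-len(idx) // 10 :]]
        centre = apexward.mean(axis=0) + np.array([0.0, 18.0, 0.0])
        zz, yy, xx = np.ogrid[: cone.shape[0], : cone.shape[1], : cone.shape[2]]
        bulge = (
            (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
        ) <= 15**2
        bulged = cone | bulge
        ci = conicity_index(project_silhouette(bulged, sp, principal_axes(bulged, sp)))
        assert ci > base_ci

    def test_silhouette_on_one_side_of_base_line_rejected(self):
        sil = np.zeros((50, 50), bool)
        sil[30:40, 10:40] = True  # entirely apical
        with pytest.raises(ValueError, match="base line"):
            conicity_index(Projection2D(sil, 10.0, 5.0))

    def test_matches_pixel_count_oracle_within_1pct(self, conicity_oracle):
        rng = np.random.default_rng(0)
        for trial in range(3):
            semi = (
                float(rng.uniform(1800, 2600)),
                float(rng.uniform(900, 1400)),
                float(rng.uniform(900, 1400)),
            )
            mask, sp = _ellipsoid_mask(semi, spacing=40.0)
            frame = principal_axes(mask, sp)
            proj = project_silhouette(mask, sp, frame)
            assert proj.silhouette.shape[0] <= 200
            ci = conicity_index(proj)
            assert ci == pytest.approx(conicity_oracle(proj), rel=0.01)


class TestApexVolume:
    def test_symmetric_ellipsoid_halves_exactly(self):
        mask, sp = _ellipsoid_mask((1500.0, 750.0, 750.0))
        frame = principal_axes(mask, sp)
        apex = apex_volume_mm3(mask, sp, frame)
        total = chamber_volume_mm3(mask, sp)
        assert apex == pytest.approx(total / 2, rel=0.01)

    def test_cone_apical_fraction_is_27_over_64(self):
        spec = PhantomSpec(
            grid_shape=(180, 170, 170),
            voxel_spacing_um=(40.0, 40.0, 40.0),
            chamber_shape="cone",
            chamber_semi_axes_um=(3000.0, 3000.0, 3000.0),
        )
        cone = generate_chamber_solid(spec)
        sp = spec.voxel_spacing_um
        frame = principal_axes(cone, sp)
        frac = apex_volume_mm3(cone, sp, frame) / chamber_volume_mm3(cone, sp)
        assert frac == pytest.approx(27 / 64, rel=0.02)

    def test_apical_and_basal_parts_partition_the_chamber(self):
        mask, sp = _ellipsoid_mask((1500.0, 750.0, 600.0))
        frame = principal_axes(mask, sp)
        apex = apex_volume_mm3(mask, sp, frame)
        flipped = principal_axes(mask, sp)
        flipped.axes[0] = -flipped.axes[0]
        basal = apex_volume_mm3(mask, sp, flipped)
        total = chamber_volume_mm3(mask, sp)
        # strict > on both sides leaves only exact-plane voxels unassigned
        assert apex + basal <= total
        assert (total - apex - basal) / total < 0.02


class TestMeshAndCurvature:
    def test_sphere_mesh_area_and_volume_match_analytic(self):
        mask, sp = _sphere_mask(2000.0)
        mesh = chamber_mesh(mask, sp)
        assert mesh.is_watertight
        assert mesh.area / 1e6 == pytest.approx(4 * np.pi * 4, rel=0.03)
        assert mesh.volume / 1e9 == pytest.approx(mask.sum() * np.prod(sp) / 1e9, rel=0.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            chamber_mesh(np.zeros((10, 10, 10), bool), (1, 1, 1))

    def test_clean_sphere_mesh_curvature_within_5pct_at_all_vertices(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=2000.0)
        H = mean_curvature(mesh)
        assert np.all(np.abs(H - 0.5) < 0.025)

    def test_cylinder_lateral_surface_curvature_is_half_inverse_radius(self):
        mesh = trimesh.creation.cylinder(radius=1000.0, height=6000.0, sections=96)
        mesh = mesh.subdivide()
        H = mean_curvature(mesh)
        v = mesh.vertices
        lateral = np.abs(v[:, 2]) < 2000.0
        vals = H[lateral & np.isfinite(H)]
        assert np.median(vals) == pytest.approx(0.5, rel=0.05)

    def test_voxelized_sphere_area_weighted_mean_within_5pct(self):
        mask, sp = _sphere_mask(2000.0)
        mesh = chamber_mesh(mask, sp)
        H = mean_curvature(mesh)
        A = _vertex_areas(mesh)
        assert np.sum(H * A) / A.sum() == pytest.approx(0.5, rel=0.05)

    def test_sphere_histogram_spikes_at_inverse_radius(self):
        mask, sp = _sphere_mask(2000.0)
        mesh = chamber_mesh(mask, sp)
        H = mean_curvature(mesh)
        frame = principal_axes(mask, sp)
        hist = apical_curvature_histogram(mesh, H, frame, bins=16, hist_range_mm=(-1, 1))
        assert hist.frequencies.sum() == pytest.approx(1.0)
        mode_centre = (
            hist.bin_edges_mm[np.argmax(hist.frequencies)]
            + (hist.bin_edges_mm[1] - hist.bin_edges_mm[0]) / 2
        )
        assert abs(mode_centre - 0.5) <= 0.125  # mode within one bin of 1/r
        assert hist.mean_mm == pytest.approx(0.5, rel=0.05)

    def test_apical_dilation_shifts_curvature_distribution(self):
        mask, sp = _ellipsoid_mask((1800.0, 900.0, 900.0))
        frame = principal_axes(mask, sp)
        mesh = chamber_mesh(mask, sp)
        base_hist = apical_curvature_histogram(mesh, mean_curvature(mesh), frame)
        # apical bulge: a sphere pushed sideways out of the apex region
        idx = np.argwhere(mask)
        apex_vox = idx[np.argmax(idx[:, 0])]
        zz, yy, xx = np.ogrid[: mask.shape[0], : mask.shape[1], : mask.shape[2]]
        bulge = (
            (zz - (apex_vox[0] - 8)) ** 2
            + (yy - (apex_vox[1] + 14)) ** 2
            + (xx - apex_vox[2]) ** 2
        ) <= 12**2
        dilated = mask | bulge
        frame2 = principal_axes(dilated, sp)
        mesh2 = chamber_mesh(dilated, sp)
        hist2 = apical_curvature_histogram(mesh2, mean_curvature(mesh2), frame2)
        l1 = np.abs(base_hist.frequencies - hist2.frequencies).sum()
        assert l1 > 0.1

        # the dilation neck introduces strongly concave surface that the
        # plain ellipsoid entirely lacks
        def concave_mass(mesh, frame):
            H = mean_curvature(mesh)
            A = _vertex_areas(mesh)
            sel = ((mesh.vertices - frame.centroid_um) @ frame.axes[0] > 0) & np.isfinite(H)
            return np.sum(A[sel & (H < -0.5)]) / np.sum(A[sel])

        assert concave_mass(mesh, frame) < 0.002
        assert concave_mass(mesh2, frame2) > 0.01


class TestScaleCovariance:
    @pytest.mark.parametrize("s", [0.5, 2.0])
    def test_conicity_volume_curvature_scale_as_expected(self, s):
        mask, _ = _ellipsoid_mask((1500.0, 750.0, 600.0), spacing=40.0)
        sp1 = (40.0, 40.0, 40.0)
        sp2 = tuple(40.0 * s for _ in range(3))  # same voxels, scaled physically
        f1, f2 = principal_axes(mask, sp1), principal_axes(mask, sp2)
        ci1 = conicity_index(project_silhouette(mask, sp1, f1))
        ci2 = conicity_index(project_silhouette(mask, sp2, f2))
        assert ci2 == pytest.approx(ci1, rel=1e-6)
        v1, v2 = chamber_volume_mm3(mask, sp1), chamber_volume_mm3(mask, sp2)
        assert v2 == pytest.approx(v1 * s**3, rel=1e-9)
        H1 = mean_curvature(chamber_mesh(mask, sp1))
        H2 = mean_curvature(chamber_mesh(mask, sp2))
        assert np.nanmedian(H2) == pytest.approx(np.nanmedian(H1) / s, rel=1e-3)
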