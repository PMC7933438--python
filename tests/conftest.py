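"""Shared fixtures: reference phantoms (built once per session) and
independent brute-force oracles for thickness and conicity."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from cardiomorph import (
    diastolic_heart_spec,
    generate_heart_phantom,
    local_thickness,
    principal_axes,
    segment_chamber,
    tissue_mask,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_local_thickness(mask: np.ndarray, spacing) -> np.ndarray:
    """Exhaustive maximal-sphere thickness: for every foreground voxel q,
    the largest 2*EDT(p) over all foreground voxels p whose inscribed
    sphere contains q.  O(N^2); only for small masks."""
    mask = np.asarray(mask, bool)
    spacing = np.asarray(spacing, float)
    edt = ndi.distance_transform_edt(mask, sampling=spacing)
    idx = np.argwhere(mask)
    radii = edt[mask]
    thick = np.zeros(mask.shape)
    q_idx = idx
    for start in range(0, len(q_idx), 1024):
        chunk = q_idx[start : start + 1024]
        # squared physical distance from every chunk voxel to every centre
        d2 = np.zeros((len(chunk), len(idx)))
        for ax in range(3):
            d2 += ((chunk[:, ax : ax + 1] - idx[None, :, ax]) * spacing[ax]) ** 2
        covered = d2 <= radii[None, :] ** 2
        best = np.where(covered, 2.0 * radii[None, :], 0.0).max(axis=1)
        thick[tuple(chunk.T)] = best
    return thick


def pixel_count_conicity(proj) -> float:
    """Conicity via explicit point-in-triangle pixel counting.

    Builds the same fitted triangle (base-line endpoints + apical extreme)
    but measures its area by counting silhouette-grid pixel centres inside
    the polygon rather than by the closed-form triangle formula.
    """
    sil = proj.silhouette
    px = proj.pixel_um
    u1 = (np.arange(sil.shape[0]) - proj.base_row) * px
    apical = u1 > 0
    row_frac = np.clip(u1 / px + 0.5, 0.0, 1.0)
    apical_area = float(sil.sum(axis=1) @ row_frac)
    i_base = int(round(proj.base_row))
    cols = np.nonzero(sil[i_base])[0]
    # same triangle vertices as the pipeline (cell-union extents); only the
    # area measurement differs
    j0, j1 = cols.min() - 0.5, cols.max() + 0.5
    rows = np.nonzero(sil.any(axis=1) & apical)[0]
    i_apex_row = rows[np.argmax(u1[rows])]
    apex_i = u1[i_apex_row] / px + proj.base_row + 0.5
    apex_j = float(np.mean(np.nonzero(sil[i_apex_row])[0]))
    # triangle vertices in (row, col) pixel coordinates
    a = np.array([proj.base_row, j0])
    b = np.array([proj.base_row, j1])
    c = np.array([apex_i, apex_j])
    # supersampled point-in-triangle count: 4x4 sample points per pixel,
    # removing the lattice-alignment bias of single-centre counting
    sub = (np.arange(4) + 0.5) / 4.0 - 0.5
    ii, jj = np.meshgrid(np.arange(sil.shape[0]), np.arange(sil.shape[1]), indexing="ij")
    tri_pixels = 0.0
    for di in sub:
        for dj in sub:
            pi = ii.ravel() + di
            pj = jj.ravel() + dj

            def side(p1, p2):
                return (p2[0] - p1[0]) * (pj - p1[1]) - (p2[1] - p1[1]) * (pi - p1[0])

            d1, d2, d3 = side(a, b), side(b, c), side(c, a)
            inside = ((d1 <= 0) & (d2 <= 0) & (d3 <= 0)) | (
                (d1 >= 0) & (d2 >= 0) & (d3 >= 0)
            )
            tri_pixels += inside.sum() / 16.0
    return apical_area / tri_pixels


@pytest.fixture(scope="session")
def thickness_oracle():
    return brute_force_local_thickness


@pytest.fixture(scope="session")
def conicity_oracle():
    return pixel_count_conicity


# ---------------------------------------------------------------------------
# Reference phantoms (expensive; build once)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def infarct_heart():
    """Infarcted whole-heart phantom with its local-thickness map."""
    spec = diastolic_heart_spec(seed=1, spacing_um=30.0, infarct=True)
    bundle = generate_heart_phantom(spec)
    thick = local_thickness(bundle.truth_tissue, spec.voxel_spacing_um)
    return spec, bundle, thick


@pytest.fixture(scope="session")
def sham_heart_pair():
    """The same sham heart unrotated and rigidly rotated, with segmented
    chambers and principal-axis frames for each."""
    out = {}
    for key, rot in (("plain", (0.0, 0.0, 0.0)), ("rotated", (0.0, 30.0, 20.0))):
        spec = diastolic_heart_spec(seed=2, spacing_um=30.0, rotation_deg=rot)
        bundle = generate_heart_phantom(spec)
        tis = tissue_mask(bundle.image)
        chamber = segment_chamber(bundle.image, tis)
        frame = principal_axes(chamber, spec.voxel_spacing_um)
        out[key] = dict(spec=spec, bundle=bundle, tissue=tis, chamber=chamber, frame=frame)
    return out
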