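"""Tissue and LV-chamber segmentation with the diastole quality filter.

The segmenter here is classical — global Otsu threshold, morphological
cleanup, cavity extraction after capping the valve-plane opening — and
satisfies the same mask contract as a learned segmenter; externally
produced masks can be passed straight into every downstream stage, so the
segmentation backend is pluggable.

Quality control follows the diastole rule used for cleared hearts: a heart
is accepted as fully diastolic only when the chamber volume is strictly
above 10 mm³ and the chamber long axis strictly above 4 mm; hearts below
either threshold are excluded from group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .lv_morphometry import chamber_volume_mm3, long_axis_length_mm, principal_axes
from .volume_io import VolumeImage

#: 26-connectivity for tissue components, 6-connectivity for cavities
_CONN_TISSUE = np.ones((3, 3, 3), bool)
_CONN_CAVITY = ndi.generate_binary_structure(3, 1)


@dataclass
class QCResult:
    """Diastole quality-control verdict for a segmented chamber."""

    volume_mm3: float
    long_axis_mm: float
    passed: bool
    reasons: list[str] = field(default_factory=list)
    volume_threshold_mm3: float = 10.0
    long_axis_threshold_mm: float = 4.0


def _largest_component(mask: np.ndarray, structure: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=structure)
    if n == 0:
        raise ValueError("no foreground component")
    counts = np.bincount(labels.ravel())[1:]
    # ties resolve to the lowest label, i.e. the component whose first voxel
    # comes earliest in raster order — deterministic
    return labels == (int(np.argmax(counts)) + 1)


def tissue_mask(
    image: VolumeImage,
    threshold: float | None = None,
    opening_radius_vox: int = 1,
    hole_fill_fraction: float = 0.05,
    min_component_fraction: float = 0.003,
) -> np.ndarray:
    """Segment bright tissue from the structure (autofluorescence) channel.

    Global threshold (Otsu unless given) → binary opening (radius 1 voxel)
    → keep the largest 26-connected component, excluding debris such as
    scar fragments or suture material outside the heart → fill internal
    holes smaller than ``hole_fill_fraction`` of the component (so noise
    holes close but the chamber itself never does).

    Raises ``ValueError`` when thresholding leaves no dominant component,
    e.g. on a pure-noise volume.
    """
    data = image.data
    thr = float(threshold) if threshold is not None else float(threshold_otsu(data))
    fg = data > thr
    if opening_radius_vox > 0:
        fg = ndi.binary_opening(fg, structure=_CONN_CAVITY, iterations=opening_radius_vox)
    if not fg.any():
        raise ValueError("empty foreground after threshold and opening")
    comp = _largest_component(fg, _CONN_TISSUE)
    if comp.sum() < min_component_fraction * comp.size:
        raise ValueError(
            "no dominant tissue component (largest component "
            f"{comp.sum() / comp.size:.2%} of volume)"
        )
    # fill only small enclosed holes
    filled = ndi.binary_fill_holes(comp, structure=_CONN_CAVITY)
    holes, nh = ndi.label(filled & ~comp, structure=_CONN_CAVITY)
    if nh:
        sizes = np.bincount(holes.ravel())[1:]
        small = np.flatnonzero(sizes < hole_fill_fraction * comp.sum()) + 1
        comp = comp | np.isin(holes, small)
    return comp


def _edt_close(mask: np.ndarray, radius_um: float, spacing_um: Sequence[float]) -> np.ndarray:
    """Morphological closing with a physical-radius ball via two EDTs.

    The volume is padded with background by the ball radius first, so the
    dilation/erosion pair behaves correctly when the mask (or its dilation)
    would touch the array border.
    """
    pad = [int(np.ceil(radius_um / s)) + 1 for s in spacing_um]
    padded = np.pad(mask, [(p, p) for p in pad])
    dilated = ndi.distance_transform_edt(~padded, sampling=spacing_um) <= radius_um
    eroded = ndi.distance_transform_edt(dilated, sampling=spacing_um) > radius_um
    closed = eroded | padded
    sl = tuple(slice(p, -p) for p in pad)
    return closed[sl]


def segment_chamber(
    image: VolumeImage,
    tissue: np.ndarray,
    closing_radius_um: float = 1000.0,
) -> np.ndarray:
    """Extract the LV chamber as the largest cavity enclosed by the tissue.

    The basal (valve-plane) opening is capped by morphological closing of
    the tissue mask with a ball larger than the aperture (default 1 mm).
    The capped mask only decides what is *inside* the heart (via hole
    filling); the chamber is then the largest 6-connected cavity of the
    original tissue within that interior, so narrow features such as the
    apex — which the closing itself would swallow — are preserved.  The
    returned mask is disjoint from the tissue mask by construction.
    """
    tissue = np.asarray(tissue, bool)
    capped = _edt_close(tissue, closing_radius_um, image.spacing_um)
    interior = ndi.binary_fill_holes(capped, structure=_CONN_CAVITY)
    cavity = interior & ~tissue
    if not cavity.any():
        raise ValueError("no cavity enclosed by the tissue mask")
    labels, n = ndi.label(cavity, structure=_CONN_CAVITY)
    border_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    counts[border_labels] = 0
    if counts.max() == 0:
        raise ValueError("no enclosed cavity found (is the basal opening capped?)")
    return labels == int(np.argmax(counts))


def diastole_qc(
    chamber: np.ndarray,
    spacing_um: Sequence[float],
    volume_threshold_mm3: float = 10.0,
    long_axis_threshold_mm: float = 4.0,
) -> QCResult:
    """Diastole check: pass iff volume AND long axis are strictly above threshold."""
    chamber = np.asarray(chamber, bool)
    if not chamber.any():
        raise ValueError("empty chamber mask")
    vol = chamber_volume_mm3(chamber, spacing_um)
    frame = principal_axes(chamber, spacing_um)
    axis_mm = long_axis_length_mm(chamber, spacing_um, frame)
    reasons = []
    if not vol > volume_threshold_mm3:
        reasons.append(
            f"chamber volume {vol:.2f} mm³ not above {volume_threshold_mm3:g} mm³"
        )
    if not axis_mm > long_axis_threshold_mm:
        reasons.append(
            f"long axis {axis_mm:.2f} mm not above {long_axis_threshold_mm:g} mm"
        )
    return QCResult(
        volume_mm3=vol,
        long_axis_mm=axis_mm,
        passed=not reasons,
        reasons=reasons,
        volume_threshold_mm3=volume_threshold_mm3,
        long_axis_threshold_mm=long_axis_threshold_mm,
    )
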