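"""Seeded synthetic heart phantoms with exact voxel-level ground truth.

Two generators are provided, mirroring the two imaging regimes of a
light-sheet infarct study:

``generate_heart_phantom``
    A whole-heart phantom at coarse voxel spacing: an analytic LV chamber
    solid (cone, capped cone or prolate ellipsoid, optionally rotated),
    wrapped in a myocardial shell whose thickness varies by angular sector
    and apico-basal position — an apical thin-walled infarct sector
    (< 300 µm), a border ramp (300-500 µm) and remote healthy wall
    (> 500 µm) — with an optional open valve plane at the base.

``generate_wall_patch``
    A high-resolution patch of ventricular wall: parallel bands of known
    thickness, each seeded with bright tubular vessels (lumen diameter
    below 10 µm) placed as straight random tubes until the band's target
    volume fraction is met exactly.

Both render a structure (autofluorescence) channel and a vessel (lectin)
channel as piecewise-constant class intensities plus additive Gaussian
noise (no PSF blur by default, so the ground truth stays exact), and both
are bit-reproducible for a fixed (spec, seed).

Axis order is (z, y, x), 0-based voxel indexing, physical coordinate =
index x spacing (voxel-centre convention).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage as ndi

from .volume_io import VolumeImage
from .wall_thickness import ZONE_NAMES, classify_thickness

_CHAMBER_SHAPES = ("cone", "capped_cone", "prolate_ellipsoid")
_MAX_VESSEL_FRACTION = 0.40
_MAX_VESSEL_RADIUS_UM = 6.0  # lumen diameter < 10 µm, plus voxelisation tolerance


@dataclass
class IntensityModel:
    """Piecewise-constant class intensities and the additive noise level.

    ``vessel_channel_tissue`` is the tissue level in the lectin channel;
    the default ``None`` means no tissue autofluorescence there, i.e. the
    vessel channel is background plus vessels (plus noise).
    """

    background: float = 100.0
    tissue: float = 600.0
    vessel: float = 1500.0
    noise_sigma: float = 30.0
    vessel_channel_tissue: float | None = None


@dataclass
class WallSector:
    """Target wall thickness over an angular x apico-basal sector.

    Angles are degrees about the chamber long axis in [-180, 180), with
    ``phi_start > phi_end`` meaning a sector wrapping through ±180°.
    ``s`` runs 0 at the base to 1 at the apex.  Thickness ramps linearly
    from ``thickness_start_um`` to ``thickness_end_um`` across the angular
    span (equal values give a constant-thickness sector).
    """

    phi_start_deg: float
    phi_end_deg: float
    thickness_start_um: float
    thickness_end_um: float
    s_start: float = 0.0
    s_end: float = 1.0
    label: str = ""


@dataclass
class PhantomSpec:
    """Full parameterisation of a whole-heart phantom."""

    grid_shape: tuple[int, int, int]
    voxel_spacing_um: tuple[float, float, float]
    chamber_shape: str = "prolate_ellipsoid"
    chamber_semi_axes_um: tuple[float, float, float] = (2200.0, 1100.0, 1100.0)
    base_opening: bool = False
    base_aperture_um: float = 800.0
    wall_sectors: list[WallSector] = field(default_factory=list)
    default_wall_thickness_um: float = 600.0
    vessel_fraction_by_zone: dict[str, float] = field(default_factory=dict)
    vessel_radius_range_um: tuple[float, float] = (4.0, 5.0)
    tube_length_um: float = 200.0
    intensity: IntensityModel = field(default_factory=IntensityModel)
    seed: int = 0
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    debris: bool = False
    blur_sigma_um: float = 0.0
    zone_cutoffs_um: tuple[float, float] = (300.0, 500.0)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacings must be positive")
        if self.chamber_shape not in _CHAMBER_SHAPES:
            raise ValueError(f"chamber_shape must be one of {_CHAMBER_SHAPES}")
        if any(a <= 0 for a in self.chamber_semi_axes_um):
            raise ValueError("chamber semi-axes must be positive")
        for name, frac in self.vessel_fraction_by_zone.items():
            if name not in ZONE_NAMES.values():
                raise ValueError(f"unknown zone {name!r}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("vessel fractions must be in [0, 1]")
            if frac > _MAX_VESSEL_FRACTION:
                raise ValueError(
                    f"vessel fraction {frac} infeasible for non-overlapping tubes "
                    f"(limit {_MAX_VESSEL_FRACTION})"
                )
        rmin, rmax = self.vessel_radius_range_um
        if not 0 < rmin <= rmax <= _MAX_VESSEL_RADIUS_UM:
            raise ValueError(
                f"vessel radii must lie in (0, {_MAX_VESSEL_RADIUS_UM}] µm "
                "to match the target lumen scale"
            )

    def max_wall_thickness_um(self) -> float:
        t = [self.default_wall_thickness_um]
        for sec in self.wall_sectors:
            t.extend([sec.thickness_start_um, sec.thickness_end_um])
        return max(t)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "wall_sectors" in d:
            d["wall_sectors"] = [
                s if isinstance(s, WallSector) else WallSector(**s)
                for s in d["wall_sectors"]
            ]
        if "intensity" in d and not isinstance(d["intensity"], IntensityModel):
            d["intensity"] = IntensityModel(**d["intensity"])
        for key in ("grid_shape", "voxel_spacing_um", "chamber_semi_axes_um",
                    "rotation_deg", "zone_cutoffs_um", "vessel_radius_range_um"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    """Read a phantom spec from YAML or JSON."""
    return PhantomSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
    return path


@dataclass
class PhantomBundle:
    """A rendered phantom plus its exact voxel-level ground truth."""

    image: VolumeImage
    vessel_image: VolumeImage
    truth_tissue: np.ndarray
    truth_chamber: np.ndarray
    truth_lv_wall: np.ndarray
    truth_vessels: np.ndarray
    truth_thickness: np.ndarray
    truth_zones: np.ndarray
    spec: object
    truth_septum: np.ndarray | None = None


def _axis_rotation(axis: int, deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    m = np.eye(3)
    other = [a for a in range(3) if a != axis]
    m[other[0], other[0]] = c
    m[other[0], other[1]] = -s
    m[other[1], other[0]] = s
    m[other[1], other[1]] = c
    return m


def rotation_matrix(rotation_deg: Sequence[float]) -> np.ndarray:
    """Composed rotation about grid axes 0, 1, 2 (in that order), for
    (z, y, x)-ordered vectors."""
    r0, r1, r2 = rotation_deg
    return _axis_rotation(0, r0) @ _axis_rotation(1, r1) @ _axis_rotation(2, r2)


def _local_coords(spec: PhantomSpec):
    """Per-voxel coordinates in the (rotated) chamber frame, float32 µm.

    Returns (u, v, w): u along the chamber long axis, v/w transverse.
    """
    shape = spec.grid_shape
    spacing = np.asarray(spec.voxel_spacing_um, float)
    centre = (np.asarray(shape, float) - 1.0) / 2.0 * spacing
    ax = [
        (np.arange(shape[i]) * spacing[i] - centre[i]).astype(np.float32)
        for i in range(3)
    ]
    R = rotation_matrix(spec.rotation_deg)
    Rt = R.T.astype(np.float32)
    grids = [ax[0][:, None, None], ax[1][None, :, None], ax[2][None, None, :]]
    out = []
    for row in range(3):
        out.append(Rt[row, 0] * grids[0] + Rt[row, 1] * grids[1] + Rt[row, 2] * grids[2])
    return out[0], out[1], out[2]


def _chamber_inside(spec: PhantomSpec, u, v, w) -> np.ndarray:
    a, b, c = spec.chamber_semi_axes_um
    if spec.chamber_shape == "prolate_ellipsoid":
        return (u / a) ** 2 + (v / b) ** 2 + (w / c) ** 2 <= 1.0
    r2 = (v / b) ** 2 + (w / c) ** 2
    if spec.chamber_shape == "cone":
        # base disc at u = -a (radius b, c), apex at u = +a
        rho = (a - u) / (2.0 * a)
        return (u >= -a) & (u <= a) & (r2 <= rho**2)
    # capped_cone: cone with the apical quarter replaced by an ellipsoidal cap
    cap_frac = 0.25
    u_t = a - cap_frac * 2.0 * a
    rho_t = (a - u_t) / (2.0 * a)
    cone = (u >= -a) & (u <= u_t) & (r2 <= ((a - u) / (2.0 * a)) ** 2)
    cap = (u > u_t) & (
        ((u - u_t) / (a - u_t)) ** 2 + r2 / rho_t**2 <= 1.0
    )
    return cone | cap


def generate_chamber_solid(spec: PhantomSpec) -> np.ndarray:
    """Voxelise the requested analytic chamber solid (boolean mask).

    Raises ``ValueError`` when the solid does not fit inside the grid.
    """
    u, v, w = _local_coords(spec)
    chamber = _chamber_inside(spec, u, v, w)
    if not chamber.any():
        raise ValueError("chamber solid is empty on this grid")
    if (
        chamber[0].any() or chamber[-1].any()
        or chamber[:, 0].any() or chamber[:, -1].any()
        or chamber[:, :, 0].any() or chamber[:, :, -1].any()
    ):
        raise ValueError(
            "chamber solid exceeds the grid: enlarge grid_shape or shrink the "
            "chamber semi-axes"
        )
    return chamber


def _in_sector(phi_deg: np.ndarray, sector: WallSector):
    p0, p1 = sector.phi_start_deg, sector.phi_end_deg
    if p0 <= p1:
        inside = (phi_deg >= p0) & (phi_deg <= p1)
        span = p1 - p0
    else:  # wraps through +/-180
        inside = (phi_deg >= p0) | (phi_deg <= p1)
        span = 360.0 - (p0 - p1)
    frac = np.mod(phi_deg - p0, 360.0) / max(span, 1e-9)
    return inside, np.clip(frac, 0.0, 1.0)


def _thickness_field(spec: PhantomSpec, u, v, w):
    a = spec.chamber_semi_axes_um[0]
    T = np.full(spec.grid_shape, spec.default_wall_thickness_um, np.float32)
    phi = np.degrees(np.arctan2(w, v))
    s = np.clip((u + a) / (2.0 * a), 0.0, 1.0)
    septum = np.zeros(spec.grid_shape, bool)
    for sec in spec.wall_sectors:
        inside, frac = _in_sector(phi, sec)
        m = inside & (s >= sec.s_start) & (s <= sec.s_end)
        T[m] = (
            sec.thickness_start_um
            + (sec.thickness_end_um - sec.thickness_start_um) * frac[m]
        ).astype(np.float32)
        if sec.label == "septum":
            septum |= m
    return T, septum


def _add_tubes(
    rng: np.random.Generator,
    zone_mask: np.ndarray,
    occupied: np.ndarray,
    spacing: np.ndarray,
    radius_range: tuple[float, float],
    target_fraction: float,
    tube_length_um: float,
    max_attempts: int = 50000,
) -> None:
    """Lay straight non-overlapping tubes into ``occupied`` (in place) until
    the zone's vessel voxel count equals the target exactly (the last tube is
    trimmed in raster order if it would overshoot)."""
    nz = int(zone_mask.sum())
    target = int(round(target_fraction * nz))
    if target == 0:
        return
    zone_idx = np.argwhere(zone_mask)
    shape = zone_mask.shape
    added = int(np.count_nonzero(occupied & zone_mask))
    attempts = 0
    while added < target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not reach vessel fraction {target_fraction} after "
                f"{max_attempts} tube attempts"
            )
        centre = zone_idx[rng.integers(len(zone_idx))] * spacing
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        r = rng.uniform(*radius_range)
        half = tube_length_um / 2.0
        p0, p1 = centre - d * half, centre + d * half
        lo = np.maximum(np.floor((np.minimum(p0, p1) - r) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((np.maximum(p0, p1) + r) / spacing).astype(int) + 1,
            np.asarray(shape),
        )
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(lo[i], hi[i]) for i in range(3))
        coords = np.stack(
            np.meshgrid(
                *[np.arange(lo[i], hi[i]) * spacing[i] for i in range(3)],
                indexing="ij",
            ),
            axis=-1,
        )
        wvec = p1 - p0
        denom = float(wvec @ wvec)
        t = np.clip(((coords - p0) @ wvec) / denom, 0.0, 1.0)
        closest = p0 + t[..., None] * wvec
        dist2 = np.sum((coords - closest) ** 2, axis=-1)
        tube = (dist2 <= r * r) & zone_mask[sl]
        if not tube.any():
            continue
        overlap = int((tube & occupied[sl]).sum())
        if overlap > 0.5 * tube.sum():
            continue  # mostly redundant with existing vessels
        tube &= ~occupied[sl]  # vessels never double-count a voxel
        n_new = int(tube.sum())
        if n_new == 0:
            continue
        if added + n_new > target:
            keep = target - added
            flat = np.flatnonzero(tube)
            trimmed = np.zeros(tube.size, bool)
            trimmed[flat[:keep]] = True
            tube = trimmed.reshape(tube.shape)
            n_new = keep
        occupied[sl] |= tube
        added += n_new


def _render_channels(
    spec_intensity: IntensityModel,
    tissue: np.ndarray,
    vessels: np.ndarray,
    debris: np.ndarray | None,
    spacing: np.ndarray,
    blur_sigma_um: float,
    rng: np.random.Generator,
):
    inten = spec_intensity
    structure = np.full(tissue.shape, inten.background, np.float32)
    structure[tissue] = inten.tissue
    if debris is not None:
        structure[debris] = inten.tissue
    vessel_img = np.full(tissue.shape, inten.background, np.float32)
    if inten.vessel_channel_tissue is not None:
        vessel_img[tissue] = inten.vessel_channel_tissue
    vessel_img[vessels] = inten.vessel
    if blur_sigma_um > 0:
        sigma_vox = blur_sigma_um / spacing
        structure = ndi.gaussian_filter(structure, sigma_vox)
        vessel_img = ndi.gaussian_filter(vessel_img, sigma_vox)
    if inten.noise_sigma > 0:
        structure = structure + rng.normal(
            0.0, inten.noise_sigma, tissue.shape
        ).astype(np.float32)
        vessel_img = vessel_img + rng.normal(
            0.0, inten.noise_sigma, tissue.shape
        ).astype(np.float32)
    return structure, vessel_img


def generate_heart_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the full whole-heart phantom bundle for a spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_spacing_um, float)
    u, v, w = _local_coords(spec)
    chamber = generate_chamber_solid(spec)
    T, septum = _thickness_field(spec, u, v, w)
    dist = ndi.distance_transform_edt(~chamber, sampling=spacing)
    tissue = (dist > 0) & (dist <= T)
    if spec.base_opening:
        ap_r = spec.base_aperture_um / 2.0
        incyl = (v**2 + w**2) <= ap_r**2
        in_ch = incyl & chamber
        if not in_ch.any():
            raise ValueError("base aperture misses the chamber")
        u_open = float(u[in_ch].min()) + float(spacing.max())
        tissue &= ~(incyl & (u <= u_open))
    if (
        tissue[0].any() or tissue[-1].any()
        or tissue[:, 0].any() or tissue[:, -1].any()
        or tissue[:, :, 0].any() or tissue[:, :, -1].any()
    ):
        raise ValueError("myocardial shell exceeds the grid: enlarge grid_shape")
    septum &= tissue
    truth_thickness = np.where(tissue, T, 0.0).astype(np.float32)
    zones = classify_thickness(T, spec.zone_cutoffs_um)
    zones[~tissue] = 0
    lv_wall = tissue & ~septum

    vessels = np.zeros(spec.grid_shape, bool)
    for name, frac in sorted(spec.vessel_fraction_by_zone.items()):
        label = {v: k for k, v in ZONE_NAMES.items()}[name]
        _add_tubes(
            rng,
            (zones == label) & lv_wall,
            vessels,
            spacing,
            spec.vessel_radius_range_um,
            frac,
            spec.tube_length_um,
        )

    debris = None
    if spec.debris:
        debris = np.zeros(spec.grid_shape, bool)
        centre = np.array([8, 8, 8])
        zz, yy, xx = np.ogrid[: spec.grid_shape[0], : spec.grid_shape[1], : spec.grid_shape[2]]
        blob = ((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2) <= 16
        debris = blob & ~tissue & ~chamber

    structure, vessel_img = _render_channels(
        spec.intensity, tissue, vessels, debris, spacing, spec.blur_sigma_um, rng
    )
    assert not (chamber & tissue).any()
    assert not (vessels & ~tissue).any()
    return PhantomBundle(
        image=VolumeImage(structure, tuple(spacing), "autofluorescence"),
        vessel_image=VolumeImage(vessel_img, tuple(spacing), "lectin"),
        truth_tissue=tissue,
        truth_chamber=chamber,
        truth_lv_wall=lv_wall,
        truth_vessels=vessels,
        truth_thickness=truth_thickness,
        truth_zones=zones,
        spec=spec,
        truth_septum=septum if septum.any() else None,
    )


# ---------------------------------------------------------------------------
# High-resolution wall patch
# ---------------------------------------------------------------------------

@dataclass
class WallBand:
    """One band of ventricular wall of known thickness and vessel load."""

    thickness_um: float
    width_um: float
    vessel_fraction: float = 0.0


@dataclass
class WallPatchSpec:
    """A flat wall patch of parallel bands, imaged at vessel resolution."""

    bands: list[WallBand]
    voxel_spacing_um: tuple[float, float, float] = (5.0, 5.0, 5.0)
    depth_um: float = 250.0
    margin_um: float = 40.0
    vessel_radius_range_um: tuple[float, float] = (4.0, 5.0)
    tube_length_um: float = 200.0
    intensity: IntensityModel = field(default_factory=IntensityModel)
    seed: int = 0
    zone_cutoffs_um: tuple[float, float] = (300.0, 500.0)

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("at least one band required")
        for b in self.bands:
            if b.thickness_um <= 0 or b.width_um <= 0:
                raise ValueError("band thickness and width must be positive")
            if not 0.0 <= b.vessel_fraction <= _MAX_VESSEL_FRACTION:
                raise ValueError(
                    f"band vessel fraction must be in [0, {_MAX_VESSEL_FRACTION}]"
                )
        rmin, rmax = self.vessel_radius_range_um
        if not 0 < rmin <= rmax <= _MAX_VESSEL_RADIUS_UM:
            raise ValueError("vessel radii out of the target lumen range")


def generate_wall_patch(spec: WallPatchSpec) -> PhantomBundle:
    """Build a wall-patch bundle: banded tissue slab + per-band vessels."""
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_spacing_um, float)
    max_t = max(b.thickness_um for b in spec.bands)
    nz = int(np.ceil((max_t + 2 * spec.margin_um) / spacing[0]))
    ny = int(np.ceil(sum(b.width_um for b in spec.bands) / spacing[1]))
    nx = int(np.ceil(spec.depth_um / spacing[2]))
    shape = (nz, ny, nx)
    tissue = np.zeros(shape, bool)
    thickness = np.zeros(shape, np.float32)
    z = np.arange(nz) * spacing[0]
    y = np.arange(ny) * spacing[1]
    z0 = spec.margin_um
    y_edges = np.cumsum([0.0] + [b.width_um for b in spec.bands])
    band_masks = []
    for b, ylo, yhi in zip(spec.bands, y_edges[:-1], y_edges[1:]):
        band_y = (y >= ylo) & (y < yhi)
        band_z = (z >= z0) & (z < z0 + b.thickness_um)
        m = band_z[:, None, None] & band_y[None, :, None] & np.ones(nx, bool)[None, None, :]
        tissue |= m
        thickness[m] = b.thickness_um
        band_masks.append(m)
    zones = classify_thickness(thickness, spec.zone_cutoffs_um)
    zones[~tissue] = 0
    vessels = np.zeros(shape, bool)
    for b, m in zip(spec.bands, band_masks):
        _add_tubes(
            rng, m, vessels, spacing, spec.vessel_radius_range_um,
            b.vessel_fraction, spec.tube_length_um,
        )
    structure, vessel_img = _render_channels(
        spec.intensity, tissue, vessels, None, spacing, 0.0, rng
    )
    return PhantomBundle(
        image=VolumeImage(structure, tuple(spacing), "autofluorescence"),
        vessel_image=VolumeImage(vessel_img, tuple(spacing), "lectin"),
        truth_tissue=tissue,
        truth_chamber=np.zeros(shape, bool),
        truth_lv_wall=tissue,
        truth_vessels=vessels,
        truth_thickness=thickness,
        truth_zones=zones,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Reference specs emulating the study regimes
# ---------------------------------------------------------------------------

def diastolic_heart_spec(
    seed: int = 0,
    spacing_um: float = 30.0,
    infarct: bool = False,
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    **overrides,
) -> PhantomSpec:
    """A diastole-passing whole-heart phantom (~11 mm³ chamber, 4.4 mm axis).

    With ``infarct=True`` an apical anterior sector is thinned to 250 µm,
    flanked by narrow linear border ramps back to the 600 µm remote wall
    (the ramps sweep through the 300-500 µm border-zone range), emulating
    the thin dilated infarct wall with its abrupt transition to healthy
    myocardium; the opposite sector is labelled as septum.
    """
    sectors = [WallSector(120.0, -120.0, 600.0, 600.0, label="septum")]
    if infarct:
        sectors += [
            WallSector(-45.0, 45.0, 250.0, 250.0, s_start=0.45, label="infarct"),
            WallSector(-50.0, -45.0, 600.0, 250.0, s_start=0.45, label="border"),
            WallSector(45.0, 50.0, 250.0, 600.0, s_start=0.45, label="border"),
        ]
    semi = (2200.0, 1100.0, 1100.0)
    margin = 700.0 + 4 * spacing_um
    if any(r != 0 for r in rotation_deg):
        # bounding sphere: the rotated chamber fits whatever the angles
        extent = np.full(3, 2 * (max(semi) + margin))
    else:
        extent = np.array(
            [2 * (semi[0] + margin), 2 * (semi[1] + margin), 2 * (semi[2] + margin)]
        )
    shape = tuple(int(np.ceil(e / spacing_um)) for e in extent)
    kwargs = dict(
        grid_shape=shape,
        voxel_spacing_um=(spacing_um,) * 3,
        chamber_shape="prolate_ellipsoid",
        chamber_semi_axes_um=semi,
        wall_sectors=sectors,
        default_wall_thickness_um=600.0,
        seed=seed,
        rotation_deg=rotation_deg,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def infarct_wall_patch_spec(
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.07, 0.156, 0.219),
    band_width_um: float = 400.0,
    depth_um: float = 250.0,
    **overrides,
) -> WallPatchSpec:
    """Wall patch with infarct/border/remote bands (250/400/600 µm).

    Default vessel fractions follow the vehicle-treated infarcted LV:
    about 7 % of tissue volume in the infarct zone, 15.6 % in the border
    zone and 21.9 % in remote myocardium.
    """
    f_inf, f_bor, f_rem = fractions
    bands = [
        WallBand(250.0, band_width_um, f_inf),
        WallBand(400.0, band_width_um, f_bor),
        WallBand(600.0, band_width_um, f_rem),
    ]
    kwargs = dict(bands=bands, depth_um=depth_um, seed=seed)
    kwargs.update(overrides)
    return WallPatchSpec(**kwargs)
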