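"""Volume, mask and mesh I/O with explicit micrometre units.

All in-memory volumes follow a fixed ``(z, y, x)`` axis order with voxel
spacing given in micrometres per axis.  Physical coordinates are voxel
index times spacing (voxel-centre convention).  Volumes are written as
multi-page TIFF with ImageJ-style spacing metadata, or NIfTI-1 (where the
on-disk unit is millimetres, converted to µm on read).  Meshes are written
as binary PLY loadable by standard viewers, optionally carrying a
per-vertex scalar (e.g. mean curvature) in the ``quality`` property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import tifffile
import trimesh


@dataclass
class VolumeImage:
    """A 3D scalar field with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities.  Finite values only.
    spacing_um : tuple of float
        Per-axis voxel spacing ``(dz, dy, dx)`` in micrometres, all > 0.
    channel_name : str
        Free-text channel label, e.g. ``"autofluorescence"`` or ``"lectin"``.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume data must be a non-empty 3D array")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three positive values (z, y, x)")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Best-effort spacing (µm) from ImageJ metadata + resolution tags."""
    meta = tf.imagej_metadata or {}
    dz = meta.get("spacing")
    unit = (meta.get("unit") or "").lower()
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    if dz is None:
        return None
    if unit in ("um", "micron", "micrometer", "µm", "\\u00b5m"):
        scale = 1.0
    elif unit in ("mm", "millimeter"):
        scale = 1000.0
    else:
        # unknown unit: do not guess
        return None
    return (float(dz) * scale, float(dy) * scale, float(dx) * scale)


def read_volume(
    path: str | Path,
    spacing_override_um: Sequence[float] | None = None,
    channel_name: str = "",
) -> VolumeImage:
    """Read a volume from TIFF stack, directory of slices, or NIfTI.

    ``path`` may be a multi-page TIFF, a directory of single-page TIFFs
    (stacked in lexicographic filename order along z), or a NIfTI-1 file.
    Spacing is taken from file metadata when available, else from
    ``spacing_override_um``; an error is raised if neither is available.
    NIfTI zooms are interpreted as millimetres and converted to µm.
    """
    path = Path(path)
    spacing = tuple(float(s) for s in spacing_override_um) if spacing_override_um else None

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1 or slices[0].ndim != 2:
            raise ValueError("slice images have inconsistent shapes")
        data = np.stack(slices, axis=0)
        if spacing is None:
            raise ValueError("voxel spacing unavailable: pass spacing_override_um")
        return VolumeImage(data, spacing, channel_name)

    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError("expected a 3D NIfTI volume")
        # NIfTI is (x, y, z); convert to (z, y, x)
        data = np.ascontiguousarray(data.transpose(2, 1, 0))
        if spacing is None:
            zooms = img.header.get_zooms()[:3]
            if any(z <= 0 for z in zooms):
                raise ValueError("voxel spacing unavailable: pass spacing_override_um")
            spacing = (zooms[2] * 1000.0, zooms[1] * 1000.0, zooms[0] * 1000.0)
        return VolumeImage(data, spacing, channel_name)

    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a 3D TIFF stack, got shape {data.shape}")
        if spacing is None:
            spacing = _spacing_from_tiff(tf)
        if spacing is None:
            raise ValueError("voxel spacing unavailable: pass spacing_override_um")
    return VolumeImage(data, spacing, channel_name)


def write_volume(vol: VolumeImage, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF with ImageJ spacing metadata."""
    path = Path(path)
    data = vol.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    elif data.dtype == bool:
        data = data.astype(np.uint8) * 255
    dz, dy, dx = vol.spacing_um
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    return path


def write_nifti(vol: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with mm voxel sizes (µm / 1000)."""
    path = Path(path)
    dz, dy, dx = vol.spacing_um
    affine = np.diag([dx / 1000.0, dy / 1000.0, dz / 1000.0, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(vol.data.transpose(2, 1, 0)), affine)
    img.header.set_zooms((dx / 1000.0, dy / 1000.0, dz / 1000.0))
    nib.save(img, str(path))
    return path


def write_mask(mask: np.ndarray, spacing_um: Sequence[float], path: str | Path) -> Path:
    """Write a binary mask as 8-bit (0/255) TIFF."""
    return write_volume(
        VolumeImage(np.asarray(mask, bool).astype(np.uint8) * 255, tuple(spacing_um)), path
    )


def read_mask(path: str | Path, spacing_override_um: Sequence[float] | None = None):
    """Read a binary mask (any non-zero voxel is foreground)."""
    vol = read_volume(path, spacing_override_um)
    return vol.data > 0, vol.spacing_um


def write_labels(labels: np.ndarray, spacing_um: Sequence[float], path: str | Path) -> Path:
    """Write a small-integer label volume (e.g. zone partition) as 8-bit TIFF."""
    lab = np.asarray(labels)
    if lab.min() < 0 or lab.max() > 255:
        raise ValueError("labels must fit in uint8")
    return write_volume(VolumeImage(lab.astype(np.uint8), tuple(spacing_um)), path)


def write_mesh(
    mesh: trimesh.Trimesh,
    path: str | Path,
    vertex_scalar: np.ndarray | None = None,
    scalar_name: str = "quality",
) -> Path:
    """Export a surface mesh as binary PLY, optionally with a per-vertex scalar.

    The scalar (e.g. mean curvature) is stored as a float ``quality``
    vertex property, which Meshlab and comparable viewers display directly.
    """
    path = Path(path)
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty (zero-face) mesh")
    out = mesh.copy()
    if vertex_scalar is not None:
        vertex_scalar = np.asarray(vertex_scalar, np.float32)
        if vertex_scalar.shape != (len(out.vertices),):
            raise ValueError("vertex_scalar length must match vertex count")
        out.vertex_attributes[scalar_name] = vertex_scalar
    out.export(str(path), encoding="binary", include_attributes=True)
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a PLY mesh without vertex reordering (attributes preserved).

    Scalar vertex properties beyond x/y/z (e.g. the ``quality`` curvature
    channel) are exposed through ``mesh.vertex_attributes``.
    """
    mesh = trimesh.load(str(path), process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a triangle mesh")
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    if raw is not None and raw.dtype.names:
        for name in raw.dtype.names:
            if name not in ("x", "y", "z") and name not in mesh.vertex_attributes:
                mesh.vertex_attributes[name] = np.asarray(raw[name])
    return mesh


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default))
    return path


def load_json(path: str | Path):
    return json.loads(Path(path).read_text())
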