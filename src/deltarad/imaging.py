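"""Volume and mask containers, file I/O (NRRD / NIfTI-1) and isotropic resampling.

Physical coordinates are in millimetres; the voxel at integer index
``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.  Axial "layers" are
planes of constant third index.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .exceptions import VolumeIOError

__all__ = [
    "ImageVolume",
    "ROIMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_isotropic",
]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values:
        3D array of intensities (any real units).
    spacing_mm:
        Per-axis voxel spacing in millimetres, strictly positive.
    origin_mm:
        Physical coordinate of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing_mm}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest mask aligned voxel-for-voxel with a volume."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values).astype(bool)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={arr.ndim}")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing_mm}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cc(self) -> float:
        """Physical ROI volume in cm^3 (= voxel count x voxel volume)."""
        return self.voxel_count * float(np.prod(self.spacing_mm)) / 1000.0


# ---------------------------------------------------------------------------
# NRRD codec (minimal, raw little-endian encoding).  pynrrd is not a runtime
# dependency; the subset written here round-trips through this module and is
# readable by standard NRRD tools.
# ---------------------------------------------------------------------------

_NRRD_MAGIC = "NRRD0004"


def _write_nrrd(path: Path, values: np.ndarray, spacing, origin) -> None:
    arr = np.ascontiguousarray(values, dtype=np.float64)
    header = [
        _NRRD_MAGIC,
        "type: double",
        f"dimension: {arr.ndim}",
        "sizes: " + " ".join(str(s) for s in arr.shape),
        "spacings: " + " ".join(repr(float(s)) for s in spacing),
        "axis mins: " + " ".join(repr(float(o)) for o in origin),
        "encoding: raw",
        "endian: little",
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(arr.astype("<f8").tobytes(order="C"))


def _read_nrrd(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    with open(path, "rb") as fh:
        blob = fh.read()
    head_end = blob.find(b"\n\n")
    if head_end < 0 or not blob.startswith(_NRRD_MAGIC.encode()):
        raise VolumeIOError(f"{path}: not a NRRD file written by this codec")
    fields: dict[str, str] = {}
    for line in blob[:head_end].decode("ascii").splitlines()[1:]:
        if ":" in line:
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    if fields.get("encoding") != "raw":
        raise VolumeIOError(f"{path}: unsupported NRRD encoding {fields.get('encoding')!r}")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    if "spacings" in fields:
        spacing = tuple(float(s) for s in fields["spacings"].split())
    elif "space directions" in fields:
        # diagonal space directions only: "(sx,0,0) (0,sy,0) (0,0,sz)"
        vecs = fields["space directions"].replace("(", " ").replace(")", " ").split()
        mat = np.array([[float(x) for x in v.split(",")] for v in vecs])
        spacing = tuple(float(np.linalg.norm(row)) for row in mat)
    else:
        raise VolumeIOError(f"{path}: NRRD header has no voxel spacing metadata")
    origin = tuple(float(o) for o in fields.get("axis mins", "0 0 0").split())
    dtype = {"double": "<f8", "float": "<f4"}.get(fields.get("type", "double"))
    if dtype is None:
        raise VolumeIOError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    data = np.frombuffer(blob[head_end + 2 :], dtype=dtype)
    if data.size != int(np.prod(sizes)):
        raise VolumeIOError(f"{path}: NRRD payload size mismatch")
    return data.reshape(sizes).astype(np.float64), spacing, origin


def _nifti_suffix(path: Path) -> bool:
    name = path.name
    return name.endswith(".nii") or name.endswith(".nii.gz")


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as NRRD (``.nrrd``) or NIfTI-1 (``.nii`` / ``.nii.gz``)."""
    path = Path(path)
    if path.suffix == ".nrrd":
        _write_nrrd(path, vol.values, vol.spacing_mm, vol.origin_mm)
    elif _nifti_suffix(path):
        affine = np.diag(list(vol.spacing_mm) + [1.0])
        affine[:3, 3] = vol.origin_mm
        nib.save(nib.Nifti1Image(vol.values.astype(np.float64), affine), str(path))
    else:
        raise VolumeIOError(f"{path}: unknown volume format {path.suffix!r}")


def read_volume(path: str | Path) -> ImageVolume:
    """Read a volume written by :func:`write_volume`.

    Raises
    ------
    VolumeIOError
        If the file does not exist, the format is unknown, or spacing
        metadata is missing (never silently defaulted).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"{path}: no such file")
    if path.suffix == ".nrrd":
        values, spacing, origin = _read_nrrd(path)
        return ImageVolume(values, spacing, origin)
    if _nifti_suffix(path):
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        if any(s <= 0 for s in spacing):
            raise VolumeIOError(f"{path}: NIfTI affine has degenerate spacing")
        origin = tuple(float(x) for x in affine[:3, 3])
        return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)
    raise VolumeIOError(f"{path}: unknown volume format {path.suffix!r}")


def write_mask(mask: ROIMask, path: str | Path) -> None:
    write_volume(ImageVolume(mask.values.astype(np.float64), mask.spacing_mm, mask.origin_mm), path)


def read_mask(path: str | Path) -> ROIMask:
    vol = read_volume(path)
    return ROIMask(vol.values > 0.5, vol.spacing_mm, vol.origin_mm)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_shape(shape, spacing, target: float) -> tuple[int, int, int]:
    return tuple(max(1, int(round(n * s / target))) for n, s in zip(shape, spacing))


def resample_isotropic(
    vol: ImageVolume,
    mask: ROIMask | None = None,
    target_mm: float = 1.0,
) -> tuple[ImageVolume, ROIMask | None]:
    """Resample a volume (trilinear) and its mask (nearest-neighbour) to an
    isotropic grid.

    The output grid shares the input origin; its extent along each axis is
    ``round(n * spacing / target)`` voxels.  A volume already at the target
    spacing is returned unchanged (identity).
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    if mask is not None and mask.shape != vol.shape:
        raise ValueError("mask is not aligned to the volume")
    spacing = vol.spacing_mm
    if all(abs(s - target_mm) < 1e-12 for s in spacing):
        return vol, mask

    out_shape = _target_shape(vol.shape, spacing, target_mm)
    # coordinate of output voxel j along axis a in input index units
    grids = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(out_shape, spacing)],
        indexing="ij",
    )
    coords = np.stack(grids)
    values = ndimage.map_coordinates(vol.values, coords, order=1, mode="nearest")
    out_vol = ImageVolume(values, (target_mm,) * 3, vol.origin_mm)
    out_mask = None
    if mask is not None:
        m = ndimage.map_coordinates(
            mask.values.astype(np.uint8), coords, order=0, mode="constant", cval=0
        )
        out_mask = ROIMask(m > 0, (target_mm,) * 3, vol.origin_mm)
    return out_vol, out_mask
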