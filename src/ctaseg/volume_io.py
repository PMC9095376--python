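"""Volume and mask containers plus readers/writers for medical image formats.

All arrays are indexed ``(z, y, x)``: axis 0 walks axial slices, matching
how a CTA stack is acquired and how the per-slice stages (Hough seeding,
2D cavity filling) operate.  ``spacing`` and ``origin`` follow the same
axis order and are expressed in millimetres.

Supported on-disk formats: NIfTI (``.nii``/``.nii.gz``), MetaImage
(``.mha``/``.mhd``), NRRD (``.nrrd``) — all via SimpleITK — and bare
NumPy arrays (``.npy``), which carry no spacing metadata and default to
1 mm isotropic with a logged warning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

#: file extension -> canonical format token
_EXTENSIONS = {
    ".nii": "nifti",
    ".nii.gz": "nifti",
    ".mha": "metaimage",
    ".mhd": "metaimage",
    ".nrrd": "nrrd",
    ".npy": "npy-raw",
}

SITK_FORMATS = ("nifti", "metaimage", "nrrd")


class VolumeFormatError(ValueError):
    """Raised when a file's header and payload disagree or the format is unknown."""


@dataclass
class Volume:
    """A 3D scalar field with physical voxel geometry.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units, e.g. HU), indexed (z, y, x).
    spacing:
        Per-axis voxel size in mm, (z, y, x) order, all positive.
    origin:
        Physical offset of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all extents must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite (no NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_physical(self, index: tuple[float, float, float]) -> np.ndarray:
        """Physical position (mm) of a 0-based voxel index."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)


@dataclass
class BinaryMask:
    """A 0/1 labelling of a volume's voxels (1 = foreground / vessel)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        values = np.unique(self.data)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0 or 1, found {values[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())


def _infer_format(path: str) -> str:
    lower = path.lower()
    if lower.endswith(".nii.gz"):
        return "nifti"
    ext = os.path.splitext(lower)[1]
    try:
        return _EXTENSIONS[ext]
    except KeyError:
        raise VolumeFormatError(
            f"cannot infer format from '{path}'; supported: {sorted(set(_EXTENSIONS.values()))}"
        ) from None


def _read_sitk(path: str) -> tuple[np.ndarray, tuple, tuple]:
    try:
        image = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise IOError(f"failed to read '{path}': {exc}") from exc
    data = sitk.GetArrayFromImage(image)  # already (z, y, x)
    if data.ndim == 2:  # single-slice files come back 2D
        data = data[np.newaxis]
    # SimpleITK reports spacing/origin in (x, y, z); reverse to (z, y, x).
    spacing = tuple(reversed(image.GetSpacing()))
    origin = tuple(reversed(image.GetOrigin()))
    return data, spacing, origin


def _write_sitk(data: np.ndarray, spacing, origin, path: str) -> None:
    image = sitk.GetImageFromArray(data)
    image.SetSpacing(tuple(float(s) for s in reversed(spacing)))
    image.SetOrigin(tuple(float(o) for o in reversed(origin)))
    try:
        sitk.WriteImage(image, path)
    except RuntimeError as exc:
        raise IOError(f"failed to write '{path}': {exc}") from exc


def read_volume(path: str, format: str | None = None) -> Volume:
    """Read a 3D volume from disk.

    ``format`` is one of ``nifti``, ``metaimage``, ``nrrd``, ``npy-raw``;
    when omitted it is inferred from the file extension.  Files without
    spacing metadata (``npy-raw``) default to 1 mm isotropic spacing and
    log a warning.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: '{path}'")
    fmt = format or _infer_format(path)
    if fmt == "npy-raw":
        try:
            data = np.load(path)
        except Exception as exc:
            raise IOError(f"failed to read '{path}': {exc}") from exc
        logger.warning("'%s' carries no spacing metadata; defaulting to 1 mm isotropic", path)
        spacing, origin = (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)
    elif fmt in SITK_FORMATS:
        data, spacing, origin = _read_sitk(path)
    else:
        raise VolumeFormatError(f"unknown format '{fmt}'")
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise VolumeFormatError(f"'{path}' contains non-finite intensities")
    return Volume(data=data, spacing=spacing, origin=origin)


def read_mask(path: str, format: str | None = None) -> BinaryMask:
    """Read a binary mask; values must be exactly 0 or 1."""
    volume = read_volume(path, format=format)
    return BinaryMask(data=volume.data, spacing=volume.spacing, origin=volume.origin)


def write_volume(volume: Volume, path: str, format: str | None = None) -> None:
    """Write a volume to disk (NIfTI / MetaImage / NRRD, or .npy without metadata)."""
    fmt = format or _infer_format(path)
    if fmt == "npy-raw":
        np.save(path, volume.data)
    elif fmt in SITK_FORMATS:
        _write_sitk(volume.data, volume.spacing, volume.origin, path)
    else:
        raise VolumeFormatError(f"unknown format '{fmt}'")


def write_mask(mask: BinaryMask, path: str, format: str | None = None) -> None:
    """Write a binary mask to disk; validates the 0/1 invariant before writing."""
    if not isinstance(mask, BinaryMask):
        mask = BinaryMask(data=mask.data, spacing=mask.spacing, origin=mask.origin)
    fmt = format or _infer_format(path)
    if fmt == "npy-raw":
        np.save(path, mask.data)
        return
    if fmt not in SITK_FORMATS:
        raise VolumeFormatError(f"unknown format '{fmt}'")
    _write_sitk(mask.data.astype(np.uint8), mask.spacing, mask.origin, path)
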