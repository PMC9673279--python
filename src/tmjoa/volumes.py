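"""Volume containers, NRRD/NIfTI round-trip I/O and VOI cropping.

Conventions used throughout the package: voxel indexing is 0-based with
axis order (x, y, z) as stored in the numpy array; spacing is isotropic
and expressed in millimetres per voxel.  Volumes of interest (VOIs) are
exact 30x30x30 sub-grid copies -- no resampling and no zero-padding, so
texture statistics are computed on untouched intensities.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

#: Side length (voxels) of a volume of interest.
VOI_SIDE = 30


class AnisotropicSpacingError(ValueError):
    """Raised when a volume does not have equal spacing on all axes."""


@dataclass
class GreyVolume:
    """A 3D greyscale grid with isotropic voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        HU-like intensities.
    spacing : float
        Millimetres per voxel, identical on every axis.
    origin : tuple of float
        Physical position (mm) of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    volume_id: str = "volume"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxel values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class MaskVolume:
    """A binary segmentation grid aligned with a :class:`GreyVolume`."""

    voxels: np.ndarray
    spacing: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    volume_id: str = "mask"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        uniq = np.unique(self.voxels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class VOIBlock:
    """A 30x30x30 sub-volume with provenance back to its parent volume."""

    voxels: np.ndarray
    spacing: float = 1.0
    parent_id: str = "volume"
    corner: tuple[int, int, int] = (0, 0, 0)
    region_label: str = "condyle"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != (VOI_SIDE, VOI_SIDE, VOI_SIDE):
            raise ValueError(
                f"a VOI must be {VOI_SIDE}^3 voxels, got shape {self.voxels.shape}"
            )


def _sitk_to_arrays(img: sitk.Image) -> tuple[np.ndarray, float, tuple]:
    spacing = img.GetSpacing()
    if not np.allclose(spacing, spacing[0], rtol=1e-6, atol=1e-9):
        raise AnisotropicSpacingError(
            f"anisotropic spacing {spacing}: this pipeline assumes isotropic "
            "voxels and refuses to resample implicitly"
        )
    # SimpleITK returns (z, y, x); transpose to the package's (x, y, z).
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, float(spacing[0]), tuple(img.GetOrigin())


def read_volume(path: str | os.PathLike, fmt: str | None = None) -> GreyVolume:
    """Read an NRRD or NIfTI volume from disk.

    The format is inferred from the file extension unless ``fmt`` is one of
    ``{"nrrd", "nifti"}``.  Anisotropic files raise
    :class:`AnisotropicSpacingError` rather than being silently resampled.
    """
    path = os.fspath(path)
    if fmt is not None:
        suffixes = {"nrrd": (".nrrd",), "nifti": (".nii", ".nii.gz")}
        if fmt not in suffixes:
            raise ValueError(f"unknown format {fmt!r}; expected 'nrrd' or 'nifti'")
        if not path.endswith(suffixes[fmt]):
            raise ValueError(f"file {path!r} does not look like {fmt}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # pragma: no cover - ITK wraps parse errors
        raise IOError(f"could not parse volume file {path!r}: {exc}") from exc
    arr, spacing, origin = _sitk_to_arrays(img)
    return GreyVolume(
        voxels=arr,
        spacing=spacing,
        origin=origin,
        volume_id=os.path.splitext(os.path.basename(path))[0],
    )


def read_mask(path: str | os.PathLike) -> MaskVolume:
    """Read a binary segmentation mask (NRRD or NIfTI)."""
    vol = read_volume(path)
    return MaskVolume(
        voxels=(vol.voxels > 0).astype(np.uint8),
        spacing=vol.spacing,
        origin=vol.origin,
        volume_id=vol.volume_id,
    )


def write_volume(vol: GreyVolume | MaskVolume, path: str | os.PathLike) -> None:
    """Write a volume as NRRD (``.nrrd``) or NIfTI (``.nii``/``.nii.gz``)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing((vol.spacing,) * 3)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, os.fspath(path))


def crop_voi(
    vol: GreyVolume,
    center: tuple[int, int, int],
    region_label: str = "condyle",
) -> VOIBlock:
    """Crop a 30x30x30 VOI centred on a voxel index.

    The block spans ``center - 15 .. center + 15`` (exclusive) on each axis
    and must fit entirely inside the volume; out-of-bounds requests raise
    IndexError instead of zero-padding, because padded voxels would corrupt
    the texture statistics computed downstream.
    """
    half = VOI_SIDE // 2
    corner = tuple(int(c) - half for c in center)
    for ax, (lo, n) in enumerate(zip(corner, vol.shape)):
        if lo < 0 or lo + VOI_SIDE > n:
            raise IndexError(
                f"VOI at center {tuple(center)} exceeds volume bounds on axis "
                f"{ax} (extent {lo}..{lo + VOI_SIDE} vs size {n})"
            )
    x0, y0, z0 = corner
    block = vol.voxels[x0 : x0 + VOI_SIDE, y0 : y0 + VOI_SIDE, z0 : z0 + VOI_SIDE]
    return VOIBlock(
        voxels=block.copy(),
        spacing=vol.spacing,
        parent_id=vol.volume_id,
        corner=corner,
        region_label=region_label,
    )
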