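"""CT volume container and file I/O.

A :class:`CTVolume` is a 3-D array of Hounsfield units plus the voxel
spacing (mm per axis) and, when known, the acquisition settings that
produced it.  Volumes are read and written as NIfTI through nibabel;
DICOM series are read through pydicom with the rescale slope/intercept
applied so the in-memory array is always in HU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["CTVolume", "load_volume", "save_volume", "VolumeIOError"]


class VolumeIOError(ValueError):
    """Raised for unreadable files or missing geometry metadata."""


@dataclass
class CTVolume:
    """3-D CT image in Hounsfield units.

    Parameters
    ----------
    data:
        3-D array of HU values.
    spacing:
        Voxel spacing in mm per axis, same axis order as ``data``.
    mAs, kVp:
        Acquisition settings, if known.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    mAs: float | None = None
    kVp: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"voxel spacing must be 3 positive values, got {self.spacing}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def load_volume(path: str | os.PathLike) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    HU values and voxel spacing are preserved exactly on a
    save/load round-trip of NIfTI files.  For DICOM, the per-file
    rescale slope and intercept are applied so stored values come back
    in HU.  Missing spacing metadata raises :class:`VolumeIOError`
    rather than silently assuming a default.
    """
    path = Path(path)
    if path.is_dir():
        return _load_dicom_series(path)
    return _load_nifti(path)


def save_volume(vol: CTVolume, path: str | os.PathLike, dtype=None) -> None:
    """Write a volume as NIfTI with voxel spacing in the header."""
    import nibabel as nib

    data = vol.data if dtype is None else np.asarray(vol.data, dtype=dtype)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


def _load_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(os.fspath(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeIOError(f"cannot read {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeIOError(f"{path}: voxel spacing metadata missing or invalid ({zooms})")
    return CTVolume(data=data, spacing=tuple(float(z) for z in zooms))


def _load_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(os.fspath(f))
        except Exception:
            continue
        if hasattr(ds, "pixel_array") or "PixelData" in ds:
            datasets.append(ds)
    if not datasets:
        raise VolumeIOError(f"{directory}: no readable DICOM slices found")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    first = datasets[0]
    pixel_spacing = getattr(first, "PixelSpacing", None)
    if pixel_spacing is None:
        raise VolumeIOError(f"{directory}: PixelSpacing missing; refusing to assume a default")
    row_mm, col_mm = float(pixel_spacing[0]), float(pixel_spacing[1])

    if len(datasets) > 1 and all(hasattr(d, "ImagePositionPatient") for d in datasets):
        zs = [float(d.ImagePositionPatient[2]) for d in datasets]
        slice_mm = float(np.median(np.diff(zs)))
        slice_mm = abs(slice_mm)
    else:
        slice_mm = getattr(first, "SpacingBetweenSlices", None) or getattr(first, "SliceThickness", None)
        if slice_mm is None:
            raise VolumeIOError(f"{directory}: slice spacing metadata missing")
        slice_mm = float(slice_mm)
    if slice_mm <= 0 or row_mm <= 0 or col_mm <= 0:
        raise VolumeIOError(f"{directory}: non-positive voxel spacing")

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    data = np.stack(slices, axis=-1)  # (rows, cols, n_slices)

    kvp = getattr(first, "KVP", None)
    mas = getattr(first, "Exposure", None)
    return CTVolume(
        data=data,
        spacing=(row_mm, col_mm, slice_mm),
        mAs=float(mas) if mas is not None else None,
        kVp=float(kvp) if kvp is not None else None,
    )
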