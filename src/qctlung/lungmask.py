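"""Automatic lung segmentation for high-contrast volumes, plus mask I/O.

Healthy aerated lung is hundreds of HU darker than every surrounding
structure, so a density threshold, removal of exterior air (components
touching the volume border), a minimum-volume filter and a morphological
clean-up recover the lung fields reliably at any of the studied noise
levels.  Consolidated (ARDS) lung approaches soft-tissue density and is
invisible to a threshold: the function then returns only the aerated
remnant and emits :class:`ConsolidationWarning`, signalling that a
manually drawn mask should be supplied instead.  Manual masks are
consumed as NIfTI files aligned to the CT grid; no drawing UI exists.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "LungMask",
    "segment_lungs_auto",
    "load_mask",
    "save_mask",
    "NoLungFoundError",
    "ConsolidationWarning",
]


class NoLungFoundError(ValueError):
    """No connected component survived the segmentation filters."""


class ConsolidationWarning(UserWarning):
    """The segmented region looks consolidated; a manual mask is advisable."""


@dataclass
class LungMask:
    """Binary lung region aligned to a CT volume."""

    mask: np.ndarray
    source: str  # "auto" | "manual"
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def volume_ml(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.voxel_spacing)) / 1000.0

    def validate_against(self, ct: CTVolume) -> None:
        if self.mask.shape != ct.data.shape:
            raise ValueError(f"mask shape {self.mask.shape} != volume shape {ct.data.shape}")
        if not np.allclose(self.voxel_spacing, ct.spacing, rtol=1e-4):
            raise ValueError(f"mask spacing {self.voxel_spacing} != volume spacing {ct.spacing}")


def _border_labels(labels: np.ndarray) -> set[int]:
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1]]
    out: set[int] = set()
    for f in faces:
        out.update(np.unique(f).tolist())
    out.discard(0)
    return out


def segment_lungs_auto(
    ct: CTVolume,
    threshold_hu: float = -200.0,
    min_volume_ml: float = 100.0,
    closing_iterations: int = 2,
    dense_warn_fraction: float = 0.25,
) -> LungMask:
    """Threshold-based lung segmentation for high-contrast volumes.

    Steps: keep voxels below ``threshold_hu``; drop connected components
    touching the volume border (exterior air); drop components smaller
    than ``min_volume_ml``; binary closing and hole filling.  Raises
    :class:`NoLungFoundError` when nothing survives.

    A :class:`ConsolidationWarning` is emitted when more than
    ``dense_warn_fraction`` of the segmented voxels are denser than
    -500 HU: that density profile means a large poorly/nonaerated load,
    i.e. the threshold has likely missed consolidated tissue and a
    manual mask is required.
    """
    data = np.asarray(ct.data, dtype=float)
    candidate = data < threshold_hu

    labels, n = ndimage.label(candidate)
    if n == 0:
        raise NoLungFoundError("no voxels below the lung threshold")

    drop = _border_labels(labels)
    sizes = ndimage.sum_labels(np.ones_like(labels, dtype=np.int64), labels, index=np.arange(1, n + 1))
    min_voxels = min_volume_ml * 1000.0 / float(np.prod(ct.spacing))
    keep = [i + 1 for i in range(n) if (i + 1) not in drop and sizes[i] >= min_voxels]
    if not keep:
        raise NoLungFoundError("no lung found: every component touched the border or was too small")

    mask = np.isin(labels, keep)
    if closing_iterations > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_closing(mask, structure=structure, iterations=closing_iterations)
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise NoLungFoundError("no lung found after morphological clean-up")

    dense_fraction = float((data[mask] > -500.0).mean())
    if dense_fraction > dense_warn_fraction:
        warnings.warn(
            f"{dense_fraction:.0%} of the segmented lung is denser than -500 HU; "
            "the region looks consolidated and a manually drawn mask is recommended",
            ConsolidationWarning,
            stacklevel=2,
        )

    return LungMask(mask=mask, source="auto", voxel_spacing=ct.spacing)


def load_mask(path: str | os.PathLike, reference: CTVolume | None = None, source: str = "manual") -> LungMask:
    """Read a uint8 NIfTI mask, optionally validating it against a CT volume."""
    from .volume import load_volume

    vol = load_volume(path)
    mask = LungMask(mask=vol.data > 0, source=source, voxel_spacing=vol.spacing)
    if reference is not None:
        mask.validate_against(reference)
    return mask


def save_mask(mask: LungMask, path: str | os.PathLike) -> None:
    from .volume import CTVolume as _V
    from .volume import save_volume

    save_volume(_V(mask.mask.astype(np.uint8), mask.voxel_spacing), path, dtype=np.uint8)
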