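"""Quantitative CT lung densitometry.

Per-scan analysis of a lung region of interest: total gas+tissue volume,
tissue mass, the four-compartment decomposition by aeration
(hyperinflated, normally aerated, poorly aerated, nonaerated), and the
mass-frequency histogram in 50-HU intervals.

The physics convention is the standard densitometric one: a voxel at
0 HU is water-equivalent tissue (1 g/ml), a voxel at -1000 HU is pure
gas (zero mass), and in between the tissue fraction varies linearly,
``(HU + 1000)/1000``.  Tissue mass is therefore
``voxel volume [ml] x (HU + 1000)/1000 [g/ml]``.  Voxels denser than the
exclusion bound (+200 HU by default) are not part of any compartment;
they are tallied separately because pushing nonaerated tissue past that
bound is exactly how image noise erodes measured lung volume and mass at
very low dose.  Voxels below -1000 HU are clamped to -1000 (zero mass).

Compartment membership is decided on the HU value rounded to the nearest
integer (half away from zero), matching thresholds printed as integer
bounds such as "-900 to -501".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import CTVolume

__all__ = [
    "CompartmentScheme",
    "QCTResult",
    "HistogramResult",
    "tissue_fraction",
    "quantify",
    "histogram_50hu",
    "default_scheme",
    "COMPARTMENT_NAMES",
]

COMPARTMENT_NAMES = (
    "hyperinflated",
    "normally_aerated",
    "poorly_aerated",
    "nonaerated",
)

CLAMP_FLOOR_HU = -1000
DEFAULT_EXCLUSION_HU = 200


@dataclass(frozen=True)
class CompartmentScheme:
    """Contiguous integer-HU compartments covering [clamp floor, exclusion bound].

    The default intervals are the usual aeration thresholds:
    hyperinflated [-1000, -901], normally aerated [-900, -501],
    poorly aerated [-500, -101], nonaerated [-100, +200].  The exclusion
    bound can be raised (e.g. to +500) to keep dense voxels in the
    nonaerated compartment instead of discarding them.
    """

    intervals: tuple[tuple[str, int, int], ...]
    exclusion_hu: int = DEFAULT_EXCLUSION_HU
    clamp_floor_hu: int = CLAMP_FLOOR_HU

    def __post_init__(self) -> None:
        lo_expected = self.clamp_floor_hu
        for name, lo, hi in self.intervals:
            if lo != lo_expected:
                raise ValueError(
                    f"compartment intervals must be contiguous; '{name}' starts at {lo}, expected {lo_expected}"
                )
            if hi < lo:
                raise ValueError(f"compartment '{name}' has empty interval [{lo}, {hi}]")
            lo_expected = hi + 1
        if self.intervals[-1][2] != self.exclusion_hu:
            raise ValueError(
                f"compartments must cover up to the exclusion bound {self.exclusion_hu}; "
                f"last interval ends at {self.intervals[-1][2]}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.intervals)

    def interval(self, name: str) -> tuple[int, int]:
        for n, lo, hi in self.intervals:
            if n == name:
                return lo, hi
        raise KeyError(name)


def default_scheme(exclusion_hu: int = DEFAULT_EXCLUSION_HU) -> CompartmentScheme:
    """The four-compartment aeration scheme (optionally raised exclusion bound)."""
    if exclusion_hu < 200:
        raise ValueError("exclusion bound below +200 HU would truncate the nonaerated compartment")
    return CompartmentScheme(
        intervals=(
            ("hyperinflated", -1000, -901),
            ("normally_aerated", -900, -501),
            ("poorly_aerated", -500, -101),
            ("nonaerated", -100, exclusion_hu),
        ),
        exclusion_hu=exclusion_hu,
    )


@dataclass
class QCTResult:
    """Quantitative result for one scan / mask pair.

    Fractions are percentages of total in-compartment tissue mass.  When
    every voxel is excluded the fractions are undefined
    (``fractions_defined`` is False and the values are NaN).
    """

    total_volume_ml: float
    total_mass_g: float
    compartment_mass_g: dict[str, float]
    compartment_fraction_pct: dict[str, float]
    excluded_mass_g: float
    excluded_voxels: int
    n_voxels: int
    voxel_volume_ml: float
    fractions_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "total_volume_ml": self.total_volume_ml,
            "total_mass_g": self.total_mass_g,
            "compartment_mass_g": dict(self.compartment_mass_g),
            "compartment_fraction_pct": dict(self.compartment_fraction_pct),
            "excluded_mass_g": self.excluded_mass_g,
            "excluded_voxels": self.excluded_voxels,
            "n_voxels": self.n_voxels,
            "voxel_volume_ml": self.voxel_volume_ml,
            "fractions_defined": self.fractions_defined,
        }


@dataclass
class HistogramResult:
    """Mass-frequency distribution over 50-HU bins.

    ``bin_edges`` has 25 entries (-1000, -950, ..., +200); bin ``k``
    collects rounded HU in ``[edges[k], edges[k+1] - 1]`` (the last bin
    is closed at +200).  ``mass_fraction_pct`` sums to 100 whenever any
    mass is included.
    """

    bin_edges: np.ndarray
    mass_fraction_pct: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass_fraction_pct = np.asarray(self.mass_fraction_pct, dtype=float)
        if len(self.bin_edges) != len(self.mass_fraction_pct) + 1:
            raise ValueError("bin_edges must have one more entry than mass_fraction_pct")


def tissue_fraction(hu, floor: float = CLAMP_FLOOR_HU, ceiling: float = DEFAULT_EXCLUSION_HU):
    """Fraction of a voxel's volume occupied by tissue-density material.

    ``(clamp(HU, -1000, +200) + 1000) / 1000`` -- 0 at pure gas, 1 at
    water, up to 1.2 at the exclusion bound.  The gas fraction is
    ``1 - tissue_fraction`` for HU <= 0.
    """
    hu = np.asarray(hu, dtype=float)
    out = (np.clip(hu, floor, ceiling) + 1000.0) / 1000.0
    return out if out.ndim else float(out)


def _round_half_away(hu: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (so -100.5 -> -101)."""
    return np.copysign(np.floor(np.abs(hu) + 0.5), hu)


def _masked_values(ct: CTVolume, mask) -> np.ndarray:
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if mask_arr.shape != ct.data.shape:
        raise ValueError(f"mask shape {mask_arr.shape} does not match volume shape {ct.data.shape}")
    if not mask_arr.any():
        raise ValueError("mask is empty")
    return np.asarray(ct.data, dtype=float)[mask_arr]


def quantify(ct: CTVolume, mask, scheme: CompartmentScheme | None = None) -> QCTResult:
    """Compute volume, tissue mass and compartment decomposition inside a mask.

    Voxels whose rounded HU exceeds the exclusion bound contribute only
    to the excluded tally; total volume counts the remaining voxels.
    """
    scheme = scheme or default_scheme()
    hu = _masked_values(ct, mask)
    vox_ml = ct.voxel_volume_ml
    n_voxels = hu.size

    rhu = _round_half_away(hu)
    excluded = rhu > scheme.exclusion_hu
    n_excluded = int(excluded.sum())

    mass = vox_ml * tissue_fraction(hu, scheme.clamp_floor_hu, scheme.exclusion_hu)
    excluded_mass = float(mass[excluded].sum())

    included = ~excluded
    rhu_in = np.clip(rhu[included], scheme.clamp_floor_hu, scheme.exclusion_hu)
    mass_in = mass[included]

    bounds = np.array([hi for _, _, hi in scheme.intervals], dtype=float)
    comp_idx = np.searchsorted(bounds, rhu_in, side="left")
    comp_mass = {
        name: float(mass_in[comp_idx == i].sum()) for i, name in enumerate(scheme.names)
    }
    total_mass = float(mass_in.sum())
    total_volume = (n_voxels - n_excluded) * vox_ml

    if total_mass > 0:
        fractions = {k: 100.0 * v / total_mass for k, v in comp_mass.items()}
        defined = True
    else:
        fractions = {k: float("nan") for k in comp_mass}
        defined = False

    return QCTResult(
        total_volume_ml=total_volume,
        total_mass_g=total_mass,
        compartment_mass_g=comp_mass,
        compartment_fraction_pct=fractions,
        excluded_mass_g=excluded_mass,
        excluded_voxels=n_excluded,
        n_voxels=n_voxels,
        voxel_volume_ml=vox_ml,
        fractions_defined=defined,
    )


def histogram_50hu(ct: CTVolume, mask, scheme: CompartmentScheme | None = None) -> HistogramResult:
    """Mass-weighted HU histogram in 24 bins of 50 HU from -1000 to +200.

    Bin edges are aligned with the compartment boundaries.  Voxels above
    the exclusion bound are dropped; voxels below -1000 are clamped into
    the first bin.  Fractions are percentages of included tissue mass.
    """
    scheme = scheme or default_scheme()
    hu = _masked_values(ct, mask)
    vox_ml = ct.voxel_volume_ml

    rhu = _round_half_away(hu)
    included = rhu <= scheme.exclusion_hu
    hu_in = hu[included]
    rhu_in = np.clip(rhu[included], CLAMP_FLOOR_HU, DEFAULT_EXCLUSION_HU)
    mass = vox_ml * tissue_fraction(hu_in, scheme.clamp_floor_hu, scheme.exclusion_hu)

    edges = np.arange(CLAMP_FLOOR_HU, DEFAULT_EXCLUSION_HU + 1, 50, dtype=float)  # 25 edges
    n_bins = len(edges) - 1
    idx = np.clip(((rhu_in - CLAMP_FLOOR_HU) // 50).astype(int), 0, n_bins - 1)
    bin_mass = np.bincount(idx, weights=mass, minlength=n_bins)

    total = bin_mass.sum()
    if total > 0:
        fractions = 100.0 * bin_mass / total
    else:
        fractions = np.full(n_bins, np.nan)
    return HistogramResult(bin_edges=edges, mass_fraction_pct=fractions)
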