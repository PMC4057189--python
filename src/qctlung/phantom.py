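"""Digital chest phantoms and mAs-dependent scan simulation.

The phantom is the study's stand-in for a sheep thorax: an elliptic body
shell of soft tissue, two ellipsoidal lung fields whose voxel HU values
realise a prescribed mass composition over the four aeration
compartments, and a uniform cylindrical aorta insert used as the noise
ROI.  Two conditions are modelled:

* ``healthy`` -- mostly normally aerated tissue, compartments mixed
  uniformly in space;
* ``ARDS`` -- predominantly nonaerated tissue, consolidated
  preferentially along the gravity axis (dependent regions densest),
  with a sigmoid-like transition produced by logistic jitter on the
  gravity coordinate.

Scan simulation adds zero-mean Gaussian noise whose standard deviation
follows the tube-current law sigma(mAs) = sqrt(a/mAs + b) -- quantum
noise plus an electronic floor -- or, when the model carries a lookup of
measured (mAs, sigma) points, those measured values take precedence.
Reconstruction-filter correlation is not modelled beyond an optional
isotropic Gaussian smoothing of the noise field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls

from .qct import COMPARTMENT_NAMES, CompartmentScheme, default_scheme, quantify
from .volume import CTVolume

__all__ = [
    "PhantomSpec",
    "Phantom",
    "NoiseModel",
    "AcquisitionSettings",
    "make_phantom",
    "simulate_scan",
    "noise_sigma",
    "fit_noise_model",
    "perturb_spec",
    "HEALTHY_MASS_FRACTIONS",
    "ARDS_MASS_FRACTIONS",
    "REFERENCE_NOISE_HU",
    "PhantomError",
]


class PhantomError(ValueError):
    """Raised for infeasible phantom specifications."""


def _normalized(fractions: dict[str, float]) -> dict[str, float]:
    total = sum(fractions.values())
    return {k: 100.0 * v / total for k, v in fractions.items()}


#: Default mass composition of the healthy (baseline) arm, % of tissue mass.
#: Printed study means renormalised to sum exactly to 100.
HEALTHY_MASS_FRACTIONS: dict[str, float] = _normalized(
    {
        "hyperinflated": 0.6,
        "normally_aerated": 86.6,
        "poorly_aerated": 11.5,
        "nonaerated": 1.4,
    }
)

#: Default mass composition of the oleic-acid ARDS arm, % of tissue mass.
ARDS_MASS_FRACTIONS: dict[str, float] = _normalized(
    {
        "hyperinflated": 0.0,
        "normally_aerated": 9.1,
        "poorly_aerated": 27.3,
        "nonaerated": 63.5,
    }
)

#: Measured image noise (HU) per tube current-time product (mAs): the
#: mean SD of HU in a uniform aortic ROI at each acquisition setting.
REFERENCE_NOISE_HU: dict[float, float] = {140.0: 10.0, 60.0: 15.9, 15.0: 37.5, 7.5: 73.8}

#: Default HU mean per compartment for phantom truth volumes.  The
#: nonaerated mean sits at +50 HU so that heavy noise can push part of
#: that mass past the +200 HU exclusion bound, reproducing the
#: volume-underestimation mechanism seen at ultra-low dose.
DEFAULT_HU_MEANS: dict[str, float] = {
    "hyperinflated": -950.0,
    "normally_aerated": -700.0,
    "poorly_aerated": -300.0,
    "nonaerated": 50.0,
}

#: Half-width of the symmetric uniform HU band each compartment's voxels
#: are spread over.  Bands stay >= 50 HU clear of compartment boundaries
#: so that moderate noise (sigma <= ~40 HU) produces essentially no
#: cross-compartment leakage, while sigma ~ 74 HU does -- the printed
#: dose-agreement pattern.
DEFAULT_HU_HALF_WIDTHS: dict[str, float] = {
    "hyperinflated": 30.0,
    "normally_aerated": 150.0,
    "poorly_aerated": 150.0,
    "nonaerated": 50.0,
}


@dataclass(frozen=True)
class AcquisitionSettings:
    """CT acquisition parameters; defaults follow the study protocol
    (120 kVp, 0.5 s rotation, 32 x 0.5 mm collimation, pitch 0.85,
    5 mm reconstructed slices, 0.625 mm pixels)."""

    mAs: float
    kVp: float = 120.0
    pitch: float = 0.85
    n_detector_rows: int = 32
    collimation_mm: float = 0.5
    rotation_time_s: float = 0.5
    slice_width_mm: float = 5.0
    pixel_size_mm: float = 0.625

    def __post_init__(self) -> None:
        if self.mAs <= 0:
            raise ValueError(f"mAs must be positive, got {self.mAs}")


@dataclass(frozen=True)
class NoiseModel:
    """Image-noise law sigma(mAs) = sqrt(a/mAs + b).

    ``a`` (HU^2 * mAs) is the quantum-noise coefficient, ``b`` (HU^2) an
    electronic floor.  When ``lookup`` holds measured (mAs -> sigma)
    points, those take precedence over the parametric law at matching
    mAs; the law interpolates/extrapolates elsewhere.
    """

    a: float
    b: float
    lookup: dict[float, float] | None = None

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError(f"noise coefficients must be non-negative (a={self.a}, b={self.b})")

    @classmethod
    def from_table(cls, table: dict[float, float] | None = None) -> "NoiseModel":
        """Model backed by a measured lookup table (defaults to the
        reference study measurements), with the parametric law fitted to
        the same points for off-table mAs."""
        table = dict(table or REFERENCE_NOISE_HU)
        fitted, _ = fit_noise_model(list(table.items()), keep_lookup=False)
        return cls(a=fitted.a, b=fitted.b, lookup=table)

    def law_sigma(self, mAs: float) -> float:
        """Parametric sigma, ignoring any lookup table."""
        if mAs <= 0:
            raise ValueError(f"mAs must be positive, got {mAs}")
        return math.sqrt(self.a / mAs + self.b)

    def sigma(self, mAs: float) -> float:
        if mAs <= 0:
            raise ValueError(f"mAs must be positive, got {mAs}")
        if self.lookup:
            for m, s in self.lookup.items():
                if math.isclose(m, mAs, rel_tol=1e-9, abs_tol=1e-12):
                    return float(s)
        return self.law_sigma(mAs)


def noise_sigma(mAs: float, noise: NoiseModel) -> float:
    """Image-noise SD (HU) at a given mAs: lookup value if tabulated,
    else the parametric quantum + floor law."""
    return noise.sigma(mAs)


def fit_noise_model(
    observations, keep_lookup: bool = True
) -> tuple[NoiseModel, np.ndarray]:
    """Least-squares calibration of sigma^2 = a/mAs + b with a, b >= 0.

    Parameters
    ----------
    observations:
        Iterable of ``(mAs, sigma)`` pairs; at least two distinct mAs.
    keep_lookup:
        Keep the observations as an exact lookup on the returned model
        (they are the calibration measurements, so matching queries
        return them verbatim).  Set False for the pure parametric law.

    Returns
    -------
    (model, residuals):
        residuals are ``sigma_observed - law_sigma(mAs)`` per point.
    """
    obs = [(float(m), float(s)) for m, s in observations]
    if len(obs) < 2:
        raise ValueError("need at least two (mAs, sigma) observations")
    mas = np.array([m for m, _ in obs])
    sig = np.array([s for _, s in obs])
    if np.any(mas <= 0):
        raise ValueError("mAs values must be positive")
    if np.any(sig < 0):
        raise ValueError("sigma values must be non-negative")
    if np.unique(mas).size < 2:
        raise ValueError("observations must span at least two distinct mAs values")

    design = np.column_stack([1.0 / mas, np.ones_like(mas)])
    coef, _ = nnls(design, sig**2)
    model = NoiseModel(a=float(coef[0]), b=float(coef[1]), lookup=dict(obs) if keep_lookup else None)
    residuals = sig - np.sqrt(coef[0] / mas + coef[1])
    return model, residuals


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a ground-truth chest phantom.

    ``target_fractions`` are mass percentages per compartment and must
    sum to 100.  ``gravity_axis`` selects the axis along which ARDS
    consolidation accumulates (higher index = dependent).  Geometry
    fields are in voxel units of the grid; they shape the thorax but do
    not affect any contracted quantity.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 64)
    voxel_spacing: tuple[float, float, float] = (3.0, 3.0, 5.0)
    condition: str = "healthy"
    target_fractions: dict[str, float] = field(default_factory=lambda: dict(HEALTHY_MASS_FRACTIONS))
    compartment_hu_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    compartment_hu_half_widths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HU_HALF_WIDTHS)
    )
    gravity_axis: int = 1
    aorta_hu: float = 45.0
    body_hu: float = 40.0
    seed: int = 0
    # geometry (voxel units, relative to grid centre)
    lung_semiaxes: tuple[float, float, float] = (17.0, 29.0, 16.0)
    lung_offset: float = 26.0
    body_semiaxes: tuple[float, float] = (58.0, 48.0)
    aorta_radius: float = 8.0
    aorta_offset: float = 20.0
    consolidation_transition_mm: float = 15.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise PhantomError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing) or len(self.voxel_spacing) != 3:
            raise PhantomError(f"voxel_spacing must be 3 positive values, got {self.voxel_spacing}")
        if self.condition not in ("healthy", "ARDS"):
            raise PhantomError(f"condition must be 'healthy' or 'ARDS', got {self.condition!r}")
        if self.gravity_axis not in (0, 1, 2):
            raise PhantomError(f"gravity_axis must be 0, 1 or 2, got {self.gravity_axis}")
        total = sum(self.target_fractions.get(n, 0.0) for n in COMPARTMENT_NAMES)
        if abs(total - 100.0) > 1e-9:
            raise PhantomError(f"target_fractions must sum to 100, got {total}")
        if any(v < 0 for v in self.target_fractions.values()):
            raise PhantomError("target_fractions must be non-negative")
        scheme = default_scheme()
        for name in COMPARTMENT_NAMES:
            target = self.target_fractions.get(name, 0.0)
            mean = self.compartment_hu_means[name]
            half = self.compartment_hu_half_widths.get(name, 0.0)
            lo, hi = scheme.interval(name)
            if target > 0 and (mean - half < lo or mean + half > hi):
                raise PhantomError(
                    f"compartment '{name}': HU band [{mean - half}, {mean + half}] "
                    f"not contained in its interval [{lo}, {hi}]"
                )

    def hu_band(self, name: str) -> tuple[float, float]:
        mean = self.compartment_hu_means[name]
        half = self.compartment_hu_half_widths.get(name, 0.0)
        return mean - half, mean + half


@dataclass
class Phantom:
    """Noise-free ground truth: HU volume, lung and aorta masks, and the
    quantitative result computed on the truth volume."""

    truth_volume: CTVolume
    lung_mask: np.ndarray
    aorta_mask: np.ndarray
    true_result: "object"
    spec: PhantomSpec


def _compartment_counts(n: int, fractions: dict[str, float], densities: dict[str, float]) -> dict[str, int]:
    """Voxel counts realising target *mass* fractions.

    Mass per voxel scales with compartment density rho = (HU+1000)/1000,
    so the voxel-number share of compartment c is proportional to
    f_c / rho_c.  Largest-remainder rounding; positive targets get at
    least one voxel.
    """
    weights = {}
    for name in COMPARTMENT_NAMES:
        f = fractions.get(name, 0.0)
        if f > 0 and densities[name] <= 0:
            raise PhantomError(f"compartment '{name}' has target mass but zero density")
        weights[name] = f / densities[name] if f > 0 else 0.0
    total_w = sum(weights.values())
    if total_w <= 0:
        raise PhantomError("no compartment has positive target mass")
    exact = {k: n * w / total_w for k, w in weights.items()}
    counts = {k: int(math.floor(v)) for k, v in exact.items()}
    for k, f in fractions.items():
        if f > 0 and counts.get(k, 0) == 0:
            counts[k] = 1
    remainder = n - sum(counts.values())
    order = sorted(exact, key=lambda k: exact[k] - math.floor(exact[k]), reverse=True)
    i = 0
    while remainder != 0:
        k = order[i % len(order)]
        step = 1 if remainder > 0 else -1
        if step < 0 and (counts[k] <= 1 and fractions.get(k, 0) > 0):
            i += 1
            continue
        counts[k] += step
        remainder -= step
        i += 1
    return counts


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build a deterministic (seeded) ground-truth phantom.

    The noise-free quantitative fractions match ``spec.target_fractions``
    to well within 0.5 percentage points; ARDS phantoms consolidate
    along the gravity axis with a sigmoid-like transition.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    xi, yi, zi = np.meshgrid(
        np.arange(nx) - (nx - 1) / 2.0,
        np.arange(ny) - (ny - 1) / 2.0,
        np.arange(nz) - (nz - 1) / 2.0,
        indexing="ij",
    )

    bx, by = spec.body_semiaxes
    body = (xi / bx) ** 2 + (yi / by) ** 2 <= 1.0

    ax, ay, az = spec.lung_semiaxes
    lungs = np.zeros(spec.grid_shape, dtype=bool)
    for side in (-1.0, 1.0):
        lungs |= ((xi - side * spec.lung_offset) / ax) ** 2 + (yi / ay) ** 2 + (zi / az) ** 2 <= 1.0
    lungs &= body

    aorta = (xi**2 + (yi - spec.aorta_offset) ** 2) <= spec.aorta_radius**2
    aorta &= body
    lungs &= ~aorta  # aorta wins where the cylinder grazes a lung field

    if not lungs.any():
        raise PhantomError("phantom geometry produced an empty lung field")
    if aorta.sum() < 2:
        raise PhantomError("aorta insert too small")

    truth = np.full(spec.grid_shape, -1000.0, dtype=np.float32)
    truth[body] = spec.body_hu
    truth[aorta] = spec.aorta_hu

    densities = {n: (spec.compartment_hu_means[n] + 1000.0) / 1000.0 for n in COMPARTMENT_NAMES}
    n_lung = int(lungs.sum())
    counts = _compartment_counts(n_lung, spec.target_fractions, densities)

    # Spatial assignment: sort lung voxels by a gravity score and hand
    # out compartments from least to most dependent.
    coords = (xi[lungs], yi[lungs], zi[lungs])
    gravity = coords[spec.gravity_axis] * spec.voxel_spacing[spec.gravity_axis]
    if spec.condition == "ARDS":
        score = gravity + rng.logistic(0.0, spec.consolidation_transition_mm, size=n_lung)
    else:
        score = rng.random(n_lung)
    order = np.argsort(score, kind="stable")

    values = np.empty(n_lung, dtype=np.float32)
    start = 0
    for name in COMPARTMENT_NAMES:  # aeration order: least dense first
        c = counts.get(name, 0)
        if c == 0:
            continue
        lo, hi = spec.hu_band(name)
        band = np.linspace(lo, hi, c, dtype=np.float64) if c > 1 else np.array([(lo + hi) / 2.0])
        values[order[start : start + c]] = rng.permutation(band).astype(np.float32)
        start += c

    truth[lungs] = values

    vol = CTVolume(data=truth, spacing=spec.voxel_spacing)
    result = quantify(vol, lungs)
    for name in COMPARTMENT_NAMES:
        target = spec.target_fractions.get(name, 0.0)
        got = result.compartment_fraction_pct[name]
        if abs(got - target) > 0.5:
            raise PhantomError(
                f"phantom composition infeasible: '{name}' realised {got:.3f}% vs target {target:.3f}%"
            )
    return Phantom(truth_volume=vol, lung_mask=lungs, aorta_mask=aorta, true_result=result, spec=spec)


def perturb_spec(
    base: PhantomSpec,
    rng: np.random.Generator,
    fraction_sd: dict[str, float] | None = None,
    size_cv: float = 0.1,
) -> PhantomSpec:
    """Sample one subject's spec around a condition's base spec.

    Compartment targets are jittered with the given per-compartment SDs
    (percentage points), clipped at zero and renormalised to 100; lung
    semi-axes are scaled by a common factor with coefficient of
    variation ``size_cv`` (volume CV ~ 3x that).  This is the
    between-animal variability the paired study needs for meaningful
    regression and limits-of-agreement estimates.
    """
    fractions = dict(base.target_fractions)
    if fraction_sd:
        for name in COMPARTMENT_NAMES:
            sd = fraction_sd.get(name, 0.0)
            if sd > 0:
                fractions[name] = max(0.0, fractions.get(name, 0.0) + sd * rng.standard_normal())
        total = sum(fractions.values())
        if total <= 0:
            fractions = dict(base.target_fractions)
        else:
            fractions = {k: 100.0 * v / total for k, v in fractions.items()}
    scale = float(np.clip(1.0 + size_cv * rng.standard_normal(), 0.7, 1.3))
    semiaxes = tuple(s * scale for s in base.lung_semiaxes)
    seed = int(rng.integers(0, 2**31 - 1))
    return replace(base, target_fractions=fractions, lung_semiaxes=semiaxes, seed=seed)


def simulate_scan(
    phantom: Phantom,
    acq: AcquisitionSettings,
    noise: NoiseModel,
    seed: int,
    smooth_fwhm_mm: float = 0.0,
) -> CTVolume:
    """Simulate a scan at ``acq.mAs``: truth + i.i.d. Gaussian HU noise.

    Noise SD is ``noise.sigma(acq.mAs)`` and is applied everywhere
    (lung, body, aorta).  ``smooth_fwhm_mm`` optionally smooths the
    noise field isotropically (rescaled to preserve the target SD) to
    mimic reconstruction-filter correlation.
    """
    sigma = noise.sigma(acq.mAs)
    truth = phantom.truth_volume.data
    if sigma == 0:
        data = truth.copy()
    else:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, sigma, size=truth.shape)
        if smooth_fwhm_mm > 0:
            sig_vox = [smooth_fwhm_mm / 2.355 / s for s in phantom.truth_volume.spacing]
            eps = ndimage.gaussian_filter(eps, sig_vox)
            sd = eps.std()
            if sd > 0:
                eps *= sigma / sd
        data = truth + eps
    return CTVolume(
        data=data,
        spacing=phantom.truth_volume.spacing,
        mAs=acq.mAs,
        kVp=acq.kVp,
    )
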