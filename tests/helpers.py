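"""Independent oracles and small utilities shared across tests.

The oracles here deliberately avoid the package's own code paths: the
convolution oracle integrates the mass-weighted Gaussian analytically
with scipy.stats.norm, and the Bland-Altman oracle recomputes every
statistic from raw differences with plain numpy.
"""

import numpy as np
from scipy.stats import norm

from qctlung import CTVolume
from qctlung.phantom import DEFAULT_HU_HALF_WIDTHS, DEFAULT_HU_MEANS
from qctlung.qct import COMPARTMENT_NAMES


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def composition_truth_values(mass_fractions, n_total):
    """HU truth values (1-D) realising a compartment mass composition,
    using the phantom's default per-compartment uniform bands."""
    dens = {k: (DEFAULT_HU_MEANS[k] + 1000.0) / 1000.0 for k in COMPARTMENT_NAMES}
    weights = {k: mass_fractions[k] / dens[k] for k in COMPARTMENT_NAMES if mass_fractions.get(k, 0) > 0}
    total = sum(weights.values())
    chunks = []
    for k, w in weights.items():
        n = int(round(n_total * w / total))
        lo = DEFAULT_HU_MEANS[k] - DEFAULT_HU_HALF_WIDTHS[k]
        hi = DEFAULT_HU_MEANS[k] + DEFAULT_HU_HALF_WIDTHS[k]
        chunks.append(np.linspace(lo, hi, n))
    return np.concatenate(chunks)


def values_as_volume(values, fill_hu=300.0):
    """Pack 1-D HU values into a cubic CTVolume plus a mask selecting them."""
    n = values.size
    side = int(np.ceil(n ** (1.0 / 3.0)))
    arr = np.full(side**3, fill_hu)
    arr[:n] = values
    mask = np.zeros(side**3, bool)
    mask[:n] = True
    return CTVolume(arr.reshape(side, side, side), (1.0, 1.0, 1.0)), mask.reshape(side, side, side)


def expected_noisy_histogram(truth_values, sigma, chunk=200_000):
    """Analytic expectation of the mass-weighted 50-HU histogram of
    truth + N(0, sigma^2) noise, as percentages of included mass.

    Integer-rounded binning means bin k >= 1 collects real HU in
    [lo_k - 0.5, lo_k + 49.5); bin 0 additionally absorbs everything
    below (clamped, zero mass below -1000); the last bin is closed at
    the +200.5 rounding boundary with the mass weight capped at 1.2.
    """
    edges = np.concatenate([[-1000.0], np.arange(-950.5, 150.0, 50.0), [200.0, 200.5]])
    n_seg = len(edges) - 1  # 25 segments; the last two both belong to bin 23
    seg_sum = np.zeros(n_seg)
    cap_sum = 0.0
    for start in range(0, truth_values.size, chunk):
        t = truth_values[start : start + chunk, None]
        a = (edges[None, :] - t) / sigma
        Phi = norm.cdf(a)
        phi = norm.pdf(a)
        seg = ((t + 1000.0) * (Phi[:, 1:] - Phi[:, :-1]) + sigma * (phi[:, :-1] - phi[:, 1:])) / 1000.0
        seg_sum += seg.sum(axis=0)
        cap_sum += 1.2 * (Phi[:, -1] - Phi[:, -2]).sum()
    bins = np.empty(24)
    bins[:23] = seg_sum[:23]
    bins[23] = seg_sum[23] + cap_sum
    return 100.0 * bins / bins.sum()


def bland_altman_oracle(ref, alt):
    """Brute-force Bland-Altman statistics from raw differences."""
    ref = np.asarray(ref, float)
    alt = np.asarray(alt, float)
    d = ref - alt
    bias = d.mean()
    sd = np.sqrt(((d - bias) ** 2).sum() / (len(d) - 1))
    return {"bias": bias, "sd": sd, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}
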