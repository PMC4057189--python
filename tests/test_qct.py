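"""Quantitative core: tissue fraction, compartment masses, histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from qctlung import (
    AcquisitionSettings,
    CTVolume,
    NoiseModel,
    default_scheme,
    histogram_50hu,
    quantify,
    simulate_scan,
    tissue_fraction,
)


def uniform_volume(hu, n=1000, spacing=(1.0, 1.0, 1.0)):
    side = int(round(n ** (1 / 3)))
    data = np.full((side, side, side), float(hu))
    return CTVolume(data, spacing), np.ones_like(data, bool)


class TestTissueFraction:
    @pytest.mark.parametrize(
        "hu,expected",
        [(-1000, 0.0), (0, 1.0), (-300, 0.7), (200, 1.2), (300, 1.2), (-1500, 0.0)],
    )
    def test_linear_with_clamping(self, hu, expected):
        assert tissue_fraction(hu) == pytest.approx(expected)

    def test_gas_fraction_complement(self):
        hu = np.array([-1000.0, -500.0, 0.0])
        assert np.allclose(1.0 - tissue_fraction(hu), [1.0, 0.5, 0.0])


class TestQuantify:
    def test_uniform_volume_closed_form(self):
        """512,000 voxels at -300 HU with 0.625 x 0.625 x 5 mm voxels:
        1000 ml, 700 g, all poorly aerated."""
        data = np.full((80, 80, 80), -300.0)
        ct = CTVolume(data, (0.625, 0.625, 5.0))
        res = quantify(ct, np.ones_like(data, bool))
        assert res.total_volume_ml == pytest.approx(1000.0)
        assert res.total_mass_g == pytest.approx(700.0)
        assert res.compartment_fraction_pct["poorly_aerated"] == pytest.approx(100.0)

    def test_two_value_mass_weighting(self):
        """Half the mask at -700, half at -50: mass weights 0.30 vs 0.95,
        so nonaerated = 0.95/1.25 = 76%."""
        data = np.full((10, 10, 10), -700.0)
        data[:5] = -50.0
        ct = CTVolume(data, (1.0, 1.0, 1.0))
        res = quantify(ct, np.ones_like(data, bool))
        assert res.compartment_fraction_pct["nonaerated"] == pytest.approx(76.0)
        assert res.compartment_fraction_pct["normally_aerated"] == pytest.approx(24.0)

    def test_all_excluded(self):
        ct, mask = uniform_volume(300.0)
        res = quantify(ct, mask)
        assert res.total_volume_ml == 0.0
        assert res.total_mass_g == 0.0
        assert res.excluded_voxels == res.n_voxels
        assert not res.fractions_defined
        assert np.isnan(res.compartment_fraction_pct["nonaerated"])

    def test_volume_counts_only_included_voxels(self):
        data = np.full((10, 10, 10), -300.0)
        data[0] = 500.0  # 100 excluded voxels
        ct = CTVolume(data, (1.0, 1.0, 1.0))
        res = quantify(ct, np.ones_like(data, bool))
        assert res.excluded_voxels == 100
        assert res.total_volume_ml == pytest.approx((1000 - 100) * ct.voxel_volume_ml)

    @pytest.mark.parametrize(
        "hu,compartment",
        [
            (-900.4, "normally_aerated"),
            (-900.6, "hyperinflated"),
            (-100.5, "poorly_aerated"),  # ties round away from zero
            (-100.4, "nonaerated"),
            (200.4, "nonaerated"),
        ],
    )
    def test_boundary_rounding(self, hu, compartment):
        ct, mask = uniform_volume(hu, n=27)
        res = quantify(ct, mask)
        assert res.compartment_fraction_pct[compartment] == pytest.approx(100.0)

    def test_exclusion_boundary_rounding(self):
        ct, mask = uniform_volume(200.6, n=27)
        res = quantify(ct, mask)
        assert res.excluded_voxels == res.n_voxels

    def test_raised_exclusion_bound_keeps_dense_tissue(self):
        ct, mask = uniform_volume(300.0)
        res = quantify(ct, mask, default_scheme(exclusion_hu=500))
        assert res.excluded_voxels == 0
        assert res.compartment_fraction_pct["nonaerated"] == pytest.approx(100.0)

    def test_shape_mismatch_rejected(self):
        ct, _ = uniform_volume(-300.0)
        with pytest.raises(ValueError):
            quantify(ct, np.ones((2, 2, 2), bool))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hu=hnp.arrays(np.float64, 64, elements=st.floats(-1400, 600)),
        scale=st.floats(0.5, 4.0),
    )
    def test_mass_conservation_and_scale_invariance(self, hu, scale):
        """Compartment + excluded mass equals the unexcluded total
        exactly, and fractions do not depend on voxel volume."""
        data = hu.reshape(4, 4, 4)
        ct = CTVolume(data, (1.0, 1.0, 1.0))
        mask = np.ones_like(data, bool)
        res = quantify(ct, mask)

        vox = ct.voxel_volume_ml
        total_unexcluded = vox * ((np.clip(hu, -1000, 200) + 1000) / 1000).sum()
        recomposed = sum(res.compartment_mass_g.values()) + res.excluded_mass_g
        assert recomposed == pytest.approx(total_unexcluded, rel=1e-12, abs=1e-12)

        scaled = quantify(CTVolume(data, (scale, scale, scale)), mask)
        if res.fractions_defined:
            for name, frac in res.compartment_fraction_pct.items():
                assert scaled.compartment_fraction_pct[name] == pytest.approx(frac, rel=1e-9)


class TestHistogram:
    def test_uniform_single_bin(self):
        ct, mask = uniform_volume(-300.0)
        h = histogram_50hu(ct, mask)
        idx = list(h.bin_edges[:-1]).index(-300.0)
        assert h.mass_fraction_pct[idx] == pytest.approx(100.0)
        assert h.mass_fraction_pct.sum() == pytest.approx(100.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hu=hnp.arrays(np.float64, 64, elements=st.floats(-1400, 195)))
    def test_normalization(self, hu):
        ct = CTVolume(hu.reshape(4, 4, 4), (1.0, 1.0, 1.0))
        h = histogram_50hu(ct, np.ones((4, 4, 4), bool))
        assert len(h.mass_fraction_pct) == 24
        assert h.mass_fraction_pct.sum() == pytest.approx(100.0)
        assert (h.mass_fraction_pct >= 0).all()

    def test_subfloor_values_clamped_into_first_bin(self):
        data = np.full((4, 4, 4), -1005.0)
        data[0, 0, 0] = -300.0  # the only voxel carrying mass
        ct = CTVolume(data, (1.0, 1.0, 1.0))
        h = histogram_50hu(ct, np.ones((4, 4, 4), bool))
        # clamped voxels have zero mass: all mass ends up at -300
        idx = list(h.bin_edges[:-1]).index(-300.0)
        assert h.mass_fraction_pct[idx] == pytest.approx(100.0)


class TestNoiseShiftSignatures:
    """Directional compartment shifts under increasing image noise."""

    def test_ards_poorly_gains_nonaerated_loses(self, ards_phantom):
        fr = {}
        for sigma in (15.9, 73.8):
            scan = simulate_scan(
                ards_phantom, AcquisitionSettings(mAs=60), NoiseModel(sigma**2 * 60, 0.0), seed=31
            )
            fr[sigma] = quantify(scan, ards_phantom.lung_mask).compartment_fraction_pct
        assert fr[73.8]["poorly_aerated"] > fr[15.9]["poorly_aerated"]
        assert fr[73.8]["nonaerated"] < fr[15.9]["nonaerated"]

    def test_healthy_hyperinflated_gains(self, healthy_phantom):
        fr = {}
        for sigma in (15.9, 73.8):
            scan = simulate_scan(
                healthy_phantom, AcquisitionSettings(mAs=60), NoiseModel(sigma**2 * 60, 0.0), seed=32
            )
            fr[sigma] = quantify(scan, healthy_phantom.lung_mask).compartment_fraction_pct
        assert fr[73.8]["hyperinflated"] > fr[15.9]["hyperinflated"]

    def test_ards_volume_nonincreasing_in_noise(self, ards_phantom):
        volumes = []
        for sigma in (0.0, 15.9, 37.5, 73.8):
            scan = simulate_scan(
                ards_phantom, AcquisitionSettings(mAs=60), NoiseModel(sigma**2 * 60, 0.0), seed=33
            )
            volumes.append(quantify(scan, ards_phantom.lung_mask).total_volume_ml)
        assert all(b <= a for a, b in zip(volumes, volumes[1:]))
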