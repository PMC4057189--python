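"""Bland-Altman, paired tests, agreement tables, ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qctlung import (
    PairedSeries,
    StudyArm,
    StudyConfig,
    bland_altman,
    compare_histograms,
    compare_pairs,
    group_anova,
    paired_test,
    run_paired_study,
)
from qctlung.agreement import MEASURE_LABELS

from helpers import bland_altman_oracle


def series(ref, alt, name="x"):
    return PairedSeries(name=name, unit="", values_ref=np.asarray(ref, float), values_alt=np.asarray(alt, float))


class TestBlandAltman:
    def test_identical_series_degenerate(self):
        res = bland_altman(series([1, 2, 3], [1, 2, 3]))
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert res.degenerate

    def test_hand_computed_example(self):
        res = bland_altman(series([10, 12, 14], [9, 10, 11]))
        assert res.bias == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(0.04)
        assert res.loa_high == pytest.approx(3.96)

    def test_midpoint_identity(self):
        rng = np.random.default_rng(5)
        res = bland_altman(series(rng.normal(50, 10, 20), rng.normal(48, 10, 20)))
        assert res.bias == pytest.approx((res.loa_low + res.loa_high) / 2.0, rel=1e-12)
        assert res.loa_low <= res.bias <= res.loa_high

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)), min_size=3, max_size=40
        )
    )
    def test_oracle_equivalence(self, data):
        ref = [r for r, _ in data]
        alt = [a for _, a in data]
        res = bland_altman(series(ref, alt))
        oracle = bland_altman_oracle(ref, alt)
        assert res.bias == pytest.approx(oracle["bias"], abs=1e-9)
        assert res.sd_diff == pytest.approx(oracle["sd"], abs=1e-9)
        assert res.loa_low == pytest.approx(oracle["loa_low"], abs=1e-9)
        assert res.loa_high == pytest.approx(oracle["loa_high"], abs=1e-9)

    def test_bias_antisymmetry(self):
        rng = np.random.default_rng(6)
        ref, alt = rng.normal(0, 5, 15), rng.normal(1, 5, 15)
        fwd = bland_altman(series(ref, alt))
        rev = bland_altman(series(alt, ref))
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.loa_low == pytest.approx(-fwd.loa_high)
        assert rev.loa_high == pytest.approx(-fwd.loa_low)

    def test_units_invariance(self):
        rng = np.random.default_rng(7)
        ref, alt = rng.normal(10, 2, 12), rng.normal(11, 2, 12)
        base = bland_altman(series(ref, alt))
        scaled = bland_altman(series(ref * 3.5, alt * 3.5))
        assert scaled.bias == pytest.approx(3.5 * base.bias)
        assert scaled.loa_high == pytest.approx(3.5 * base.loa_high)
        assert scaled.prop_slope == pytest.approx(base.prop_slope)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            series([1.0], [1.0])


class TestPairedTest:
    def test_all_zero_differences_flagged(self):
        res = paired_test(series([1, 2, 3, 4], [1, 2, 3, 4]))
        assert res.p == 1.0
        assert res.degenerate

    def test_t_branch_matches_closed_form(self):
        """One-sample t on the differences, computed from the textbook
        formula t = mean / (sd / sqrt(n))."""
        diffs = np.array([1, 2, 3, 2, 1, 2, 3, 2, 1, 2], float)
        res = paired_test(series(diffs, np.zeros_like(diffs)), alpha_normality=0.01)
        assert res.test_name == "paired t-test"
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        p_expected = 2.0 * stats.t.sf(abs(t), len(diffs) - 1)
        assert res.p == pytest.approx(p_expected, rel=1e-9)

    def test_skewed_differences_take_signed_rank_branch(self):
        diffs = np.array([0.1, 0.2, 0.1, 0.15, 0.1, 0.2, 0.1, 8.0, 9.0, 10.0])
        res = paired_test(series(diffs, np.zeros_like(diffs)))
        assert res.test_name == "Wilcoxon signed-rank"


@pytest.fixture(scope="module")
def healthy_140_report():
    config = StudyConfig(arms=[StudyArm("healthy", 20, 140.0)], seed=77)
    return run_paired_study(config)


class TestCompareTables:
    def test_agreement_table_layout(self, healthy_140_report):
        table = healthy_140_report.agreement_tables[("healthy", 140.0)]
        assert list(table.index) == list(MEASURE_LABELS.values())
        assert list(table.columns) == [
            "mean_ref", "sd_ref", "mean_alt", "sd_alt", "p", "r2", "bias", "loa_low", "loa_high",
        ]

    def test_healthy_high_dose_biases_below_one_point(self, healthy_140_report):
        """20 simulated healthy pairs at the 60/140-mAs noise levels:
        every compartment-fraction bias below 1 percentage point."""
        table = healthy_140_report.agreement_tables[("healthy", 140.0)]
        fractions = [v for v in MEASURE_LABELS.values() if v.endswith("(%)")]
        assert table.loc[fractions, "bias"].abs().max() < 1.0

    def test_identical_pairs_all_zero(self, healthy_140_report, ards_phantom):
        from qctlung import quantify

        res = quantify(ards_phantom.truth_volume, ards_phantom.lung_mask)
        table = compare_pairs([(res, res)] * 4)
        assert (table["bias"] == 0).all()
        assert (table["p"] == 1.0).all()

    def test_mismatched_schemas_rejected(self, ards_phantom):
        from qctlung import quantify

        res = quantify(ards_phantom.truth_volume, ards_phantom.lung_mask)
        import copy

        broken = copy.deepcopy(res)
        broken.compartment_fraction_pct = {"only_one": 100.0}
        with pytest.raises(ValueError):
            compare_pairs([(res, res), (res, broken)])


@pytest.fixture(scope="module")
def hist_pairs(ards_phantom, noise_model):
    from qctlung import AcquisitionSettings, histogram_50hu, simulate_scan

    pairs = []
    for i in range(6):
        ref = simulate_scan(ards_phantom, AcquisitionSettings(mAs=60), noise_model, seed=500 + i)
        alt = simulate_scan(ards_phantom, AcquisitionSettings(mAs=7.5), noise_model, seed=600 + i)
        pairs.append(
            (histogram_50hu(ref, ards_phantom.lung_mask), histogram_50hu(alt, ards_phantom.lung_mask))
        )
    return pairs


class TestCompareHistograms:
    def test_identical_pairs_no_flags(self, hist_pairs):
        same = [(r, r) for r, _ in hist_pairs]
        table = compare_histograms(same)
        assert not table["significant"].any()

    def test_label_swap_symmetry(self, hist_pairs):
        fwd = compare_histograms(hist_pairs)
        rev = compare_histograms([(a, r) for r, a in hist_pairs])
        assert np.allclose(rev["mean_diff"], -fwd["mean_diff"])
        assert np.allclose(rev["p"], fwd["p"], rtol=1e-9)

    def test_low_dose_changes_concentrate_at_dense_boundary(self, hist_pairs):
        """Ultra-low-dose noise redistributes nonaerated mass: the bins
        flanking the nonaerated/poorly-aerated boundary are flagged and
        the largest mean shift sits in the dense part of the histogram."""
        table = compare_histograms(hist_pairs)
        boundary_bins = table.loc[[-150.0, -100.0, 0.0, 50.0], "significant"]
        assert boundary_bins.all()
        assert -200.0 <= table["mean_diff"].abs().idxmax() <= 100.0

    def test_mismatched_edges_rejected(self, hist_pairs):
        import copy

        broken = copy.deepcopy(hist_pairs)
        broken[0][1].bin_edges[:] = broken[0][1].bin_edges + 10
        with pytest.raises(ValueError):
            compare_histograms(broken)


class TestGroupAnova:
    def test_identical_constant_groups(self):
        res = group_anova([[5.0, 5.0, 5.0], [5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        res = group_anova([g1, g2])
        t = stats.ttest_ind(g1, g2)
        assert not res.rank_transformed
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-9)

    def test_noise_levels_always_separable(self):
        """Groups drawn at the four studied noise means/SDs (n=10) give
        p < 0.001 in >= 95% of 200 replicates."""
        means = [10.0, 15.9, 37.5, 73.8]
        sds = [1.1, 3.5, 10.6, 17.5]
        rng = np.random.default_rng(9)
        hits = sum(
            group_anova([rng.normal(m, s, 10) for m, s in zip(means, sds)]).p < 1e-3
            for _ in range(200)
        )
        assert hits >= 190

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_anova([[1.0, 2.0]])
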