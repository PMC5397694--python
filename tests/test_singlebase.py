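import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hydroxycall import sim, singlebase
from hydroxycall.io import GenomicInterval
from hydroxycall.singlebase import (
    call_hmc,
    classify_hydroxymethylated_region,
    delta_density_summary,
    power_two_proportion,
    region_average_hmc,
    two_proportion_test,
)

from conftest import make_calls_frame


def reference_prop_test(x1, n1, x2, n2, correction=True):
    """Independent 2x2 chi-square-with-correction computation (brute force)."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    delta = x1 / n1 - x2 / n2
    yates = min(0.5, abs(delta) / (1 / n1 + 1 / n2)) if correction else 0.0
    if (expected == 0).any():
        return delta, 1.0
    stat = (((np.abs(table - expected) - yates) ** 2) / expected).sum()
    return delta, float(stats.chi2.sf(stat, 1))


class TestTwoProportionTest:
    # expected p-values frozen from R 4.3.3 prop.test (two-sided, Yates)
    @pytest.mark.parametrize(
        "x1,n1,x2,n2,expect_p",
        [
            (10, 10, 0, 10, 5.69941162333185e-05),
            (9, 10, 1, 10, 0.0017451186995289),
            (15, 20, 5, 18, 0.00972014339559023),
            (50, 60, 30, 60, 0.0002338436799708),
            (8, 10, 8, 10, 1.0),
        ],
    )
    def test_matches_r_prop_test(self, x1, n1, x2, n2, expect_p):
        delta, p = two_proportion_test(x1, n1, x2, n2)
        assert delta == pytest.approx(x1 / n1 - x2 / n2)
        assert p == pytest.approx(expect_p, rel=1e-9)

    def test_identical_proportions_give_p_one(self):
        delta, p = two_proportion_test(8, 10, 8, 10)
        assert delta == 0 and p == 1.0

    def test_extreme_separation_significant(self):
        delta, p = two_proportion_test(10, 10, 0, 10)
        assert delta == 1.0 and p < 0.001
        # cross-check direction with Fisher's exact test
        assert stats.fisher_exact([[10, 0], [0, 10]])[1] < 0.001

    def test_agrees_with_brute_force_for_all_small_tables(self):
        """Oracle equivalence on every 2x2 table with N <= 15 per arm."""
        for n1 in range(1, 16):
            for n2 in range(1, 16):
                x1 = np.repeat(np.arange(n1 + 1), n2 + 1)
                x2 = np.tile(np.arange(n2 + 1), n1 + 1)
                delta, p = two_proportion_test(
                    x1, np.full_like(x1, n1), x2, np.full_like(x2, n2)
                )
                for k in range(len(x1)):
                    d_ref, p_ref = reference_prop_test(x1[k], n1, x2[k], n2)
                    assert delta[k] == pytest.approx(d_ref, abs=1e-12)
                    assert p[k] == pytest.approx(p_ref, abs=1e-10)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(0, 0, 1, 10)


class TestCallHmc:
    def _tables(self, rows):
        bis = pd.DataFrame(
            [(c, p, nb_nc, nb) for c, p, nb_nc, nb, *_ in rows],
            columns=["chrom", "pos", "NC", "N"],
        )
        ox = pd.DataFrame(
            [(c, p, no_nc, no) for c, p, _, _, no_nc, no in rows],
            columns=["chrom", "pos", "NC", "N"],
        )
        return bis, ox

    def test_low_coverage_in_either_arm_excluded(self):
        bis, ox = self._tables(
            [("chr1", 10, 8, 9, 5, 50), ("chr1", 20, 10, 12, 5, 12)]
        )
        calls = call_hmc(bis, ox, min_cov=10)
        assert calls["pos"].tolist() == [20]

    def test_negative_delta_never_significant(self):
        bis, ox = self._tables([("chr1", 10, 2, 20, 18, 20)])
        calls = call_hmc(bis, ox)
        assert not calls["significant"].iloc[0]
        assert calls["p_value"].iloc[0] < 0.05  # tested significant two-sided...
        assert calls["delta"].iloc[0] < 0  # ...but on the wrong side

    def test_empty_intersection_warns(self, caplog):
        bis = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "NC": [5], "N": [20]})
        ox = pd.DataFrame({"chrom": ["chr2"], "pos": [1], "NC": [5], "N": [20]})
        calls = call_hmc(bis, ox)
        assert calls.empty

    def test_type_one_error_controlled_under_null(self, null_truth):
        bis, oxbis = sim.simulate_bisoxbis_counts(null_truth, 30, seed=31)
        calls = call_hmc(bis, oxbis)
        assert len(calls) > 3000
        # one-sided delta>0 condition halves the nominal two-sided rate
        assert calls["significant"].mean() <= 0.05


class TestRegionAverage:
    def test_rule_forced_example(self):
        calls = make_calls_frame([0.30, 0.05], [0.01, 0.2], positions=[10, 20])
        res = region_average_hmc(calls, [GenomicInterval("chrS", 0, 100)])
        assert res["avg_hmc"].iloc[0] == pytest.approx(0.15)

    def test_all_discarded_region_undefined(self):
        calls = make_calls_frame([0.15, -0.02], [0.2, 0.5], positions=[10, 20])
        res = region_average_hmc(calls, [GenomicInterval("chrS", 0, 100)])
        assert not res["defined"].iloc[0]
        assert np.isnan(res["avg_hmc"].iloc[0])

    def test_boundary_delta_imputes_to_zero(self):
        calls = make_calls_frame([0.10], [0.5], positions=[10])
        res = region_average_hmc(calls, [GenomicInterval("chrS", 0, 100)])
        assert res["avg_hmc"].iloc[0] == 0.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(77)
        n = 400
        calls = make_calls_frame(
            rng.uniform(-0.3, 0.5, n), rng.uniform(0, 1, n),
            positions=np.sort(rng.choice(10_000, n, replace=False)),
        )
        regions = []
        for _ in range(100):
            s = int(rng.integers(0, 9_000))
            regions.append(GenomicInterval("chrS", s, s + int(rng.integers(50, 1500))))
        res = region_average_hmc(calls, regions)
        for k, iv in enumerate(regions):
            vals = []
            for _, row in calls.iterrows():
                if not (iv.start <= row["pos"] < iv.end):
                    continue
                if row["significant"]:
                    vals.append(row["delta"])
                elif row["delta"] < 0:
                    continue
                elif row["delta"] > 0.10:
                    continue
                else:
                    vals.append(0.0)
            if vals:
                assert res["avg_hmc"].iloc[k] == pytest.approx(np.mean(vals))
            else:
                assert not res["defined"].iloc[k]


class TestRegionClassification:
    def test_at_least_one_significant_cpg(self):
        calls = make_calls_frame([0.3, 0.02], [0.01, 0.9], positions=[10, 20])
        regions = [GenomicInterval("chrS", 0, 15), GenomicInterval("chrS", 15, 30)]
        got = classify_hydroxymethylated_region(calls, regions)
        assert got.tolist() == [True, False]

    def test_min_sig_parameter(self):
        calls = make_calls_frame([0.3], [0.01], positions=[10])
        region = [GenomicInterval("chrS", 0, 15)]
        assert classify_hydroxymethylated_region(calls, region, min_sig=2).tolist() == [False]


class TestPower:
    def test_null_case_returns_alpha(self):
        assert power_two_proportion(0.5, 0.5, 100) == 0.05

    def test_extreme_separation(self):
        assert power_two_proportion(0.9, 0.1, 100) > 0.999

    # frozen from R 4.3.3 power.prop.test
    @pytest.mark.parametrize(
        "p1,p2,n,expect",
        [
            (0.8, 0.7, 60, 0.242046886774767),
            (0.5, 0.3, 25, 0.298854130686759),
        ],
    )
    def test_matches_r_power_prop_test(self, p1, p2, n, expect):
        assert power_two_proportion(p1, p2, n) == pytest.approx(expect, rel=1e-9)

    def test_matches_monte_carlo_rejection_rate(self):
        # the normal-approximation power corresponds to the uncorrected
        # chi-square test; the Yates-corrected variant is more conservative
        p1, p2, n, alpha = 0.8, 0.7, 60, 0.05
        rng = np.random.default_rng(5)
        reps = 10_000
        x1 = rng.binomial(n, p1, reps)
        x2 = rng.binomial(n, p2, reps)
        _, p = two_proportion_test(
            x1, np.full(reps, n), x2, np.full(reps, n), correction=False
        )
        mc = (p < alpha).mean()
        assert power_two_proportion(p1, p2, n, alpha) == pytest.approx(mc, abs=0.02)


class TestDeltaSummary:
    def test_null_distribution_centred_at_zero(self, null_truth):
        bis, oxbis = sim.simulate_bisoxbis_counts(null_truth, 30, seed=41)
        calls = call_hmc(bis, oxbis)
        summ = delta_density_summary(calls)
        se = calls["delta"].std(ddof=1) / np.sqrt(len(calls))
        assert abs(summ["median"]) < 3 * se

    def test_significant_fraction_tracks_truth(self, small_calls):
        summ = delta_density_summary(small_calls)
        assert 0 < summ["significant_fraction"] < 1
        assert summ["n_tested"] == len(small_calls)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            delta_density_summary(pd.DataFrame(columns=["delta", "significant"]))


def test_sensitivity_increases_with_coverage():
    """Higher coverage detects more truly hydroxymethylated CpGs."""
    model = {"Tx": {"mc_mean": 0.5, "mc_conc": 60, "hmc_mean": 0.3, "hmc_conc": 60}}
    truth = sim.simulate_methylome(3000, {"Tx": 1.0}, model, seed=51)
    sens = []
    for cov, seed in ((10, 61), (20, 62), (60, 63)):
        bis, oxbis = sim.simulate_bisoxbis_counts(truth, cov, seed=seed)
        calls = call_hmc(bis, oxbis)
        sens.append(calls["significant"].mean())
    assert sens[0] <= sens[1] <= sens[2]
    assert sens[2] > sens[0]
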