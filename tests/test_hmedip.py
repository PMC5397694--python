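import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hydroxycall import sim
from hydroxycall.hmedip import (
    bin_logfc,
    build_summit_set,
    call_enriched,
    classify_peaks_by_hmc,
    conditional_binomial_test,
    count_fragments_on_tiles,
    filter_low_tiles,
    nb_exact_test,
    permutation_null,
    summit_gap_hmc,
)
from hydroxycall.io import GenomicInterval
from hydroxycall.singlebase import call_hmc

from conftest import make_calls_frame


class TestTileCounting:
    SIZES = {"chr1": 1200}

    def test_fragment_at_zero_hits_first_tile_only(self):
        frags = {"s": [GenomicInterval("chr1", 0, 1)]}
        t = count_fragments_on_tiles(frags, self.SIZES)
        assert t["s"].tolist() == [1, 0, 0, 0]

    def test_fragment_at_250_spans_two_tiles(self):
        frags = {"s": [GenomicInterval("chr1", 250, 251)]}
        t = count_fragments_on_tiles(frags, self.SIZES)
        assert t["s"].tolist() == [1, 1, 0, 0]

    def test_matches_brute_force_overlap_counting(self):
        rng = np.random.default_rng(14)
        starts = rng.integers(0, 1100, 200)
        frags = {"s": [GenomicInterval("chr1", int(s), int(s) + 1) for s in starts]}
        t = count_fragments_on_tiles(frags, self.SIZES, tile_width=300, extend=300)
        for k in range(len(t)):
            a, b = t["start"].iloc[k], t["end"].iloc[k]
            naive = sum(
                1 for s in starts if max(int(s), a) < min(min(int(s) + 300, 1200), b)
            )
            assert t["s"].iloc[k] == naive


class TestLowCountFilter:
    def test_total_nineteen_removed_twenty_kept(self):
        t = pd.DataFrame(
            {"chrom": "c", "start": [0, 300], "end": [300, 600],
             "a": [5, 5], "b": [5, 5], "c_in": [9, 10]}
        )
        kept = filter_low_tiles(t, min_total=20, sample_cols=["a", "b", "c_in"])
        assert kept["start"].tolist() == [300]

    def test_zero_threshold_is_identity(self):
        t = pd.DataFrame({"chrom": "c", "start": [0], "end": [300], "a": [0]})
        assert len(filter_low_tiles(t, min_total=0, sample_cols=["a"])) == 1


class TestNbExactTest:
    def _table(self, ip, inp):
        return pd.DataFrame(
            {"chrom": "c", "start": np.arange(len(ip)) * 300,
             "end": np.arange(1, len(ip) + 1) * 300, "ip": ip, "inp": inp}
        )

    def test_symmetric_null_gives_p_one(self):
        t = self._table([25], [25])
        res = nb_exact_test(t, ["ip"], ["inp"], lib_sizes={"ip": 100.0, "inp": 100.0})
        assert res["logFC"].iloc[0] == pytest.approx(0.0)
        assert res["p_value"].iloc[0] == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        ip = rng.poisson(30, 50)
        inp = rng.poisson(20, 50)
        libs = {"ip": 2000.0, "inp": 2000.0}
        a = nb_exact_test(self._table(ip, inp), ["ip"], ["inp"], lib_sizes=libs)
        b = nb_exact_test(self._table(inp, ip), ["ip"], ["inp"], lib_sizes=libs)
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-12)
        np.testing.assert_allclose(a["logFC"], -b["logFC"], rtol=1e-9)

    def test_poisson_limit_matches_conditional_binomial(self):
        """At phi -> 0 the exact NB test collapses to the binomial test."""
        pairs = [(s1, s - s1) for s in range(1, 51) for s1 in range(s + 1)]
        t = self._table([a for a, _ in pairs], [b for _, b in pairs])
        res = nb_exact_test(
            t, ["ip"], ["inp"], dispersion=1e-8,
            lib_sizes={"ip": 1000.0, "inp": 1000.0},
        )
        for (s1, s2), p in zip(pairs, res["p_value"]):
            s = s1 + s2
            lo = stats.binom.cdf(s1, s, 0.5)
            hi = stats.binom.sf(s1 - 1, s, 0.5)
            expect = min(1.0, 2 * min(lo, hi))
            assert p == pytest.approx(expect, abs=1e-6)

    def test_null_fdr_rate_controlled(self, small_truth):
        tiles, _ = sim.simulate_hmedip(
            small_truth, enrichment_fn=lambda h: np.ones_like(h),
            background_mean=20, seed=15,
        )
        tiles = filter_low_tiles(tiles, sample_cols=["ip1", "ip2", "input"])
        res = nb_exact_test(tiles, ["ip1", "ip2"], ["input"])
        assert call_enriched(res).mean() <= 0.1

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(self._table([1], [1]), ["ip"], ["inp"], dispersion=-1)


class TestCallAndBin:
    def test_call_rules(self):
        t = pd.DataFrame({"FDR": [0.05, 0.2, 0.01], "logFC": [2.0, 2.0, -1.0]})
        assert call_enriched(t).tolist() == [True, False, False]

    @pytest.mark.parametrize("fc,expect", [(1.0, "low"), (2.0, "medium"), (3.0, "high")])
    def test_logfc_bins(self, fc, expect):
        t = pd.DataFrame({"logFC": [fc]})
        assert bin_logfc(t).iloc[0] == expect

    def test_boundaries_assigned_to_lower_bin(self):
        t = pd.DataFrame({"logFC": [1.8, 2.4]})
        assert bin_logfc(t).tolist() == ["low", "medium"]


class TestSummitSet:
    def test_windows_and_gaps_tile_the_genome(self):
        ss = build_summit_set([("chr1", 500), ("chr1", 2000)], {"chr1": 3000})
        seg = ss.segments
        assert seg["start"].iloc[0] == 0 and seg["end"].iloc[-1] == 3000
        assert (seg["start"].iloc[1:].to_numpy() == seg["end"].iloc[:-1].to_numpy()).all()
        win = ss.windows()
        assert ((win["end"] - win["start"]) == 301).all()

    def test_window_clipped_at_chrom_start(self):
        ss = build_summit_set([("chr1", 50)], {"chr1": 1000})
        win = ss.windows()
        assert win["start"].iloc[0] == 0 and win["end"].iloc[0] == 201

    def test_overlapping_windows_merged(self):
        ss = build_summit_set([("chr1", 500), ("chr1", 600)], {"chr1": 2000})
        assert len(ss.windows()) == 1


def _planted_layout(n_cpg=3000, seed=81, cov=40):
    """Truth with distinct high-5hmC islands; summits planted on them."""
    model = {
        "Enh": {"mc_mean": 0.4, "mc_conc": 30, "hmc_mean": 0.35, "hmc_conc": 40},
        "Quies": {"mc_mean": 0.6, "mc_conc": 30, "hmc_mean": 0.0, "hmc_conc": 10},
    }
    truth = sim.simulate_methylome(
        n_cpg, {"Enh": 0.15, "Quies": 0.85}, model, seed=seed, block_size=40
    )
    bis, oxbis = sim.simulate_bisoxbis_counts(truth, cov, seed=seed + 1)
    calls = call_hmc(bis, oxbis)
    enh = truth.table[truth.table["feature"] == "Enh"]
    # one summit per enhancer block centre
    pos = enh["pos"].to_numpy()
    brk = np.flatnonzero(np.diff(pos) > 2000)
    blocks = np.split(pos, brk + 1)
    summits = [("chrS", int(b[len(b) // 2])) for b in blocks if len(b) > 5]
    return truth, calls, summits


class TestSummitGapAudit:
    def test_planted_summits_have_higher_hmc(self):
        truth, calls, summits = _planted_layout()
        ss = build_summit_set(summits, truth.chrom_sizes)
        res = summit_gap_hmc(ss, calls)
        assert np.median(res["window_hmc"]) > np.median(res["gap_hmc"])
        assert res["kw_p"] < 0.01

    def test_identical_content_gives_p_one(self):
        calls = make_calls_frame([0.2] * 8, [0.001] * 8, positions=np.arange(8) * 100)
        ss = build_summit_set([("chrS", 200), ("chrS", 600)], {"chrS": 800})
        res = summit_gap_hmc(ss, calls)
        assert res["kw_p"] == pytest.approx(1.0)

    def test_planted_signal_beats_permutation_null(self):
        truth, calls, summits = _planted_layout()
        ss = build_summit_set(summits, truth.chrom_sizes)
        res = permutation_null(ss, calls, n_perm=199, seed=5)
        assert res["observed"] > np.quantile(res["null"], 0.975)
        assert res["p_value"] < 0.05

    def test_zero_permutations_rejected(self):
        truth, calls, summits = _planted_layout(n_cpg=500)
        ss = build_summit_set(summits, truth.chrom_sizes)
        with pytest.raises(ValueError):
            permutation_null(ss, calls, n_perm=0)


class TestPeakClassification:
    def test_low_coverage_peak_ineligible(self):
        calls = make_calls_frame([0.3, 0.3], [0.001, 0.001], positions=[100, 900])
        calls.loc[0, "n_bis"] = 9  # one CpG below 10x makes its peak ineligible
        peaks = [GenomicInterval("chrS", 0, 300), GenomicInterval("chrS", 800, 1000)]
        res = classify_peaks_by_hmc(peaks, calls, n_perm=10, seed=1,
                                    chrom_sizes={"chrS": 1000})
        assert res["n_eligible"] == 1

    def test_planted_hmc_peaks_beat_random_placement(self):
        truth, calls_f, summits = _planted_layout(seed=91)
        bis, oxbis = sim.simulate_bisoxbis_counts(truth, 40, seed=92)
        calls_all = call_hmc(bis, oxbis, min_cov=0)
        peaks = [
            GenomicInterval("chrS", max(0, p - 150), p + 150) for _, p in summits
        ]
        res = classify_peaks_by_hmc(
            peaks, calls_all, n_perm=100, seed=93, chrom_sizes=truth.chrom_sizes
        )
        assert res["observed_fraction"] > np.nanquantile(res["null_fractions"], 0.975)

    def test_no_eligible_peaks_rejected(self):
        calls = make_calls_frame([0.3], [0.001], positions=[100])
        with pytest.raises(ValueError):
            classify_peaks_by_hmc(
                [GenomicInterval("chrS", 500, 600)], calls, n_perm=5,
                chrom_sizes={"chrS": 1000},
            )
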