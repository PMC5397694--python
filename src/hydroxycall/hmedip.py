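"""hMeDIP enrichment testing over genomic tiles and the specificity audit.

Immunoprecipitated (IP) and input fragment counts over fixed 300-bp tiles
are contrasted with a conditional negative-binomial exact test at a fixed
dispersion (no library-normalisation factors; library sizes only). Tiles
with FDR < 0.1 and logFC > 0 are called 5hmC-enriched.

The specificity audit compares single-base 5hmC calls inside peak-summit
windows (summit +/- 150 bp) against the uncaptured gaps between them, with
a length-preserving permutation of the window/gap segment labels along the
covered genome as the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval
from .singlebase import cpg_contributions

__all__ = [
    "count_fragments_on_tiles",
    "filter_low_tiles",
    "nb_exact_test",
    "call_enriched",
    "SummitSet",
    "build_summit_set",
    "summit_gap_hmc",
    "permutation_null",
    "classify_peaks_by_hmc",
    "bin_logfc",
]


def count_fragments_on_tiles(
    fragments: dict[str, Sequence[GenomicInterval]],
    chrom_sizes: dict[str, int],
    tile_width: int = 300,
    extend: int = 300,
) -> pd.DataFrame:
    """Count extended fragments over a fixed tiling of the genome.

    Each fragment is extended to length ``extend`` from its 5' position
    (start for +/unstranded, end for -) and increments every tile it
    overlaps by >= 1 bp. ``fragments`` maps sample name -> intervals.
    """
    if tile_width <= 0 or extend <= 0:
        raise ValueError("tile_width and extend must be > 0")
    frames = []
    for chrom, size in chrom_sizes.items():
        n_tiles = int(np.ceil(size / tile_width))
        starts = np.arange(n_tiles, dtype=np.int64) * tile_width
        df = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": np.minimum(starts + tile_width, size)}
        )
        for sample, ivs in fragments.items():
            counts = np.zeros(n_tiles, dtype=np.int64)
            for iv in ivs:
                if iv.chrom != chrom:
                    continue
                if iv.strand == "-":
                    s, e = iv.end - extend, iv.end
                else:
                    s, e = iv.start, iv.start + extend
                s, e = max(s, 0), min(e, size)
                if s >= e:
                    continue
                first = s // tile_width
                last = (e - 1) // tile_width
                counts[first : last + 1] += 1
            df[sample] = counts
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("chrom", "start", "end", "avg_hmc")
            and pd.api.types.is_numeric_dtype(table[c])]


def filter_low_tiles(table: pd.DataFrame, min_total: int = 20,
                     sample_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Drop tiles whose total count across all samples is below ``min_total``."""
    cols = list(sample_cols) if sample_cols else _sample_columns(table)
    if not cols:
        raise ValueError("no sample count columns found")
    keep = table[cols].sum(axis=1) >= min_total
    return table[keep].reset_index(drop=True)


def _conditional_tail_logp(s1: int, s: int, r1: float, r2: float) -> tuple[float, float]:
    """log P(S1 <= s1 | S) and log P(S1 >= s1 | S) under the conditional NB.

    S1 ~ NB(size r1), S2 ~ NB(size r2) with a common success probability,
    so P(S1 = k | S1 + S2 = s) is proportional to
    C(k + r1 - 1, k) * C(s - k + r2 - 1, s - k). The binomial-coefficient
    logs are accumulated as cumulative sums of log((r + j)/(j + 1)), which
    stays exact even for the huge sizes of the Poisson limit.
    """
    k = np.arange(s + 1, dtype=float)
    if np.isinf(r1) or np.isinf(r2):
        # Poisson limit with equal rates: Binomial(s, w) where w depends on
        # the size ratio; handled by the caller via finite sizes instead.
        raise ValueError("sizes must be finite; use a tiny dispersion for the Poisson limit")
    logw1 = np.concatenate(([0.0], np.cumsum(np.log(r1 + k[:-1]) - np.log(k[:-1] + 1.0))))
    logw2 = np.concatenate(([0.0], np.cumsum(np.log(r2 + k[:-1]) - np.log(k[:-1] + 1.0))))
    logw = logw1 + logw2[::-1]
    logz = logsumexp(logw)
    lo = logsumexp(logw[: s1 + 1]) - logz
    hi = logsumexp(logw[s1:]) - logz
    return lo, hi


def conditional_binomial_test(s1: int, s2: int, w: float = 0.5) -> float:
    """Poisson-limit exact test: S1 | S1+S2 ~ Binomial(S, w), tail doubled."""
    s = s1 + s2
    lo = stats.binom.cdf(s1, s, w)
    hi = stats.binom.sf(s1 - 1, s, w)
    return float(min(1.0, 2.0 * min(lo, hi)))


def nb_exact_test(
    table: pd.DataFrame,
    ip_cols: Sequence[str],
    input_cols: Sequence[str],
    dispersion: float = 0.01,
    lib_sizes: dict[str, float] | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Conditional NB exact test of IP vs input per tile at fixed dispersion.

    Counts are mean-scaled to a common library size (the geometric mean of
    the per-sample library sizes; no normalisation factors), summed within
    the IP and input groups, and the group totals compared conditionally
    on the tile total: with n replicates the group sum is NB with size
    n/dispersion, so P(S_IP = k | total) follows the conditional NB law.
    Two-sided p-values double the smaller tail (capped at 1). logFC and
    logCPM use a prior count to avoid log 0; BH-adjusted FDR is appended.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    ip_cols, input_cols = list(ip_cols), list(input_cols)
    all_cols = ip_cols + input_cols
    counts = table[all_cols].to_numpy(dtype=float)
    if lib_sizes is None:
        lib = counts.sum(axis=0)
    else:
        lib = np.array([lib_sizes[c] for c in all_cols], dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    common = float(np.exp(np.mean(np.log(lib))))
    pseudo = np.rint(counts * (common / lib)).astype(np.int64)
    n_ip, n_in = len(ip_cols), len(input_cols)
    s_ip = pseudo[:, :n_ip].sum(axis=1)
    s_in = pseudo[:, n_ip:].sum(axis=1)

    # dispersion 0 is the Poisson limit; use the conditional binomial directly
    if dispersion == 0:
        w = n_ip / (n_ip + n_in)
        pvals = np.array(
            [conditional_binomial_test(int(a), int(b), w) for a, b in zip(s_ip, s_in)]
        )
    else:
        r1 = n_ip / dispersion
        r2 = n_in / dispersion
        pvals = np.empty(len(s_ip))
        for i, (a, b) in enumerate(zip(s_ip, s_in)):
            s = int(a + b)
            if s == 0:
                pvals[i] = 1.0
                continue
            lo, hi = _conditional_tail_logp(int(a), s, r1, r2)
            pvals[i] = min(1.0, 2.0 * min(np.exp(lo), np.exp(hi)))

    cpm_prior = prior_count / common * 1e6
    ip_cpm = (s_ip / n_ip) / common * 1e6
    in_cpm = (s_in / n_in) / common * 1e6
    logfc = np.log2(ip_cpm + cpm_prior) - np.log2(in_cpm + cpm_prior)
    out = table.copy()
    for col in all_cols:
        out[f"logcpm_{col}"] = np.log2(
            (table[col].to_numpy(dtype=float) + prior_count)
            / (lib[all_cols.index(col)] + 2 * prior_count)
            * 1e6
        )
    out["logFC"] = logfc
    out["p_value"] = pvals
    out["FDR"] = multipletests(pvals, method="fdr_bh")[1]
    return out


def call_enriched(table: pd.DataFrame, fdr: float = 0.1, min_logfc: float = 0.0) -> np.ndarray:
    """Tiles called 5hmC-enriched: FDR < 0.1 and logFC > 0 by default."""
    return (table["FDR"].to_numpy() < fdr) & (table["logFC"].to_numpy() > min_logfc)


def bin_logfc(table: pd.DataFrame, low_lt: float = 1.8, high_gt: float = 2.4) -> pd.Series:
    """Split tiles into low / medium / high enrichment by logFC.

    Cut-offs: low logFC <= ``low_lt``, high logFC > ``high_gt``, medium in
    between (boundary values go to the lower bin).
    """
    fc = table["logFC"].to_numpy(dtype=float)
    lab = np.where(fc <= low_lt, "low", np.where(fc <= high_gt, "medium", "high"))
    return pd.Series(lab, index=table.index, name="logfc_bin")


@dataclass
class SummitSet:
    """Alternating window/gap segmentation of the covered genome.

    ``segments`` is a per-chromosome DataFrame (chrom, start, end,
    is_window) whose segments tile [0, chrom size) disjointly in order.
    """

    segments: pd.DataFrame
    chrom_sizes: dict[str, int]

    def windows(self) -> pd.DataFrame:
        return self.segments[self.segments["is_window"]].reset_index(drop=True)

    def gaps(self) -> pd.DataFrame:
        return self.segments[~self.segments["is_window"]].reset_index(drop=True)


def build_summit_set(
    summits: Sequence[tuple[str, int]] | Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    half_width: int = 150,
) -> SummitSet:
    """Expand peak summits +/-``half_width`` bp and derive the gaps.

    Summits may be (chrom, pos) pairs or 1-bp intervals. Windows are
    merged where they overlap and clipped at chromosome ends; gaps are
    the complement within each chromosome.
    """
    pts: dict[str, list[int]] = {}
    for s in summits:
        if isinstance(s, GenomicInterval):
            pts.setdefault(s.chrom, []).append(s.start)
        else:
            chrom, pos = s
            pts.setdefault(chrom, []).append(int(pos))
    rows = []
    for chrom, size in chrom_sizes.items():
        wins: list[list[int]] = []
        for pos in sorted(pts.get(chrom, [])):
            a = max(0, pos - half_width)
            b = min(size, pos + half_width + 1)
            if wins and a <= wins[-1][1]:
                wins[-1][1] = max(wins[-1][1], b)
            else:
                wins.append([a, b])
        cur = 0
        for a, b in wins:
            if a > cur:
                rows.append((chrom, cur, a, False))
            rows.append((chrom, a, b, True))
            cur = b
        if cur < size:
            rows.append((chrom, cur, size, False))
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "is_window"])
    if len(seg) < 2:
        raise ValueError("degenerate segmentation: need at least one window and one gap")
    return SummitSet(seg, dict(chrom_sizes))


def _segment_averages(
    seg: pd.DataFrame, pos_by_chrom: dict[str, np.ndarray],
    cum_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment mean contribution and contributing-CpG count."""
    avg = np.full(len(seg), np.nan)
    cnt = np.zeros(len(seg), dtype=np.int64)
    for chrom, grp in seg.groupby("chrom", sort=False):
        if chrom not in pos_by_chrom:
            continue
        pos = pos_by_chrom[chrom]
        cumv, cumc = cum_by_chrom[chrom]
        i = np.searchsorted(pos, grp["start"].to_numpy())
        j = np.searchsorted(pos, grp["end"].to_numpy())
        c = cumc[j] - cumc[i]
        v = cumv[j] - cumv[i]
        rows = grp.index.to_numpy()
        cnt[rows] = c
        with np.errstate(invalid="ignore"):
            avg[rows] = np.where(c > 0, v / np.maximum(c, 1), np.nan)
    return avg, cnt


def _prepare_contributions(calls: pd.DataFrame):
    contrib = cpg_contributions(calls)
    pos_by, cum_by = {}, {}
    for chrom, grp in calls.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        v = contrib[calls.index.get_indexer(grp.index)][order]
        valid = ~np.isnan(v)
        cumv = np.concatenate(([0.0], np.cumsum(np.where(valid, v, 0.0))))
        cumc = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
        pos_by[chrom] = pos
        cum_by[chrom] = (cumv, cumc)
    return pos_by, cum_by


def summit_gap_hmc(summit_set: SummitSet, calls: pd.DataFrame) -> dict:
    """Region-average 5hmC distributions over windows vs gaps + KW test."""
    seg = summit_set.segments.reset_index(drop=True)
    pos_by, cum_by = _prepare_contributions(calls)
    avg, _ = _segment_averages(seg, pos_by, cum_by)
    is_win = seg["is_window"].to_numpy()
    win = avg[is_win & ~np.isnan(avg)]
    gap = avg[~is_win & ~np.isnan(avg)]
    if len(win) == 0 or len(gap) == 0:
        raise ValueError("no defined window or gap regions")
    pooled = np.concatenate([win, gap])
    if np.ptp(pooled) <= 1e-12 * max(1.0, np.abs(pooled).max()):
        h, p = 0.0, 1.0  # all values identical: no rank difference
    else:
        h, p = stats.kruskal(win, gap)
    return {
        "window_hmc": win,
        "gap_hmc": gap,
        "mean_diff": float(win.mean() - gap.mean()),
        "kw_statistic": float(h),
        "kw_p": float(p),
    }


def permutation_null(
    summit_set: SummitSet,
    calls: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Permutation null for the summit-minus-gap mean 5hmC difference.

    The (length, label) sequence of window/gap segments is randomly
    permuted along each chromosome — segment lengths and the window/gap
    label multiset are preserved, coordinates are re-laid end to end — and
    the mean window minus mean gap region-average 5hmC recomputed each
    time. Empirical p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seg = summit_set.segments.reset_index(drop=True)
    if seg["chrom"].nunique() == len(seg):
        raise ValueError("degenerate single-segment segmentation")
    pos_by, cum_by = _prepare_contributions(calls)

    observed = summit_gap_hmc(summit_set, calls)["mean_diff"]
    rng = np.random.default_rng(seed)
    lengths = (seg["end"] - seg["start"]).to_numpy()
    labels = seg["is_window"].to_numpy()
    chroms = seg["chrom"].to_numpy()
    per_chrom = [
        (lengths[chroms == c], labels[chroms == c], pos_by.get(c), cum_by.get(c))
        for c in pd.unique(chroms)
    ]
    total_len = int(lengths.sum())
    null = np.empty(n_perm)
    for b in range(n_perm):
        w_sum = w_n = g_sum = g_n = 0.0
        laid = 0
        for ln_c, lb_c, pos, cums in per_chrom:
            order = rng.permutation(len(ln_c))
            ln = ln_c[order]
            lb = lb_c[order]
            ends = np.cumsum(ln)
            starts = ends - ln
            laid += int(ends[-1])
            if pos is None:
                continue
            cumv, cumc = cums
            i = np.searchsorted(pos, starts)
            j = np.searchsorted(pos, ends)
            c = cumc[j] - cumc[i]
            v = cumv[j] - cumv[i]
            ok = c > 0
            avg = v[ok] / c[ok]
            win = lb[ok]
            w_sum += avg[win].sum()
            w_n += win.sum()
            g_sum += avg[~win].sum()
            g_n += (~win).sum()
        assert laid == total_len  # lengths conserved under permutation
        null[b] = (w_sum / w_n if w_n else np.nan) - (g_sum / g_n if g_n else np.nan)
    emp_p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return {"observed": float(observed), "null": null, "p_value": float(emp_p)}


def classify_peaks_by_hmc(
    peaks: Sequence[GenomicInterval],
    calls_all: pd.DataFrame,
    min_cov: int = 10,
    n_perm: int = 200,
    seed: int | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> dict:
    """Fraction of eligible peaks with average 5hmC > 0, with a placement null.

    ``calls_all`` must be an unfiltered call table (min_cov=0) so peak
    eligibility — every CpG in the peak covered >= ``min_cov`` in both
    treatments, and at least one CpG present — can be assessed. Average
    5hmC per peak follows the discard/impute rules. The expected fraction
    comes from length-preserving uniform random placement of the same
    peaks (``n_perm`` rounds).
    """
    from .singlebase import _region_index, region_average_hmc

    idx_per_peak = _region_index(calls_all, peaks)
    nb = pd.Series(calls_all["n_bis"].to_numpy(), index=calls_all.index)
    no = pd.Series(calls_all["n_oxbis"].to_numpy(), index=calls_all.index)
    eligible = []
    for iv, idx in zip(peaks, idx_per_peak):
        if len(idx) == 0:
            continue
        if (nb.loc[idx] >= min_cov).all() and (no.loc[idx] >= min_cov).all():
            eligible.append(iv)
    if not eligible:
        raise ValueError("no eligible peaks (coverage filter removed all)")

    def fraction_positive(pks: list[GenomicInterval]) -> float:
        ra = region_average_hmc(calls_all, pks)
        defined = ra[ra["defined"]]
        if defined.empty:
            return np.nan
        return float((defined["avg_hmc"] > 0).mean())

    observed = fraction_positive(eligible)
    rng = np.random.default_rng(seed)
    sizes = chrom_sizes or {
        c: int(g["pos"].max()) + 1 for c, g in calls_all.groupby("chrom")
    }
    null = np.empty(n_perm)
    for b in range(n_perm):
        placed = []
        for iv in eligible:
            size = sizes[iv.chrom]
            ln = len(iv)
            start = int(rng.integers(0, max(1, size - ln)))
            placed.append(GenomicInterval(iv.chrom, start, start + ln))
        null[b] = fraction_positive(placed)
    return {
        "n_eligible": len(eligible),
        "observed_fraction": observed,
        "null_fractions": null,
        "p_value": float((1.0 + np.nansum(null >= observed)) / (n_perm + 1.0)),
    }
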