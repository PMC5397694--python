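"""Single-base 5hmC calling from paired Bis/OxBis count tables.

The 5hmC level at a CpG is estimated by subtraction: delta = p_Bis -
p_OxBis, where p_Bis = NC_Bis/N_Bis reads out total modification (5modC)
and p_OxBis = NC_OxBis/N_OxBis reads out 5mC. Retained counts are modelled
as NC ~ Binomial(N, p), so the natural test for delta > 0 is the classical
two-sample proportion test (chi-square on the 2x2 retained/converted table
with Yates continuity correction, the default of R's prop.test). A CpG is
called significantly hydroxymethylated when the two-sided p-value is below
alpha AND delta > 0.

Region-level averaging applies the discard/impute rules: significant CpGs
contribute delta; non-significant CpGs with 0 <= delta <= 10% are imputed
to zero; non-significant CpGs with delta > 10% and all CpGs with delta < 0
are discarded (too noisy, respectively chemically impossible).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval

__all__ = [
    "two_proportion_test",
    "call_hmc",
    "cpg_contributions",
    "region_average_hmc",
    "classify_hydroxymethylated_region",
    "power_two_proportion",
    "delta_density_summary",
]

CALL_COLUMNS = [
    "chrom", "pos", "p_bis", "p_oxbis", "delta", "p_value", "significant",
    "n_bis", "n_oxbis",
]


def two_proportion_test(nc_bis, n_bis, nc_oxbis, n_oxbis, correction: bool = True):
    """Two-sample two-sided proportion test on retained-cytosine counts.

    Vectorised chi-square test on the 2x2 table
    [[NC_Bis, N_Bis - NC_Bis], [NC_OxBis, N_OxBis - NC_OxBis]] with Yates
    continuity correction capped at |delta| / (1/N_Bis + 1/N_OxBis), which
    is exactly the construction of R's ``prop.test`` default.

    Returns
    -------
    (delta, p_value) : arrays (or scalars for scalar input);
    delta = NC_Bis/N_Bis - NC_OxBis/N_OxBis.
    """
    scalar = np.isscalar(n_bis)
    x1 = np.atleast_1d(np.asarray(nc_bis, dtype=float))
    n1 = np.atleast_1d(np.asarray(n_bis, dtype=float))
    x2 = np.atleast_1d(np.asarray(nc_oxbis, dtype=float))
    n2 = np.atleast_1d(np.asarray(n_oxbis, dtype=float))
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("zero coverage: N_Bis and N_OxBis must be >= 1")
    if np.any(x1 < 0) or np.any(x2 < 0) or np.any(x1 > n1) or np.any(x2 > n2):
        raise ValueError("retained counts must satisfy 0 <= NC <= N")

    p1, p2 = x1 / n1, x2 / n2
    delta = p1 - p2
    n = n1 + n2
    succ = x1 + x2
    fail = n - succ
    # expected counts under the common-proportion null
    e11 = n1 * succ / n
    e12 = n1 * fail / n
    e21 = n2 * succ / n
    e22 = n2 * fail / n
    yates = 0.0
    if correction:
        yates = np.minimum(0.5, np.abs(delta) / (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (
            (np.abs(x1 - e11) - yates) ** 2 / e11
            + (np.abs(n1 - x1 - e12) - yates) ** 2 / e12
            + (np.abs(x2 - e21) - yates) ** 2 / e21
            + (np.abs(n2 - x2 - e22) - yates) ** 2 / e22
        )
    p_value = stats.chi2.sf(stat, df=1)
    # degenerate margins (all retained or all converted): proportions equal
    degenerate = (succ == 0) | (fail == 0)
    p_value = np.where(degenerate, 1.0, p_value)
    if scalar:
        return float(delta[0]), float(p_value[0])
    return delta, p_value


def call_hmc(
    bis: pd.DataFrame,
    oxbis: pd.DataFrame,
    min_cov: int = 10,
    alpha: float = 0.05,
    correction: bool = True,
    adjust: bool = False,
) -> pd.DataFrame:
    """Call per-CpG hydroxymethylation from paired Bis/OxBis count tables.

    CpGs present in both tables with coverage >= ``min_cov`` in *both*
    treatments are tested; a CpG is significant when p < alpha and
    delta > 0 (p is BH-adjusted first if ``adjust``). All tested CpGs are
    retained in the output with their delta and p-value.
    """
    merged = bis.merge(oxbis, on=["chrom", "pos"], suffixes=("_bis", "_oxbis"))
    merged = merged[(merged["N_bis"] >= min_cov) & (merged["N_oxbis"] >= min_cov)]
    if merged.empty:
        import logging

        logging.getLogger(__name__).warning("no CpGs pass the joint coverage filter")
        return pd.DataFrame(columns=CALL_COLUMNS)
    delta, p = two_proportion_test(
        merged["NC_bis"].to_numpy(),
        merged["N_bis"].to_numpy(),
        merged["NC_oxbis"].to_numpy(),
        merged["N_oxbis"].to_numpy(),
        correction=correction,
    )
    p_crit = multipletests(p, method="fdr_bh")[1] if adjust else p
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"].to_numpy(),
            "pos": merged["pos"].to_numpy(),
            "p_bis": merged["NC_bis"].to_numpy() / merged["N_bis"].to_numpy(),
            "p_oxbis": merged["NC_oxbis"].to_numpy() / merged["N_oxbis"].to_numpy(),
            "delta": delta,
            "p_value": p,
            "significant": (p_crit < alpha) & (delta > 0),
            "n_bis": merged["N_bis"].to_numpy(),
            "n_oxbis": merged["N_oxbis"].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def cpg_contributions(calls: pd.DataFrame, impute_limit: float = 0.10) -> np.ndarray:
    """Per-CpG 5hmC value entering region averages; NaN marks a discard.

    Significant CpGs contribute their delta. Non-significant CpGs with
    0 <= delta <= ``impute_limit`` are imputed to zero; non-significant
    CpGs with delta > ``impute_limit`` and any CpG with delta < 0 are
    discarded (NaN).
    """
    delta = calls["delta"].to_numpy(dtype=float)
    sig = calls["significant"].to_numpy(dtype=bool)
    out = np.full(len(calls), np.nan)
    out[sig] = delta[sig]
    impute = ~sig & (delta >= 0) & (delta <= impute_limit)
    out[impute] = 0.0
    return out


def _region_index(
    calls: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> list[np.ndarray]:
    """Indices of call rows inside each region (calls need not be sorted)."""
    idx_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in calls.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx_by_chrom[chrom] = (pos[order], grp.index.to_numpy()[order])
    out = []
    for iv in regions:
        if iv.chrom not in idx_by_chrom:
            out.append(np.array([], dtype=int))
            continue
        pos, rows = idx_by_chrom[iv.chrom]
        i, j = np.searchsorted(pos, (iv.start, iv.end))
        out.append(rows[i:j])
    return out


def region_average_hmc(
    calls: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    impute_limit: float = 0.10,
) -> pd.DataFrame:
    """Average 5hmC per region under the discard/impute rules.

    Regions where every CpG was discarded (or that contain no tested CpG)
    get ``avg_hmc = NaN`` and ``defined = False``.
    """
    contrib = cpg_contributions(calls, impute_limit=impute_limit)
    contrib_by_row = pd.Series(contrib, index=calls.index)
    rows = []
    for k, (iv, idx) in enumerate(zip(regions, _region_index(calls, regions))):
        vals = contrib_by_row.loc[idx].to_numpy() if len(idx) else np.array([])
        vals = vals[~np.isnan(vals)]
        rows.append(
            (
                k, iv.chrom, iv.start, iv.end, iv.name,
                len(idx), len(vals),
                float(vals.mean()) if len(vals) else np.nan,
                bool(len(vals)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "region", "chrom", "start", "end", "name",
            "n_cpg", "n_contributing", "avg_hmc", "defined",
        ],
    )


def classify_hydroxymethylated_region(
    calls: pd.DataFrame, regions: Sequence[GenomicInterval], min_sig: int = 1
) -> np.ndarray:
    """True for regions containing at least ``min_sig`` significant CpGs."""
    sig = calls["significant"].to_numpy(dtype=bool)
    sig_by_row = pd.Series(sig, index=calls.index)
    return np.array(
        [
            int(sig_by_row.loc[idx].sum()) >= min_sig if len(idx) else False
            for idx in _region_index(calls, regions)
        ]
    )


def power_two_proportion(p1: float, p2: float, n: float, alpha: float = 0.05) -> float:
    """Normal-approximation power of the two-sided two-proportion test.

    Equal group sizes ``n``; mirrors the closed form of R's
    ``power.prop.test``. Degenerate p1 == p2 returns the alpha level.
    """
    if not (0 <= p2 <= 1 and 0 <= p1 <= 1):
        raise ValueError("proportions must be in [0, 1]")
    if n < 2:
        raise ValueError("n must be >= 2")
    if p1 == p2:
        return alpha
    d = abs(p1 - p2)
    pbar = (p1 + p2) / 2.0
    qbar = 1.0 - pbar
    qu = stats.norm.ppf(1.0 - alpha / 2.0)
    sd1 = np.sqrt(p1 * (1 - p1) + p2 * (1 - p2))
    return float(stats.norm.cdf((np.sqrt(n) * d - qu * np.sqrt(2 * pbar * qbar)) / sd1))


def delta_density_summary(calls: pd.DataFrame, n_bins: int = 80) -> dict:
    """Empirical distribution of delta over all tested CpGs.

    Returns quantiles, a histogram on [-1, 1], and the fraction of tested
    CpGs called significantly hydroxymethylated.
    """
    if calls.empty:
        raise ValueError("no tested CpGs: cannot summarise an empty call table")
    delta = calls["delta"].to_numpy(dtype=float)
    qs = np.array([0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99])
    hist, edges = np.histogram(delta, bins=n_bins, range=(-1.0, 1.0), density=True)
    return {
        "n_tested": int(len(calls)),
        "quantiles": dict(zip(qs.tolist(), np.quantile(delta, qs).tolist())),
        "median": float(np.median(delta)),
        "hist_density": hist,
        "hist_edges": edges,
        "significant_fraction": float(calls["significant"].mean()),
    }
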