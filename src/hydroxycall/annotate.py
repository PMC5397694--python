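"""Genomic-feature annotation and descriptive enrichment statistics.

Covers the level-binned observed/expected enrichment of hydroxymethylated
CpGs across chromatin features (hypergeometric overlap test), per-region
hydroxymethylated-CpG fractions, the 5hmC contribution to total
methylation, and the whole-genome vs array platform-overlap classes with
their Kruskal-Wallis comparison.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval
from .singlebase import _region_index, cpg_contributions

__all__ = [
    "bin_calls_by_level",
    "observed_expected_enrichment",
    "region_hmc_fraction",
    "region_hmc_contribution",
    "platform_overlap",
    "label_cpgs_by_feature",
]

DEFAULT_LEVEL_EDGES = (0.0, 0.10, 0.20, 0.30)


def bin_calls_by_level(
    calls: pd.DataFrame,
    variable: str = "5hmC",
    edges: Sequence[float] = DEFAULT_LEVEL_EDGES,
) -> pd.Series:
    """Assign each tested CpG to a level bin.

    Bins are left-closed right-open with the final bin unbounded, labelled
    e.g. "0-10", "10-20", "20-30", ">30" for the default percent edges.
    ``variable`` selects delta ("5hmC") or p_bis ("5modC").
    """
    edges = list(edges)
    if len(edges) < 1:
        raise ValueError("edges must be non-empty")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    if variable == "5hmC":
        values = calls["delta"].to_numpy(dtype=float)
    elif variable == "5modC":
        values = calls["p_bis"].to_numpy(dtype=float)
    else:
        raise ValueError("variable must be '5hmC' or '5modC'")
    labels = [
        f"{round(a * 100):g}-{round(b * 100):g}" for a, b in zip(edges, edges[1:])
    ] + [f">{round(edges[-1] * 100):g}"]
    idx = np.searchsorted(edges, values, side="right") - 1
    idx = np.clip(idx, 0, len(labels) - 1)
    return pd.Series(
        pd.Categorical.from_codes(idx, categories=labels), index=calls.index, name="level_bin"
    )


def label_cpgs_by_feature(
    calls: pd.DataFrame, features: Sequence[GenomicInterval], fill: str = "None"
) -> pd.Series:
    """Feature label per CpG (first covering interval wins; ``fill`` if none)."""
    out = np.full(len(calls), fill, dtype=object)
    taken = np.zeros(len(calls), dtype=bool)
    positions = {i: row for i, row in enumerate(calls.index)}
    row_to_i = {row: i for i, row in positions.items()}
    for iv, idx in zip(features, _region_index(calls, features)):
        for row in idx:
            i = row_to_i[row]
            if not taken[i]:
                out[i] = iv.name or "feature"
                taken[i] = True
    return pd.Series(out, index=calls.index, name="feature")


def observed_expected_enrichment(
    cpg_set: np.ndarray, feature_labels: Sequence
) -> pd.DataFrame:
    """Observed/expected feature enrichment of a CpG subset.

    Parameters
    ----------
    cpg_set : boolean mask over the CpG universe (True = CpG in the set).
    feature_labels : per-CpG feature label for the whole universe.

    For each feature, expected = |set| * (CpGs in feature / universe);
    the hypergeometric upper-tail p-value tests enrichment of the overlap
    (drawing |set| CpGs from the universe with the feature's CpGs as
    successes); the lower tail is reported for depletion.
    """
    mask = np.asarray(cpg_set, dtype=bool)
    labels = np.asarray(feature_labels)
    if mask.shape != labels.shape:
        raise ValueError("cpg_set and feature_labels must align")
    n_all = mask.size
    n_set = int(mask.sum())
    rows = []
    for feat in pd.unique(labels):
        in_feat = labels == feat
        m = int(in_feat.sum())
        if m == 0:
            continue
        obs = int((mask & in_feat).sum())
        expected = n_set * m / n_all
        oe = obs / expected if expected > 0 else np.nan
        p_enrich = stats.hypergeom.sf(obs - 1, n_all, m, n_set)
        p_deplete = stats.hypergeom.cdf(obs, n_all, m, n_set)
        rows.append((feat, m, obs, expected, oe, p_enrich, p_deplete))
    return pd.DataFrame(
        rows,
        columns=[
            "feature", "n_feature_cpgs", "observed", "expected",
            "oe_ratio", "p_enrichment", "p_depletion",
        ],
    )


def region_hmc_fraction(
    calls: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per region: tested CpGs, significant CpGs, and their fraction.

    Regions with no tested CpG are flagged undefined (NaN fraction) and
    should be excluded from distribution summaries.
    """
    sig = pd.Series(calls["significant"].to_numpy(dtype=bool), index=calls.index)
    rows = []
    for k, (iv, idx) in enumerate(zip(regions, _region_index(calls, regions))):
        n = len(idx)
        n_hmc = int(sig.loc[idx].sum()) if n else 0
        rows.append(
            (k, iv.chrom, iv.start, iv.end, iv.name, n, n_hmc,
             n_hmc / n if n else np.nan)
        )
    return pd.DataFrame(
        rows,
        columns=["region", "chrom", "start", "end", "name", "n_cpg", "n_hmc_cpg", "fraction"],
    )


def region_hmc_contribution(
    calls: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Per region: average 5hmC, average 5modC and the 5hmC contribution.

    The per-CpG 5hmC entering the average is delta for significant CpGs
    and zero otherwise (non-significant levels are assigned to zero);
    5modC is p_Bis. Contribution = avg_5hmC / avg_5modC, undefined when
    avg_5modC = 0.
    """
    hmc = np.where(
        calls["significant"].to_numpy(dtype=bool), calls["delta"].to_numpy(dtype=float), 0.0
    )
    hmc = np.maximum(hmc, 0.0)
    modc = calls["p_bis"].to_numpy(dtype=float)
    hmc_s = pd.Series(hmc, index=calls.index)
    modc_s = pd.Series(modc, index=calls.index)
    rows = []
    for k, (iv, idx) in enumerate(zip(regions, _region_index(calls, regions))):
        if len(idx) == 0:
            rows.append((k, iv.name, 0, np.nan, np.nan, np.nan))
            continue
        a_h = float(hmc_s.loc[idx].mean())
        a_m = float(modc_s.loc[idx].mean())
        contrib = min(a_h / a_m, 1.0) if a_m > 0 else np.nan
        rows.append((k, iv.name, len(idx), a_h, a_m, contrib))
    return pd.DataFrame(
        rows, columns=["region", "name", "n_cpg", "avg_5hmc", "avg_5modc", "contribution"]
    )


def platform_overlap(
    wg_called: np.ndarray,
    array_called: np.ndarray,
    max_hmc_wg: np.ndarray,
) -> tuple[pd.Series, pd.Series, dict]:
    """Classify universe regions by which platform called them.

    Parameters are aligned per-region arrays over the comparison universe
    (regions with >= 1 array probe and sufficient WG coverage, assembled
    by the caller). Returns the class per region ("both", "wg_only",
    "array_only", "neither"), class counts, and the Kruskal-Wallis
    comparison of the per-region maximum WG 5hmC between the "array_only"
    and "both" classes (skipped with a warning when a class is empty).
    """
    wg = np.asarray(wg_called, dtype=bool)
    arr = np.asarray(array_called, dtype=bool)
    mx = np.asarray(max_hmc_wg, dtype=float)
    if not (wg.shape == arr.shape == mx.shape):
        raise ValueError("inputs must be aligned per-region arrays")
    cls = np.where(wg & arr, "both", np.where(wg, "wg_only", np.where(arr, "array_only", "neither")))
    classes = pd.Series(cls, name="class")
    counts = classes.value_counts()
    kw: dict = {"statistic": np.nan, "p_value": np.nan, "tested": False}
    g_both = mx[cls == "both"]
    g_arr = mx[cls == "array_only"]
    if len(g_both) and len(g_arr):
        h, p = stats.kruskal(g_both, g_arr)
        kw = {"statistic": float(h), "p_value": float(p), "tested": True}
    else:
        import logging

        logging.getLogger(__name__).warning(
            "empty platform-overlap class; Kruskal-Wallis skipped"
        )
    return classes, counts, kw
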