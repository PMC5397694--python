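"""Spike-in chemistry-efficiency estimators and single-molecule patterns.

Spike-in controls with a known modification state at every site (M.SssI
CpG-methylated lambda DNA for 5mC, fully hydroxymethylated pUC18/APC
products for 5hmC) are sequenced alongside the samples in each chemistry
arm; pooled retained/converted counts at those sites estimate the
conversion, oxidation and protection efficiencies of the reactions.
Deep amplicon reads additionally give per-molecule modification patterns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "conversion_efficiency",
    "oxidation_efficiency",
    "tet_oxidation_efficiency",
    "bgt_protection_efficiency",
    "classify_single_molecules",
]

PATTERN_CLASSES = ("0", "0-10", "10-50", "50-80", "80-100")


def _pooled(counts: pd.DataFrame, state: str, assay: str | None = None) -> tuple[int, int]:
    sub = counts[counts["state"] == state]
    if assay is not None:
        sub = sub[sub["assay"] == assay]
    ret = int(sub["retained"].sum())
    conv = int(sub["converted"].sum())
    if ret + conv == 0:
        raise ValueError(f"zero coverage for state={state!r} assay={assay!r}")
    return ret, conv


def conversion_efficiency(
    counts: pd.DataFrame, state: str = "unmodified", assay: str = "Bis",
    ci_alpha: float = 0.05,
) -> dict:
    """Bisulphite conversion efficiency from unmodified spike-in cytosines.

    Efficiency = converted / (converted + retained) pooled over sites; the
    complement is the non-conversion rate. A Wilson binomial CI is
    reported.
    """
    ret, conv = _pooled(counts, state, assay)
    n = ret + conv
    eff = conv / n
    lo, hi = proportion_confint(conv, n, alpha=ci_alpha, method="wilson")
    return {
        "efficiency": eff,
        "nonconversion_rate": 1.0 - eff,
        "ci": (float(lo), float(hi)),
        "n": n,
    }


def oxidation_efficiency(
    bis_counts: pd.DataFrame, oxbis_counts: pd.DataFrame, state: str = "5hmC"
) -> dict:
    """5hmC oxidation efficiency of the OxBis reaction.

    The converted fraction at (truly hydroxymethylated) spike-in sites in
    OxBis, normalised by the retained fraction of the same sites in
    conventional Bis — i.e. conversion relative to the hydroxymethylation
    actually present — clipped to [0, 1].
    """
    ret_b, conv_b = _pooled(bis_counts, state, "Bis")
    ret_o, conv_o = _pooled(oxbis_counts, state, "OxBis")
    bis_retained_frac = ret_b / (ret_b + conv_b)
    if bis_retained_frac == 0:
        raise ValueError("Bis retained fraction is zero: efficiency undefined")
    conv_frac = conv_o / (ret_o + conv_o)
    return {
        "efficiency": float(np.clip(conv_frac / bis_retained_frac, 0.0, 1.0)),
        "n": ret_o + conv_o,
    }


def tet_oxidation_efficiency(
    tab_counts: pd.DataFrame, bis_counts: pd.DataFrame, state: str = "5mC"
) -> dict:
    """TET-mediated 5mC oxidation efficiency in the TAB reaction.

    1 minus the ratio of the retained (mC signal) fraction in TAB to that
    in Bis at 5mC spike-in sites.
    """
    ret_t, conv_t = _pooled(tab_counts, state, "TAB")
    ret_b, conv_b = _pooled(bis_counts, state, "Bis")
    frac_b = ret_b / (ret_b + conv_b)
    if frac_b == 0:
        raise ValueError("Bis retained fraction is zero: efficiency undefined")
    frac_t = ret_t / (ret_t + conv_t)
    return {
        "efficiency": float(np.clip(1.0 - frac_t / frac_b, 0.0, 1.0)),
        "n": ret_t + conv_t,
    }


def bgt_protection_efficiency(
    tab_counts: pd.DataFrame, bis_counts: pd.DataFrame, state: str = "5hmC"
) -> dict:
    """BGT-mediated 5hmC protection efficiency in the TAB reaction.

    Ratio of the retained fraction in TAB to that in Bis at 5hmC spike-in
    sites, capped at 1.
    """
    ret_t, conv_t = _pooled(tab_counts, state, "TAB")
    ret_b, conv_b = _pooled(bis_counts, state, "Bis")
    frac_b = ret_b / (ret_b + conv_b)
    if frac_b == 0:
        raise ValueError("Bis retained fraction is zero: efficiency undefined")
    frac_t = ret_t / (ret_t + conv_t)
    return {"efficiency": float(min(frac_t / frac_b, 1.0)), "n": ret_t + conv_t}


def classify_single_molecules(
    reads: pd.DataFrame | np.ndarray,
    edges: tuple[float, ...] = (0.0, 0.10, 0.50, 0.80, 1.0),
) -> dict:
    """Classify reads by their per-molecule modified-CpG fraction.

    Classes for the default edges: exactly 0, (0, 10], (10, 50], (50, 80]
    and (80, 100] percent (zero is its own class; the other bins are
    right-closed). Returns class frequencies (summing to 1), per-read
    fractions and the region-average modification.
    """
    mat = np.asarray(reads, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("reads must be a 2-D matrix with >= 1 CpG column")
    if mat.shape[0] < 1:
        raise ValueError("need at least one read")
    frac = mat.mean(axis=1)
    inner = np.asarray(edges[1:-1])
    labels = list(PATTERN_CLASSES[: len(inner) + 2])
    # class 0 is exactly zero; remaining bins are (edges[i], edges[i+1]]
    idx = np.searchsorted(inner, frac, side="left") + 1
    idx[frac == 0] = 0
    freqs = np.bincount(idx, minlength=len(labels)).astype(float) / len(frac)
    return {
        "classes": labels,
        "frequencies": dict(zip(labels, freqs.tolist())),
        "read_fractions": frac,
        "region_average": float(mat.mean()),
    }
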