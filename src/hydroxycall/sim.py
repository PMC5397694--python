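"""Synthetic data generator for paired Bis/OxBis experiments.

The generator produces the inputs every downstream stage consumes — paired
bisulphite (Bis) and oxidative-bisulphite (OxBis) count tables, array-style
beta tables, hMeDIP/input tile counts, spike-in control counts and
single-molecule amplicon read matrices — together with the ground truth
(per-CpG 5mC and 5hmC proportions) needed for recovery tests.

Chemistry model
---------------
Conventional bisulphite reads out total modification (5modC = 5mC + 5hmC):
both 5mC and 5hmC resist conversion. Oxidative bisulphite first oxidises
5hmC to 5fC, which converts like an unmodified C, so OxBis reads out 5mC
only. The per-read probability that a cytosine is retained (sequenced as C)
is therefore

    r_Bis   = (p_5mC + p_5hmC) (1 - e_overconv) + (1 - p_5mC - p_5hmC) e_nonconv
    r_OxBis = p_5mC (1 - e_overconv) + p_5hmC (1 - eff_ox)
              + (1 - p_5mC - p_5hmC) e_nonconv

with e_nonconv the non-conversion error of unmodified C, e_overconv the
over-conversion error of a modified C, and eff_ox the 5hmC oxidation
efficiency. Retained counts are Binomial(N, r) at coverage N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomicInterval

__all__ = [
    "ChemistryModel",
    "TrueMethylome",
    "DEFAULT_LEVEL_MODEL",
    "DEFAULT_FEATURE_MIX",
    "simulate_methylome",
    "simulate_bisoxbis_counts",
    "simulate_array_betas",
    "simulate_hmedip",
    "simulate_spikein",
    "simulate_amplicon_reads",
    "retention_probability",
]


@dataclass(frozen=True)
class ChemistryModel:
    """Error/efficiency parameters of the bisulphite chemistries.

    Defaults are the efficiencies measured on the spike-in controls:
    0.42% non-conversion of unmodified C, 99.33% 5hmC oxidation in OxBis,
    98.74% TET-mediated 5mC oxidation and ~100% BGT protection of 5hmC in
    TAB, and over-conversion set from the lower end of the printed Bis
    conversion range (98.30%).
    """

    e_nonconv: float = 0.0042
    e_overconv: float = 1.0 - 0.9830
    eff_ox: float = 0.9933
    eff_tet: float = 0.9874
    eff_bgt: float = 1.0

    def __post_init__(self) -> None:
        for name in ("e_nonconv", "e_overconv", "eff_ox", "eff_tet", "eff_bgt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def perfect(cls) -> "ChemistryModel":
        return cls(e_nonconv=0.0, e_overconv=0.0, eff_ox=1.0, eff_tet=1.0, eff_bgt=1.0)


def retention_probability(
    p_5mc: np.ndarray, p_5hmc: np.ndarray, chem: ChemistryModel, treatment: str
) -> np.ndarray:
    """Per-read probability a cytosine is retained under the given treatment."""
    p_5mc = np.asarray(p_5mc, dtype=float)
    p_5hmc = np.asarray(p_5hmc, dtype=float)
    unmod = 1.0 - p_5mc - p_5hmc
    if treatment == "Bis":
        r = (p_5mc + p_5hmc) * (1 - chem.e_overconv) + unmod * chem.e_nonconv
    elif treatment == "OxBis":
        r = (
            p_5mc * (1 - chem.e_overconv)
            + p_5hmc * (1 - chem.eff_ox)
            + unmod * chem.e_nonconv
        )
    elif treatment == "TAB":
        # BGT-protected 5hmC is retained; unprotected 5hmC and TET-oxidised
        # 5mC convert; residual unoxidised 5mC behaves as modified C in Bis.
        r = (
            p_5hmc * chem.eff_bgt
            + p_5mc * (1 - chem.eff_tet) * (1 - chem.e_overconv)
            + unmod * chem.e_nonconv
        )
    else:
        raise ValueError(f"unknown treatment {treatment!r}")
    return np.clip(r, 0.0, 1.0)


@dataclass
class TrueMethylome:
    """Simulation ground truth: per-CpG (p_5mC, p_5hmC) plus the chemistry.

    ``table`` columns: chrom, pos, feature, p_5mC, p_5hmC. Positions are
    strictly increasing within a chromosome and p_5mC + p_5hmC <= 1.
    """

    table: pd.DataFrame
    chemistry: ChemistryModel = field(default_factory=ChemistryModel)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        if ((t["p_5mC"] + t["p_5hmC"]) > 1.0 + 1e-12).any():
            raise ValueError("p_5mC + p_5hmC must be <= 1 at every CpG")
        for _, grp in t.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError("positions must be strictly increasing per chrom")

    @property
    def p_5modc(self) -> np.ndarray:
        return (self.table["p_5mC"] + self.table["p_5hmC"]).to_numpy()

    def feature_intervals(self) -> list[GenomicInterval]:
        """Contiguous runs of one feature label as half-open intervals."""
        out: list[GenomicInterval] = []
        for chrom, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            feat = grp["feature"].to_numpy()
            brk = np.flatnonzero(feat[1:] != feat[:-1]) + 1
            starts = np.concatenate(([0], brk))
            ends = np.concatenate((brk, [len(feat)]))
            for i, j in zip(starts, ends):
                out.append(
                    GenomicInterval(chrom, int(pos[i]), int(pos[j - 1]) + 2, str(feat[i]))
                )
        return out


# Beta-distribution means/concentrations per chromatin feature, shaped after
# the observed genomic 5hmC landscape: enhancers and transcribed regions
# carry the highest 5hmC, active-promoter and CGI CpGs are largely
# unmethylated and 5hmC-depleted.
DEFAULT_LEVEL_MODEL: dict[str, dict[str, float]] = {
    "TssA": {"mc_mean": 0.10, "mc_conc": 10, "hmc_mean": 0.01, "hmc_conc": 30},
    "TssAFlnk": {"mc_mean": 0.50, "mc_conc": 8, "hmc_mean": 0.06, "hmc_conc": 20},
    "Tx": {"mc_mean": 0.75, "mc_conc": 8, "hmc_mean": 0.15, "hmc_conc": 15},
    "Enh": {"mc_mean": 0.55, "mc_conc": 8, "hmc_mean": 0.20, "hmc_conc": 15},
    "CGI": {"mc_mean": 0.05, "mc_conc": 15, "hmc_mean": 0.005, "hmc_conc": 50},
    "Quies": {"mc_mean": 0.70, "mc_conc": 8, "hmc_mean": 0.04, "hmc_conc": 25},
}

DEFAULT_FEATURE_MIX: dict[str, float] = {
    "TssA": 0.05,
    "TssAFlnk": 0.05,
    "Tx": 0.35,
    "Enh": 0.10,
    "CGI": 0.10,
    "Quies": 0.35,
}


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-9), 1 - 1e-9)
    return mean * conc, (1 - mean) * conc


def simulate_methylome(
    n_cpg: int,
    feature_mix: dict[str, float] | None = None,
    level_model: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
    chemistry: ChemistryModel | None = None,
    chrom: str = "chrS",
    mean_spacing: int = 100,
    block_size: int = 50,
) -> TrueMethylome:
    """Draw a ground-truth methylome of ``n_cpg`` CpGs on one chromosome.

    Feature labels are assigned in contiguous blocks of ~``block_size``
    CpGs drawn from ``feature_mix``, so that interval-level analyses see
    coherent feature territories. Within a feature, p_5mC and p_5hmC are
    drawn from the feature's beta distributions; p_5mC is then capped at
    1 - p_5hmC so the two proportions remain a valid pair (the 5hmC
    marginal keeps its configured beta mean).
    """
    if n_cpg < 1:
        raise ValueError("n_cpg must be >= 1")
    feature_mix = dict(feature_mix or DEFAULT_FEATURE_MIX)
    level_model = level_model or DEFAULT_LEVEL_MODEL
    total = sum(feature_mix.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"feature_mix proportions must sum to 1, got {total}")
    missing = set(feature_mix) - set(level_model)
    if missing:
        raise ValueError(f"feature_mix labels without level model: {sorted(missing)}")
    rng = np.random.default_rng(seed)

    gaps = rng.geometric(1.0 / mean_spacing, size=n_cpg) + 1
    pos = np.cumsum(gaps)

    labels = list(feature_mix)
    probs = np.array([feature_mix[f] for f in labels])
    n_blocks = int(np.ceil(n_cpg / block_size))
    block_labels = rng.choice(len(labels), size=n_blocks, p=probs / probs.sum())
    feat_idx = np.repeat(block_labels, block_size)[:n_cpg]
    features = np.array(labels, dtype=object)[feat_idx]

    p_5mc = np.empty(n_cpg)
    p_5hmc = np.empty(n_cpg)
    for i, lab in enumerate(labels):
        mask = feat_idx == i
        if not mask.any():
            continue
        cfg = level_model[lab]
        a, b = _beta_params(cfg["hmc_mean"], cfg["hmc_conc"])
        hm = rng.beta(a, b, size=mask.sum()) if cfg["hmc_mean"] > 0 else np.zeros(mask.sum())
        a, b = _beta_params(cfg["mc_mean"], cfg["mc_conc"])
        mc = rng.beta(a, b, size=mask.sum())
        p_5hmc[mask] = hm
        p_5mc[mask] = np.minimum(mc, 1.0 - hm)

    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "feature": features,
            "p_5mC": p_5mc,
            "p_5hmC": p_5hmc,
        }
    )
    sizes = {chrom: int(pos[-1]) + mean_spacing}
    return TrueMethylome(table, chemistry or ChemistryModel(), sizes)


def simulate_bisoxbis_counts(
    truth: TrueMethylome,
    mean_coverage: float | tuple[float, float] = (18.0, 16.0),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw paired Bis/OxBis count tables from the truth.

    Coverage is Poisson with the given mean (scalar, or a (Bis, OxBis)
    pair; the defaults are the 18x/16x study coverages), drawn
    independently per treatment; retained counts are Binomial(N, r) with r
    given by :func:`retention_probability`.
    """
    if np.isscalar(mean_coverage):
        cov_bis = cov_ox = float(mean_coverage)
    else:
        cov_bis, cov_ox = map(float, mean_coverage)
    if cov_bis <= 0 or cov_ox <= 0:
        raise ValueError("mean_coverage must be > 0")
    rng = np.random.default_rng(seed)
    t = truth.table
    p_mc = t["p_5mC"].to_numpy()
    p_hmc = t["p_5hmC"].to_numpy()
    out = []
    for treatment, cov in (("Bis", cov_bis), ("OxBis", cov_ox)):
        n = rng.poisson(cov, size=len(t))
        r = retention_probability(p_mc, p_hmc, truth.chemistry, treatment)
        nc = rng.binomial(n, r)
        df = pd.DataFrame(
            {"chrom": t["chrom"], "pos": t["pos"], "NC": nc, "N": n}
        )
        df.attrs["treatment"] = treatment
        out.append(df)
    return out[0], out[1]


def simulate_array_betas(
    truth: TrueMethylome,
    n_replicates: int = 2,
    noise_sd: float = 0.02,
    detection_fail_rate: float = 0.0,
    seed: int | None = None,
    detection_threshold: float = 0.01,
) -> pd.DataFrame:
    """Array-style beta table: one probe per CpG, Bis and OxBis arms.

    Betas are the chemistry-adjusted expected retention clamped to [0, 1]
    after additive Gaussian noise. Detection p-values are drawn below the
    threshold for passing probes and uniform above it for the configured
    failing fraction.

    Columns: probe_id, chrom, pos, then beta_<T>_<r> and detp_<T>_<r> for
    T in {Bis, OxBis} and r in 1..n_replicates.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= detection_fail_rate <= 1:
        raise ValueError("detection_fail_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = truth.table
    n = len(t)
    data: dict[str, np.ndarray | pd.Series] = {
        "probe_id": np.array([f"cg{i:08d}" for i in range(n)], dtype=object),
        "chrom": t["chrom"].to_numpy(),
        "pos": t["pos"].to_numpy(),
    }
    for treatment in ("Bis", "OxBis"):
        expect = retention_probability(
            t["p_5mC"].to_numpy(), t["p_5hmC"].to_numpy(), truth.chemistry, treatment
        )
        for rep in range(1, n_replicates + 1):
            beta = expect + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else expect.copy()
            data[f"beta_{treatment}_{rep}"] = np.clip(beta, 0.0, 1.0)
            fail = rng.random(n) < detection_fail_rate
            detp = rng.uniform(0.0, detection_threshold, size=n)
            detp[fail] = rng.uniform(detection_threshold, 1.0, size=int(fail.sum()))
            data[f"detp_{treatment}_{rep}"] = detp
    return pd.DataFrame(data)


def default_enrichment(avg_hmc: np.ndarray) -> np.ndarray:
    """IP/input enrichment as a function of tile-average 5hmC (affine, 10x
    at full hydroxymethylation)."""
    return 1.0 + 9.0 * np.asarray(avg_hmc, dtype=float)


def simulate_hmedip(
    truth: TrueMethylome,
    tile_width: int = 300,
    n_ip_reps: int = 2,
    background_mean: float = 15.0,
    enrichment_fn=default_enrichment,
    dispersion: float = 0.01,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[GenomicInterval]]:
    """hMeDIP-style tile counts: Poisson input, NB-enriched IP replicates.

    Tiles cover each truth chromosome; the per-tile IP mean is
    ``background_mean * enrichment_fn(tile-average true 5hmC)`` with
    negative-binomial noise at the given dispersion. Returns the tile count
    table (columns chrom, start, end, avg_hmc, ip1..ipK, input) and the
    list of truly enriched tiles (enrichment > 1).
    """
    if tile_width <= 0:
        raise ValueError("tile_width must be > 0")
    if n_ip_reps < 1:
        raise ValueError("n_ip_reps must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, grp in truth.table.groupby("chrom", sort=False):
        size = truth.chrom_sizes.get(chrom, int(grp["pos"].max()) + tile_width)
        n_tiles = int(np.ceil(size / tile_width))
        starts = np.arange(n_tiles, dtype=np.int64) * tile_width
        ends = np.minimum(starts + tile_width, size)
        pos = grp["pos"].to_numpy()
        hmc = grp["p_5hmC"].to_numpy()
        idx = np.clip(pos // tile_width, 0, n_tiles - 1)
        sums = np.bincount(idx, weights=hmc, minlength=n_tiles)
        cnts = np.bincount(idx, minlength=n_tiles)
        avg = np.divide(sums, cnts, out=np.zeros(n_tiles), where=cnts > 0)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "avg_hmc": avg})
        )
    tiles = pd.concat(frames, ignore_index=True)
    enrich = np.asarray(enrichment_fn(tiles["avg_hmc"].to_numpy()), dtype=float)
    tiles["input"] = rng.poisson(background_mean, size=len(tiles))
    mu = background_mean * enrich
    for rep in range(1, n_ip_reps + 1):
        if dispersion > 0:
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, mu / shape)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)
        tiles[f"ip{rep}"] = counts
    true_peaks = [
        GenomicInterval(c, int(s), int(e), "enriched")
        for c, s, e, g in zip(tiles["chrom"], tiles["start"], tiles["end"], enrich)
        if g > 1.0
    ]
    cols = ["chrom", "start", "end", "avg_hmc"] + [f"ip{r}" for r in range(1, n_ip_reps + 1)] + ["input"]
    return tiles[cols], true_peaks


SPIKEIN_KINDS = {
    # control identity -> modification state of its assayed cytosines
    "lambda_5mC": "5mC",
    "pUC18_5hmC": "5hmC",
    "APC_5hmC": "5hmC",
}


def simulate_spikein(
    kind: str,
    n_sites: int = 50,
    depth: int = 1000,
    chem: ChemistryModel | None = None,
    seed: int | None = None,
    assays: tuple[str, ...] = ("Bis", "OxBis", "TAB"),
) -> pd.DataFrame:
    """Spike-in control counts per site and assay.

    Each control contributes ``n_sites`` fully modified sites (state fixed
    by the control identity) plus ``n_sites`` unmodified cytosines that
    report the bisulphite non-conversion error. Columns: site, state,
    assay, retained, converted.
    """
    if kind not in SPIKEIN_KINDS:
        raise ValueError(f"unknown spike-in kind {kind!r}; expected {sorted(SPIKEIN_KINDS)}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    chem = chem or ChemistryModel()
    rng = np.random.default_rng(seed)
    state = SPIKEIN_KINDS[kind]
    p_mc = 1.0 if state == "5mC" else 0.0
    p_hmc = 1.0 if state == "5hmC" else 0.0
    rows = []
    for assay in assays:
        r_mod = float(retention_probability(np.array(p_mc), np.array(p_hmc), chem, assay))
        r_unmod = float(retention_probability(np.array(0.0), np.array(0.0), chem, assay))
        for st, r in ((state, r_mod), ("unmodified", r_unmod)):
            ret = rng.binomial(depth, r, size=n_sites)
            for site in range(n_sites):
                rows.append((f"{kind}_{st}_{site}", st, assay, int(ret[site]), depth - int(ret[site])))
    return pd.DataFrame(rows, columns=["site", "state", "assay", "retained", "converted"])


def simulate_amplicon_reads(
    region_truth: np.ndarray,
    n_reads: int,
    mosaicity: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Single-molecule read matrix for one amplicon.

    ``region_truth`` gives the marginal modification level per CpG.
    ``mosaicity`` interpolates between all-or-none molecules (0: each read
    is fully modified with probability equal to the mean marginal level)
    and independent per-CpG sampling (1). Returns a reads x CpGs binary
    DataFrame.
    """
    levels = np.asarray(region_truth, dtype=float)
    if levels.ndim != 1 or levels.size < 1:
        raise ValueError("region_truth must be a non-empty 1-D array of levels")
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("marginal levels must be in [0, 1]")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= mosaicity <= 1:
        raise ValueError("mosaicity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cpg = levels.size
    independent = rng.random(n_reads) < mosaicity
    mat = np.zeros((n_reads, n_cpg), dtype=np.int8)
    n_ind = int(independent.sum())
    if n_ind:
        mat[independent] = rng.random((n_ind, n_cpg)) < levels
    n_homo = n_reads - n_ind
    if n_homo:
        allmod = rng.random(n_homo) < levels.mean()
        mat[~independent] = allmod[:, None].astype(np.int8)
    return pd.DataFrame(mat, columns=[f"cpg{j + 1}" for j in range(n_cpg)])
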