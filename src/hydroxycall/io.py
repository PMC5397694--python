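"""Readers and writers for the tabular/interval formats the pipeline touches.

Internal coordinate convention is 0-based half-open (BED-native) everywhere.
The bismark-coverage dialect (1-based inclusive) is converted at the
boundary so no other module ever sees 1-based positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CPG_COUNT_COLUMNS = ["chrom", "pos", "NC", "N"]

#: recognised count-table dialects
CPG_DIALECTS = ("bismark_cov", "bedgraph_pair", "tsv")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("interval chrom must be non-empty")
        if self.start >= self.end:
            raise FormatError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    """Tabulate intervals as a chrom/start/end/name DataFrame."""
    rows = [(iv.chrom, iv.start, iv.end, iv.name) for iv in intervals]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    name = df["name"] if "name" in df.columns else [None] * len(df)
    return [
        GenomicInterval(c, int(s), int(e), n)
        for c, s, e, n in zip(df["chrom"], df["start"], df["end"], name)
    ]


def _validate_counts(df: pd.DataFrame, path: str) -> pd.DataFrame:
    nc, n = df["NC"].to_numpy(), df["N"].to_numpy()
    bad = np.flatnonzero((nc < 0) | (n < 0) | (nc > n))
    if bad.size:
        # +2 accounts for 0-based index and a header-less first data line
        raise FormatError(
            f"{path}: line {bad[0] + 1}: retained count outside [0, N] "
            f"(NC={nc[bad[0]]}, N={n[bad[0]]})"
        )
    if df.duplicated(["chrom", "pos"]).any():
        raise FormatError(f"{path}: duplicate (chrom, pos) records")
    return df


def read_cpg_counts(path, dialect: str = "bismark_cov", treatment: str | None = None) -> pd.DataFrame:
    """Read a per-CpG count table into the internal 0-based representation.

    Parameters
    ----------
    path : str or Path
        Input file.
    dialect : {"bismark_cov", "bedgraph_pair", "tsv"}
        ``bismark_cov`` is the bismark coverage format
        (chrom, start1, end1, pct, n_meth, n_unmeth; 1-based inclusive);
        ``bedgraph_pair`` is the same but 0-based half-open;
        ``tsv`` is a headered chrom/pos/NC/N table already 0-based.
    treatment : str, optional
        Tag stored in ``df.attrs["treatment"]`` (e.g. "Bis", "OxBis", "TAB").

    Returns
    -------
    pandas.DataFrame with columns chrom, pos, NC, N.
    """
    if dialect not in CPG_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {CPG_DIALECTS}")
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = set(CPG_COUNT_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        df = df[CPG_COUNT_COLUMNS].copy()
    else:
        names = ["chrom", "start", "end", "pct", "n_meth", "n_unmeth"]
        try:
            raw = pd.read_csv(path, sep="\t", header=None, names=names,
                              dtype={"chrom": str})
        except pd.errors.EmptyDataError:
            logger.warning("%s: empty count table", path)
            return pd.DataFrame(columns=CPG_COUNT_COLUMNS)
        offset = 1 if dialect == "bismark_cov" else 0
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": raw["start"].astype(np.int64) - offset,
                "NC": raw["n_meth"].astype(np.int64),
                "N": (raw["n_meth"] + raw["n_unmeth"]).astype(np.int64),
            }
        )
    if df.empty:
        logger.warning("%s: empty count table", path)
        return pd.DataFrame(columns=CPG_COUNT_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    df["NC"] = df["NC"].astype(np.int64)
    df["N"] = df["N"].astype(np.int64)
    _validate_counts(df, str(path))
    if treatment is not None:
        df.attrs["treatment"] = treatment
    return df


def write_cpg_counts(df: pd.DataFrame, path, dialect: str = "bismark_cov") -> None:
    """Write a count table; exact inverse of :func:`read_cpg_counts`."""
    if dialect not in CPG_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "tsv":
        df[CPG_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)
        return
    offset = 1 if dialect == "bismark_cov" else 0
    n = df["N"].to_numpy()
    nc = df["NC"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n > 0, 100.0 * nc / np.maximum(n, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"] + offset,
            "end": df["pos"] + offset if dialect == "bismark_cov" else df["pos"] + 1,
            "pct": pct,
            "n_meth": nc,
            "n_unmeth": n - nc,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def read_intervals(path, fmt: str = "bed") -> list[GenomicInterval]:
    """Read BED3/BED4+ intervals (0-based half-open, label from column 4).

    Overlapping intervals are preserved as-is; no merging is performed.
    """
    if fmt != "bed":
        raise ValueError(f"unknown interval format {fmt!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 else None
            try:
                out.append(GenomicInterval(fields[0], start, end, name, score, strand))
            except FormatError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                fields.append(iv.name)
            fh.write("\t".join(fields) + "\n")


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def subtract_intervals(
    minuend: list[tuple[int, int]], subtrahend: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set-subtract merged ``subtrahend`` from each interval in ``minuend``."""
    sub = _merge(subtrahend)
    out: list[tuple[int, int]] = []
    for s, e in minuend:
        cur = s
        for bs, be in sub:
            if be <= cur:
                continue
            if bs >= e:
                break
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def cgi_shores(
    cgis: Sequence[GenomicInterval],
    flank: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """CpG-island shores: the +/-`flank` bp flanks of each island.

    Shore bases falling inside *any* island (including neighbours) are
    removed, and shores are clipped at position 0 and at the chromosome end
    when ``chrom_sizes`` is given.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in cgis:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    shores: list[GenomicInterval] = []
    for iv in cgis:
        limit = chrom_sizes.get(iv.chrom) if chrom_sizes else None
        cands = [(max(0, iv.start - flank), iv.start)]
        right_end = iv.end + flank if limit is None else min(iv.end + flank, limit)
        cands.append((iv.end, right_end))
        cands = [(s, e) for s, e in cands if s < e]
        for s, e in subtract_intervals(cands, by_chrom[iv.chrom]):
            shores.append(GenomicInterval(iv.chrom, s, e, "shore"))
    return shores
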