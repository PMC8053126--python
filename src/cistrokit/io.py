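"""Readers and writers for the standard text formats the pipeline exchanges.

BED (3 or 6 columns, 0-based half-open), bedGraph, FASTA, and headered
tab-separated DE / TSS tables. Chromosome names are matched by exact string
equality throughout — no "chr" aliasing.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import CoverageTrack
from .intervals import GenomicInterval, PeakSet, VALID_STRANDS

PathLike = Union[str, Path]

GENOME_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# BED

def read_bed(path: PathLike, label: Optional[str] = None) -> PeakSet:
    """Read a BED3/BED6 file into a sorted :class:`PeakSet`.

    Coordinates are taken as 0-based half-open per the BED standard; ``track``
    and ``browser`` lines and blank lines are skipped.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = None
            if len(fields) > 5:
                if fields[5] not in VALID_STRANDS:
                    raise ParseError(
                        f"{path}:{lineno}: unknown strand symbol {fields[5]!r}"
                    )
                strand = fields[5]
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals, label=label if label is not None else Path(path).stem)


def write_bed(peaks: PeakSet, path: PathLike) -> None:
    """Write BED3, or BED6 when any interval carries name/score/strand."""
    six = any(
        iv.name is not None or iv.score is not None or iv.strand is not None
        for iv in peaks
    )
    with open(path, "w") as fh:
        for iv in peaks:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand or '.'}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path: PathLike, chrom_lengths: Mapping[str, int]) -> CoverageTrack:
    """Read a 4-column bedGraph into a uniformly binned :class:`CoverageTrack`.

    The bin width is inferred as the GCD of all interval boundaries (input
    lines must tile whole bins); uncovered bins are 0. Overlapping input
    lines and non-finite values are errors; negative values are allowed.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            if chrom not in chrom_lengths:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed line") from exc
            if start >= end or start < 0 or end > chrom_lengths[chrom]:
                raise ParseError(f"{path}:{lineno}: bad span [{start}, {end})")
            if not math.isfinite(value):
                raise ParseError(f"{path}:{lineno}: non-finite value")
            rows.append((chrom, start, end, value, lineno))

    g = 0
    for _, start, end, _, _ in rows:
        g = math.gcd(g, start)
        g = math.gcd(g, end)
    bin_width = g if g > 0 else 1

    track = CoverageTrack.zeros(bin_width, chrom_lengths)
    covered = {c: np.zeros(len(v), dtype=bool) for c, v in track.values.items()}
    for chrom, start, end, value, lineno in rows:
        i0, i1 = start // bin_width, -(-end // bin_width)
        if covered[chrom][i0:i1].any():
            raise ParseError(f"{path}:{lineno}: overlapping bedGraph lines")
        covered[chrom][i0:i1] = True
        track.values[chrom][i0:i1] = value
    track._cum.clear()
    return track


def write_bedgraph(track: CoverageTrack, path: PathLike, precision: int = 6) -> None:
    """Write a bedGraph, merging runs of equal-valued adjacent bins.

    Zero-valued runs are written too, so a round-trip through
    :func:`read_bedgraph` reconstructs the track exactly (within the printed
    precision).
    """
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            L = track.chrom_lengths[chrom]
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for i0, i1 in zip(starts, ends):
                fh.write(
                    f"{chrom}\t{i0 * w}\t{min(i1 * w, L)}\t"
                    f"{round(float(vals[i0]), precision):g}\n"
                )


# ---------------------------------------------------------------------------
# FASTA / genome

class GenomeSequence:
    """A genome as a mapping chromosome -> uppercase sequence over A,C,G,T,N."""

    __slots__ = ("seqs",)

    def __init__(self, seqs: Mapping[str, str], validate: bool = True):
        self.seqs: Dict[str, str] = {}
        for chrom, seq in seqs.items():
            seq = str(seq).upper()
            if validate and (set(seq) - GENOME_ALPHABET):
                bad = sorted(set(seq) - GENOME_ALPHABET)
                raise ValueError(f"{chrom}: characters outside A/C/G/T/N: {bad}")
            self.seqs[chrom] = seq

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence over the clipped span ``[max(start,0), min(end, len))``."""
        if chrom not in self.seqs:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        return self.seqs[chrom][max(start, 0): end]


def read_fasta(path: PathLike) -> GenomeSequence:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# DE and TSS tables

def read_de_table(
    path: PathLike,
    gene_col: str = "gene_id",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
) -> pd.DataFrame:
    """Read a differential-expression table (TSV with a header).

    Returns a DataFrame with columns ``gene_id`` (str), ``log2fc`` (float)
    and ``padj`` (float, NaN when missing). Duplicate genes and non-numeric
    fold changes are errors; ``padj`` values like "NA" become missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={gene_col: str})
    for col in (gene_col, lfc_col, padj_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out = pd.DataFrame(
        {
            "gene_id": df[gene_col].astype(str),
            "log2fc": pd.to_numeric(df[lfc_col], errors="coerce"),
            "padj": pd.to_numeric(df[padj_col], errors="coerce"),
        }
    )
    if out["log2fc"].isna().any() and df[lfc_col].notna().any():
        bad = df.loc[out["log2fc"].isna() & df[lfc_col].notna(), lfc_col]
        if len(bad):
            raise ParseError(f"{path}: non-numeric log2fc value {bad.iloc[0]!r}")
    if out["log2fc"].isna().any():
        raise ParseError(f"{path}: missing log2fc values")
    dup = out["gene_id"].duplicated()
    if dup.any():
        raise ParseError(f"{path}: duplicate gene_id {out.loc[dup, 'gene_id'].iloc[0]!r}")
    valid = out["padj"].dropna()
    if ((valid < 0) | (valid > 1)).any():
        raise ParseError(f"{path}: padj outside [0, 1]")
    return out.reset_index(drop=True)


def write_de_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tss_table(path: PathLike) -> pd.DataFrame:
    """Read a TSS annotation (TSV: gene_id, chrom, tss, strand); tss is 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    for col in ("gene_id", "chrom", "tss", "strand"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["tss"] = pd.to_numeric(df["tss"], errors="raise").astype(int)
    if (df["tss"] < 0).any():
        raise ParseError(f"{path}: negative TSS position")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene_id")
    return df[["gene_id", "chrom", "tss", "strand"]]


def write_tss_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
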