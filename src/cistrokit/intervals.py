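"""Genomic intervals and peak sets.

All coordinates are 0-based half-open (BED convention). Coordinates printed
1-based inclusive (the genome-browser convention) must be converted on
ingest with :func:`to_zero_based`; keeping a single internal
convention eliminates off-by-one drift between modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Optional, Tuple

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic range ``[start, end)`` on ``chrom``.

    Ordering (and therefore :class:`PeakSet` sorting) uses only
    ``(chrom, start, end)``; the optional annotation fields do not
    participate in comparisons.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = field(default=None, compare=False)
    score: Optional[float] = field(default=None, compare=False)
    strand: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand is not None and self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Peak center, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2


def peak_center(interval: GenomicInterval) -> int:
    """Center of an interval; ties (odd length) round down."""
    return interval.center


def to_zero_based(chrom: str, start1: int, end1: int, **kwargs) -> GenomicInterval:
    """Convert 1-based inclusive coordinates to a half-open interval.

    A printed range ``chrN:start1-end1`` of length ``end1 - start1 + 1``
    becomes ``[start1 - 1, end1)`` internally.
    """
    if start1 < 1:
        raise ValueError(f"1-based start must be >= 1, got {start1}")
    if start1 > end1:
        raise ValueError(f"1-based start {start1} exceeds end {end1}")
    return GenomicInterval(chrom, start1 - 1, end1, **kwargs)


class PeakSet:
    """An immutable, sorted collection of :class:`GenomicInterval`.

    Intervals are sorted by ``(chrom, start, end)``. Overlap among members is
    allowed (replicate peak calls may overlap each other).
    """

    __slots__ = ("label", "intervals", "_by_chrom")

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = ""):
        self.label = label
        self.intervals: Tuple[GenomicInterval, ...] = tuple(sorted(intervals))
        self._by_chrom: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __hash__(self) -> int:
        return hash(self.intervals)

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(dict.fromkeys(iv.chrom for iv in self.intervals))

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends)`` arrays, sorted by start."""
        if self._by_chrom is None:
            out: Dict[str, Tuple[list, list]] = {}
            for iv in self.intervals:
                out.setdefault(iv.chrom, ([], []))
                out[iv.chrom][0].append(iv.start)
                out[iv.chrom][1].append(iv.end)
            self._by_chrom = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in out.items()
            }
        return self._by_chrom

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "PeakSet":
        def _opt(row, col, cast):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v) else cast(v)

        ivs = [
            GenomicInterval(
                str(row["chrom"]),
                int(row["start"]),
                int(row["end"]),
                name=_opt(row, "name", str),
                score=_opt(row, "score", float),
                strand=_opt(row, "strand", str),
            )
            for row in df.to_dict("records")
        ]
        return cls(ivs, label=label)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """BEDtools semantics: >= 1 bp of shared sequence on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_mask(query: PeakSet, subject: PeakSet) -> np.ndarray:
    """Boolean array: for each query interval, does it overlap any subject interval?

    Uses the sorted-starts / cumulative-max-ends sweep: an interval ``[s, e)``
    overlaps some subject iff among subjects with ``start < e`` the maximum
    ``end`` exceeds ``s``.
    """
    subj = subject.by_chrom()
    cummax = {c: np.maximum.accumulate(ends) for c, (starts, ends) in subj.items()}
    out = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query.intervals):
        if iv.chrom not in subj:
            continue
        starts, _ = subj[iv.chrom]
        idx = int(np.searchsorted(starts, iv.end, side="left"))
        if idx > 0 and cummax[iv.chrom][idx - 1] > iv.start:
            out[i] = True
    return out
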