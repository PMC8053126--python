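"""Cistrome interval algebra.

Replicate reproducibility, blacklist/contig exclusion, shared-vs-specific
categorization of two factors' peak sets, accessibility-ranked subsetting and
seeded random sampling. Overlap is BEDtools-style: >= 1 shared bp, no
fraction-of-overlap option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .coverage import CoverageTrack
from .intervals import GenomicInterval, PeakSet, overlap_mask, overlaps, peak_center

__all__ = [
    "CistromeCategories",
    "RankedPeaks",
    "overlaps",
    "reproducible_peaks",
    "remove_excluded",
    "categorize",
    "rank_by_signal",
    "accessibility_subsets",
    "random_sample",
]

DEFAULT_EXCLUDED_PREFIXES = ("chrUn",)
DEFAULT_EXCLUDED_CHROMS = ("chrM",)


@dataclass(frozen=True)
class CistromeCategories:
    """Shared and factor-specific peak sets for a two-factor comparison.

    ``shared`` carries factor-A coordinates (first-file intersect semantics);
    which factor plays "A" is the caller's choice. Invariants — specific
    peaks overlap nothing of the other factor, and shared plus A-specific
    partition the A peaks — are asserted at construction.
    """

    shared: PeakSet
    a_specific: PeakSet
    b_specific: PeakSet


def reproducible_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Peaks of ``rep1`` overlapping >= 1 bp with any ``rep2`` peak.

    Coordinates of the first replicate are retained (``bedtools intersect -u``
    semantics).
    """
    mask = overlap_mask(rep1, rep2)
    return PeakSet(
        (iv for iv, m in zip(rep1, mask) if m), label=rep1.label
    )


def remove_excluded(
    peaks: PeakSet,
    blacklist: Optional[PeakSet] = None,
    excluded_prefixes: Sequence[str] = DEFAULT_EXCLUDED_PREFIXES,
    excluded_chroms: Sequence[str] = DEFAULT_EXCLUDED_CHROMS,
) -> PeakSet:
    """Drop peaks on excluded chromosomes or overlapping blacklisted regions.

    Defaults exclude unassigned contigs (names starting ``chrUn``) and the
    mitochondrial chromosome (``chrM`` exactly).
    """
    keep = np.ones(len(peaks), dtype=bool)
    for i, iv in enumerate(peaks):
        if iv.chrom in excluded_chroms or any(
            iv.chrom.startswith(p) for p in excluded_prefixes
        ):
            keep[i] = False
    if blacklist is not None and len(blacklist):
        keep &= ~overlap_mask(peaks, blacklist)
    return PeakSet((iv for iv, k in zip(peaks, keep) if k), label=peaks.label)


def categorize(peaks_a: PeakSet, peaks_b: PeakSet) -> CistromeCategories:
    """Split two final peak sets into shared / A-specific / B-specific.

    shared: A peaks overlapping any B peak (A coordinates kept);
    a_specific: A peaks overlapping none; b_specific: B peaks overlapping no
    A peak. ``|shared| + |a_specific| == |peaks_a|`` by construction, and the
    specificity invariants are re-checked exhaustively before returning.
    """
    a_in_b = overlap_mask(peaks_a, peaks_b)
    b_in_a = overlap_mask(peaks_b, peaks_a)
    shared = PeakSet((iv for iv, m in zip(peaks_a, a_in_b) if m), label="shared")
    a_specific = PeakSet(
        (iv for iv, m in zip(peaks_a, a_in_b) if not m), label="a_specific"
    )
    b_specific = PeakSet(
        (iv for iv, m in zip(peaks_b, b_in_a) if not m), label="b_specific"
    )
    # exhaustive consistency check: no specific peak touches the other factor
    if overlap_mask(a_specific, peaks_b).any():
        raise AssertionError("a_specific peak overlaps a B peak")
    if overlap_mask(b_specific, peaks_a).any():
        raise AssertionError("b_specific peak overlaps an A peak")
    assert len(shared) + len(a_specific) == len(peaks_a)
    return CistromeCategories(shared=shared, a_specific=a_specific, b_specific=b_specific)


@dataclass(frozen=True)
class RankedPeaks:
    """Peaks ordered by descending mean signal; ties by (chrom, start)."""

    intervals: Tuple[GenomicInterval, ...]
    signals: np.ndarray  # non-increasing, aligned with intervals

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.signals):
            raise ValueError("intervals and signals differ in length")
        if len(self.signals) > 1 and np.any(np.diff(self.signals) > 1e-12):
            raise ValueError("signals must be non-increasing")

    def __len__(self) -> int:
        return len(self.intervals)


def rank_by_signal(
    peaks: PeakSet, track: CoverageTrack, halfwidth: int
) -> RankedPeaks:
    """Rank peaks by mean track signal over ``[center - hw, center + hw)``.

    The averaging window is clipped at chromosome ends (the denominator
    shrinks; terminal peaks are not zero-penalized in rankings). Descending
    order; exact signal ties break by (chrom, start) ascending.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    sigs = np.empty(len(peaks))
    for chrom, idx in _group_indices(peaks):
        if chrom not in track.values:
            raise KeyError(f"peak chromosome {chrom!r} absent from track")
        centers = np.array([peaks[i].center for i in idx], dtype=np.int64)
        sigs[idx] = track.means(chrom, centers - halfwidth, centers + halfwidth)
    order = sorted(
        range(len(peaks)),
        key=lambda i: (-sigs[i], peaks[i].chrom, peaks[i].start),
    )
    return RankedPeaks(
        intervals=tuple(peaks[i] for i in order), signals=sigs[np.array(order, dtype=int)]
        if len(order) else sigs,
    )


def _group_indices(peaks: PeakSet):
    groups: dict = {}
    for i, iv in enumerate(peaks):
        groups.setdefault(iv.chrom, []).append(i)
    for chrom, idx in groups.items():
        yield chrom, np.asarray(idx, dtype=int)


def accessibility_subsets(
    ranked: RankedPeaks,
    k_low: int,
    k_high: int,
    accessible_calls: Optional[PeakSet] = None,
) -> Tuple[PeakSet, PeakSet]:
    """Bottom-k and top-k cuts of an accessibility ranking.

    ``low`` is the last ``k_low`` entries of the descending ranking with any
    peak overlapping an accessible-chromatin call removed afterwards (so the
    returned set may be smaller than ``k_low``); ``high`` is the first
    ``k_high`` entries, unfiltered.
    """
    n = len(ranked)
    if k_low > n or k_high > n:
        raise ValueError(f"k ({k_low}, {k_high}) exceeds ranking size {n}")
    low_ivs = ranked.intervals[n - k_low:] if k_low > 0 else ()
    low = PeakSet(low_ivs, label="low_accessibility")
    if accessible_calls is not None and len(accessible_calls) and len(low):
        mask = overlap_mask(low, accessible_calls)
        low = PeakSet(
            (iv for iv, m in zip(low, mask) if not m), label="low_accessibility"
        )
    high = PeakSet(ranked.intervals[:k_high], label="high_accessibility")
    return low, high


def random_sample(peaks: PeakSet, k: int, seed: int) -> PeakSet:
    """Sample ``k`` distinct peaks, reproducibly for a given seed."""
    if k > len(peaks):
        raise ValueError(f"cannot sample {k} from {len(peaks)} peaks")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(peaks), size=k, replace=False)
    return PeakSet((peaks[int(i)] for i in idx), label=peaks.label)
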