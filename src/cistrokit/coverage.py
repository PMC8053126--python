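"""Binned per-chromosome coverage tracks.

A :class:`CoverageTrack` stores one value per fixed-width bin for each
chromosome (the terminal bin may be shorter). The per-base value at position
``p`` is the value of the bin containing ``p``; interval means are therefore
width-weighted bin averages. Tracks hold RPKM-normalized coverage, GC
fractions, or any other per-bin signal.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np


class CoverageTrack:
    """Uniformly binned signal, queryable by half-open interval.

    Parameters
    ----------
    values
        Per-chromosome arrays, one value per bin; ``len(values[c]) ==
        ceil(chrom_lengths[c] / bin_width)``.
    bin_width
        Bin width in bp; the terminal bin of each chromosome covers only the
        remaining bases.
    chrom_lengths
        Declared chromosome lengths in bp.
    """

    __slots__ = ("values", "bin_width", "chrom_lengths", "_cum")

    def __init__(
        self,
        values: Mapping[str, np.ndarray],
        bin_width: int,
        chrom_lengths: Mapping[str, int],
    ):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bin_width = int(bin_width)
        self.chrom_lengths = {c: int(n) for c, n in chrom_lengths.items()}
        self.values: Dict[str, np.ndarray] = {}
        for chrom, arr in values.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"no declared length for chromosome {chrom!r}")
            arr = np.asarray(arr, dtype=float)
            n_expected = -(-self.chrom_lengths[chrom] // self.bin_width)
            if len(arr) != n_expected:
                raise ValueError(
                    f"{chrom}: expected {n_expected} bins, got {len(arr)}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{chrom}: non-finite track values")
            self.values[chrom] = arr
        self._cum: Dict[str, np.ndarray] = {}

    @classmethod
    def zeros(cls, bin_width: int, chrom_lengths: Mapping[str, int]) -> "CoverageTrack":
        vals = {
            c: np.zeros(-(-n // bin_width)) for c, n in chrom_lengths.items()
        }
        return cls(vals, bin_width, chrom_lengths)

    def _bin_widths(self, chrom: str) -> np.ndarray:
        n = len(self.values[chrom])
        w = np.full(n, self.bin_width, dtype=float)
        w[-1] = self.chrom_lengths[chrom] - (n - 1) * self.bin_width
        return w

    def _cumsum(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            totals = self.values[chrom] * self._bin_widths(chrom)
            self._cum[chrom] = np.concatenate(([0.0], np.cumsum(totals)))
        return self._cum[chrom]

    def totals(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized sum of per-base values over clipped ``[start, end)`` spans."""
        if chrom not in self.values:
            raise KeyError(f"chromosome {chrom!r} absent from track")
        L = self.chrom_lengths[chrom]
        w = self.bin_width
        v = self.values[chrom]
        s = np.clip(np.asarray(starts, dtype=np.int64), 0, L)
        e = np.clip(np.asarray(ends, dtype=np.int64), 0, L)
        out = np.zeros(len(s), dtype=float)
        nonempty = s < e
        if not np.any(nonempty):
            return out
        si, ei = s[nonempty], e[nonempty]
        i0 = si // w
        i1 = (ei - 1) // w
        cum = self._cumsum(chrom)
        tot = cum[i1 + 1] - cum[i0]
        tot -= (si - i0 * w) * v[i0]
        bin_end = np.minimum((i1 + 1) * w, L)
        tot -= (bin_end - ei) * v[i1]
        out[nonempty] = tot
        return out

    def total(self, chrom: str, start: int, end: int) -> float:
        return float(self.totals(chrom, np.array([start]), np.array([end]))[0])

    def means(
        self,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        zero_fill: bool = False,
    ) -> np.ndarray:
        """Per-base mean over ``[start, end)``.

        With ``zero_fill`` the denominator is the full requested width and
        positions beyond the chromosome contribute 0 (reference-point matrix
        convention); otherwise the window is clipped and the denominator
        shrinks accordingly (ranking convention). Fully out-of-range windows
        yield 0.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        tot = self.totals(chrom, starts, ends)
        if zero_fill:
            denom = (ends - starts).astype(float)
        else:
            L = self.chrom_lengths[chrom]
            denom = (np.clip(ends, 0, L) - np.clip(starts, 0, L)).astype(float)
        out = np.zeros_like(tot)
        ok = denom > 0
        out[ok] = tot[ok] / denom[ok]
        return out

    def mean(self, chrom: str, start: int, end: int, zero_fill: bool = False) -> float:
        return float(
            self.means(chrom, np.array([start]), np.array([end]), zero_fill=zero_fill)[0]
        )

    def value_at(self, chrom: str, pos: int) -> float:
        if not (0 <= pos < self.chrom_lengths[chrom]):
            raise IndexError(f"position {pos} outside {chrom}")
        return float(self.values[chrom][pos // self.bin_width])

    def per_base(self, chrom: str) -> np.ndarray:
        """Expand to a per-base array (small fixtures / oracles only)."""
        L = self.chrom_lengths[chrom]
        return np.repeat(self.values[chrom], self.bin_width)[:L]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return (
            self.bin_width == other.bin_width
            and self.chrom_lengths == other.chrom_lengths
            and set(self.values) == set(other.values)
            and all(np.array_equal(self.values[c], other.values[c]) for c in self.values)
        )
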