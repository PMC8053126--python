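"""PWM scanning and AME-style motif enrichment.

Position count matrices (JASPAR text format) are converted to log-odds
scores with a background-distributed pseudocount; sequences are scanned on
both strands and hits reported when the relative score — (raw - min) /
(max - min) over the matrix's score range — clears a threshold. Enrichment
of a motif in a foreground sequence set against a background set is a
one-sided rank-sum test on per-sequence best scores, with a Bonferroni-style
E-value over the catalog; background sets are either dinucleotide-preserving
shuffles of the input or the other factor's peak sequences (the reciprocal
design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .intervals import PeakSet
from .io import GenomeSequence
from .signal import mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "LogOddsMatrix",
    "MotifHit",
    "read_jaspar",
    "log_odds",
    "scan",
    "shuffle_background",
    "extract_peak_sequences",
    "motif_enrichment",
    "builtin_motifs",
    "reverse_complement",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """A position count matrix, rows ordered A, C, G, T."""

    identifier: str
    name: str
    counts: np.ndarray  # shape (4, w), non-negative

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValueError("counts must be a 4 x w matrix")
        if (c < 0).any():
            raise ValueError("negative count in PWM")
        if (c.sum(axis=0) <= 0).any():
            raise ValueError("PWM column with no positive count")
        object.__setattr__(self, "counts", c)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class LogOddsMatrix:
    """Log2-odds scores derived from a PWM, with the matrix score range."""

    pwm: PWM
    scores: np.ndarray  # (4, w)
    max_score: float  # sum of column maxima
    min_score: float  # sum of column minima

    @property
    def width(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based, plus-strand coordinate of the window
    strand: str  # "+" or "-"
    score: float
    rel_score: float  # (raw - min) / (max - min), in [0, 1]


def read_jaspar(path: Union[str, Path]) -> List[PWM]:
    """Read PWMs from a JASPAR-format text file (">ID name" + 4 count rows)."""
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            pwms = []
            for m in records:
                counts = np.array([m.counts[b] for b in BASES], dtype=float)
                pwms.append(
                    PWM(
                        identifier=m.matrix_id or m.name or "motif",
                        name=m.name or m.matrix_id or "motif",
                        counts=counts,
                    )
                )
        except Exception as exc:
            raise ValueError(f"{path}: malformed JASPAR record ({exc})") from exc
    return pwms


def write_jaspar(pwms: Sequence[PWM], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.identifier} {p.name}\n")
            for b in BASES:
                row = " ".join(format(v, "g") for v in p.counts[BASE_INDEX[b]])
                fh.write(f"{b}  [ {row} ]\n")


def log_odds(
    pwm: PWM,
    background: Optional[Sequence[float]] = None,
    pseudocount: float = 0.8,
) -> LogOddsMatrix:
    """Log2-odds matrix with a background-distributed pseudocount.

    ``p[b, j] = (count[b, j] + pseudocount * bg[b]) / (colsum_j + pseudocount)``
    and ``score[b, j] = log2(p[b, j] / bg[b])``.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 positive frequencies summing to 1")
    colsums = pwm.counts.sum(axis=0)
    if pseudocount <= 0 and (pwm.counts == 0).any():
        raise ValueError("zero counts require a positive pseudocount")
    p = (pwm.counts + pseudocount * bg[:, None]) / (colsums + pseudocount)[None, :]
    scores = np.log2(p / bg[:, None])
    return LogOddsMatrix(
        pwm=pwm,
        scores=scores,
        max_score=float(scores.max(axis=0).sum()),
        min_score=float(scores.min(axis=0).sum()),
    )


def _seq_to_indices(seq: str) -> np.ndarray:
    """Map a sequence to 0..3 for A/C/G/T and 4 for N/anything else."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        out[arr == ord(b)] = i
    return out


def _extended_scores(lom: LogOddsMatrix) -> np.ndarray:
    """Scores with a 5th row for N, scoring as the column minimum."""
    return np.vstack([lom.scores, lom.scores.min(axis=0)])


def _window_scores(idx: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Raw scores of every window of width w over an index array."""
    w = ext.shape[1]
    n = len(idx) - w + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return ext[windows, np.arange(w)].sum(axis=1)


def _rc_scores(lom: LogOddsMatrix) -> np.ndarray:
    """Extended scores of the reverse-complement motif."""
    rc = lom.scores[::-1, ::-1]
    return np.vstack([rc, rc.min(axis=0)])


def scan(
    seq: str,
    lom: LogOddsMatrix,
    rel_threshold: float = 0.8,
    both_strands: bool = True,
    seq_id: str = "seq",
) -> List[MotifHit]:
    """All motif hits with relative score >= threshold.

    Minus-strand hits are reported at the plus-strand coordinates of the
    window. A sequence shorter than the motif yields no hits. Windows
    containing N score the column minimum at those positions.
    """
    if not (0.0 <= rel_threshold <= 1.0):
        raise ValueError("rel_threshold must be in [0, 1]")
    idx = _seq_to_indices(seq)
    span = lom.max_score - lom.min_score
    hits: List[MotifHit] = []
    strand_mats = [("+", _extended_scores(lom))]
    if both_strands:
        strand_mats.append(("-", _rc_scores(lom)))
    for strand, ext in strand_mats:
        raw = _window_scores(idx, ext)
        if span > 0:
            rel = (raw - lom.min_score) / span
        else:
            rel = np.ones_like(raw)
        for off in np.flatnonzero(rel >= rel_threshold - 1e-12):
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    offset=int(off),
                    strand=strand,
                    score=float(raw[off]),
                    rel_score=float(min(max(rel[off], 0.0), 1.0)),
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_score(seq: str, lom: LogOddsMatrix, both_strands: bool = True) -> float:
    """Best raw log-odds score over all windows (and strands) of a sequence."""
    idx = _seq_to_indices(seq)
    best = -np.inf
    mats = [_extended_scores(lom)]
    if both_strands:
        mats.append(_rc_scores(lom))
    for ext in mats:
        raw = _window_scores(idx, ext)
        if len(raw):
            best = max(best, float(raw.max()))
    return best


# ---------------------------------------------------------------------------
# Background construction

def shuffle_background(
    seqs: Sequence[str], seed: int, k: int = 2
) -> List[str]:
    """k-mer-composition-preserving shuffles (one per input sequence).

    ``k=2`` is the dinucleotide-preserving Euler-path (Altschul-Erikson)
    shuffle; ``k=1`` is a plain mononucleotide shuffle. Deterministic for a
    given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for s in seqs:
        s = s.upper()
        if k == 1:
            arr = list(s)
            rng.shuffle(arr)
            out.append("".join(arr))
        else:
            out.append(_dinucleotide_shuffle(s, rng))
    return out


def _dinucleotide_shuffle(s: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle: same length, same dinucleotide multiset."""
    if len(s) < 3:
        return s
    # adjacency lists of the dinucleotide multigraph
    edges: Dict[str, List[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    first, last = s[0], s[-1]
    vertices = list(edges)
    for _ in range(200):
        # pick a random candidate last-edge per non-terminal vertex
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        # the chosen last edges must lead every vertex to the terminal one
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - bounded retry safeguard
        return s
    shuffled: Dict[str, List[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        idx = rng.permutation(len(rest))
        ordered = [rest[i] for i in idx]
        if v in last_edge:
            ordered.append(last_edge[v])
        shuffled[v] = ordered
    # walk the Euler path
    result = [first]
    counters = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(s) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def extract_peak_sequences(
    genome: GenomeSequence, peaks: PeakSet, flank: int = 250
) -> List[str]:
    """Sequences ``[center - flank, center + flank)`` per peak, clipped at ends."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    seqs = []
    for iv in peaks:
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
        c = iv.center
        seqs.append(genome.fetch(iv.chrom, c - flank, c + flank))
    return seqs


# ---------------------------------------------------------------------------
# Enrichment

def motif_enrichment(
    fg_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    pwms: Sequence[PWM],
    evalue_threshold: float = 1e-30,
    background: Optional[Sequence[float]] = None,
    pseudocount: float = 0.8,
) -> pd.DataFrame:
    """Rank-sum motif enrichment of foreground vs background sequences.

    Per motif, each sequence is summarized by its best raw log-odds score
    over both strands; the test is a one-sided Mann-Whitney (foreground >
    background). ``E = p x number of motifs tested`` (Bonferroni over the
    catalog); a motif is flagged enriched when ``E < evalue_threshold``.
    Motifs wider than every sequence are skipped with a warning. Records are
    sorted ascending by E.
    """
    if len(fg_seqs) == 0 or len(bg_seqs) == 0:
        raise ValueError("both sequence sets must be non-empty")
    max_len = max(
        max((len(s) for s in fg_seqs), default=0),
        max((len(s) for s in bg_seqs), default=0),
    )
    rows = []
    n_tested = 0
    for pwm in pwms:
        if pwm.width > max_len:
            logger.warning("motif %s wider than every sequence; skipped", pwm.identifier)
            continue
        n_tested += 1
        lom = log_odds(pwm, background=background, pseudocount=pseudocount)
        fg = [best_score(s, lom) for s in fg_seqs]
        bg = [best_score(s, lom) for s in bg_seqs]
        fg = [v for v in fg if np.isfinite(v)]
        bg = [v for v in bg if np.isfinite(v)]
        res = mann_whitney(fg, bg, alternative="greater", mode="auto")
        rows.append(
            {
                "motif_id": pwm.identifier,
                "motif_name": pwm.name,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    out = pd.DataFrame(rows, columns=["motif_id", "motif_name", "statistic", "pvalue"])
    out["evalue"] = out["pvalue"] * n_tested
    out["enriched"] = out["evalue"] < evalue_threshold
    return out.sort_values("evalue", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Built-in consensus-derived matrices

def _consensus_pwm(identifier: str, name: str, consensus: str, weight: float = 20.0) -> PWM:
    """Count matrix from a consensus string; 'n' spacer columns are uniform."""
    w = len(consensus)
    counts = np.zeros((4, w))
    for j, ch in enumerate(consensus.upper()):
        if ch == "N":
            counts[:, j] = weight / 4.0
        else:
            counts[BASE_INDEX[ch], j] = weight
    return PWM(identifier=identifier, name=name, counts=counts)


def builtin_motifs() -> List[PWM]:
    """A small consensus-derived catalog of steroid-receptor elements.

    Contains the inverted-repeat receptor element (two hexameric half-sites
    separated by a 3-bp spacer; bound by both receptor paralogs), the
    direct-repeat DR3 variant (reported as androgen-receptor-selective), and
    two unrelated decoy motifs (AP-1 and a GC-box) so enrichment rankings
    have competition. All are consensus-derived stand-ins, not empirical
    JASPAR frequencies; real JASPAR files can be supplied instead.
    """
    return [
        _consensus_pwm("IR3", "steroid_inverted_repeat", "AGAACANNNTGTTCT"),
        _consensus_pwm("DR3", "androgen_direct_repeat", "AGAACANNNAGAACA"),
        _consensus_pwm("AP1", "ap1_tre", "TGACTCA"),
        _consensus_pwm("GCBOX", "gc_box", "GGGGCGGGG"),
    ]
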