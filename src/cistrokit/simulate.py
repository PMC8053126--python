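"""Seeded synthetic-data generator with a ground-truth ledger.

Emulates the statistical structure the comparative-cistrome analysis
assumes: a small genome with a planted GC landscape, two factors' peak sets
(shared / A-specific / B-specific) with replicate jitter and dropout, a
"closed chromatin" subset of B-specific peaks with attenuated basal
accessibility, planted motif instances, differential-expression tables whose
regulated genes sit near peaks of the matching category, and duplicated
STARR reads with UMIs. Every planted feature is recorded in a
:class:`SyntheticTruth` ledger so parameter-recovery tests can compare the
pipeline's output against what was planted.

Peaks are rejection-sampled with a 1-kb exclusion buffer (no two peaks of
any category overlap, keeping category recovery well-defined), at a density
matching the study system's cistrome (~1 peak per 130 kb). GC environments
are written A-specific windows first and B-specific windows last, so the
B-specific elevation — the headline planted contrast — is exact even when
two environments happen to be close. All randomness flows from a single
seed through named substreams, so individual components are reproducible
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .intervals import GenomicInterval, PeakSet
from .io import (
    GenomeSequence,
    write_bed,
    write_bedgraph,
    write_de_table,
    write_fasta,
    write_tss_table,
)
from .motifs import PWM, builtin_motifs, reverse_complement
from .starr import write_fragment_table

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticDataset", "generate",
           "plant_motifs", "simulate_starr", "write_bundle"]

_EXCLUSION_BUFFER = 1_000  # bp of clear sequence required between peaks

# substream ids (single master seed fans out through these)
_STREAMS = {"peaks": 1, "genome": 2, "replicates": 3, "coverage": 4,
            "expression": 5, "starr": 6, "motifs": 7}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    The defaults are the conditions every recovery test runs under; sizes
    are desk-scale but the planted structure (category proportions, GC
    deltas, attenuation of closed chromatin, effect sizes, duplication rate)
    mirrors what the analysis assumes about real data.
    """

    n_chroms: int = 3
    chrom_length: int = 40_000_000
    # GC landscape
    baseline_gc: float = 0.41
    gc_delta_b: float = 0.14  # added within +/- gc_env_halfwidth of B-specific centers
    gc_delta_a: float = -0.06  # likewise for A-specific centers
    gc_env_halfwidth: int = 10_000
    # cistrome
    n_shared: int = 300
    n_a_specific: int = 200
    n_b_specific: int = 400
    frac_b_closed: float = 0.5
    replicate_jitter_sd: float = 25.0
    replicate_dropout: float = 0.05
    peak_width_mean: float = 400.0
    peak_width_sd: float = 80.0
    # coverage
    track_bin: int = 20
    coverage_noise: float = 0.2  # Poisson rate per bin
    atac_amp_mean: float = 8.0
    atac_amp_sd: float = 1.5
    atac_closed_attenuation: float = 0.1
    chip_amp_mean: float = 10.0
    chip_amp_sd: float = 2.0
    h3k27ac_gain_factors: Tuple[str, ...] = ("B",)
    # expression
    n_genes: int = 800
    frac_genes_linked: Mapping[str, float] = field(
        default_factory=lambda: {"shared": 0.15, "A_specific": 0.15, "B_specific": 0.15}
    )
    effect_log2fc_mean: float = 2.5
    effect_log2fc_sd: float = 0.5
    # nulls: biological spread of small true changes, shared between factors,
    # plus a little factor-specific wobble; measured against de_standard_error
    null_log2fc_sd: float = 0.15
    null_factor_noise_sd: float = 0.03
    de_standard_error: float = 0.05
    tss_max_offset: int = 15_000  # linked TSS placed within this of the peak center
    # motifs
    motif_plant_rate: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "A_specific": {"DR3": 0.9},
            "shared": {"IR3": 0.9},
            "B_specific": {"IR3": 0.9},
        }
    )
    # STARR
    # mean true fragments per region (vehicle) and genome-wide background
    # fragments per sample; the background dominates the library so RPKM
    # normalization behaves like genome-scale data
    starr_base_rate: float = 50.0
    starr_background_fragments: int = 400_000
    starr_activation: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "shared": {"A": 4.0, "B": 4.0},
            "A_specific": {"A": 4.0, "B": 1.0},
            "B_specific": {"A": 1.0, "B": 4.0},
        }
    )
    duplication_rate: float = 0.5
    umi_length: int = 8

    def __post_init__(self) -> None:
        for f in ("frac_b_closed", "replicate_dropout", "duplication_rate"):
            if not (0.0 <= getattr(self, f) <= 1.0):
                raise ValueError(f"{f} must be in [0, 1]")
        for f in ("n_chroms", "chrom_length", "n_shared", "n_a_specific",
                  "n_b_specific", "n_genes", "umi_length"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not (0.0 < self.baseline_gc < 1.0):
            raise ValueError("baseline_gc must be in (0, 1)")
        for d in (self.gc_delta_a, self.gc_delta_b):
            if not (0.0 <= self.baseline_gc + d <= 1.0):
                raise ValueError("GC delta pushes composition outside [0, 1]")

    @property
    def n_peaks(self) -> int:
        return self.n_shared + self.n_a_specific + self.n_b_specific

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @property
    def sample_names(self) -> List[str]:
        return [f"{f}_{c}" for f in ("A", "B") for c in ("vehicle", "hormone")]


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of everything the generator planted."""

    peaks: pd.DataFrame  # peak_id, chrom, start, end, center, category, closed
    motifs: pd.DataFrame  # peak_id, motif_id, offset, strand
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, linked_category, linked_peak_id,
    #                      true_log2fc_A, true_log2fc_B
    starr: pd.DataFrame  # peak_id, category, activation_A, activation_B,
    #                      n_true_<sample> columns
    starr_library: pd.DataFrame  # sample, n_true_fragments


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    seed: int
    truth: SyntheticTruth
    chrom_lengths: Dict[str, int]
    rep_peaks: Dict[str, Tuple[PeakSet, PeakSet]]  # factor -> (rep1, rep2)
    accessible_calls: PeakSet
    tss: pd.DataFrame
    de_tables: Dict[str, pd.DataFrame]  # factor -> DE table
    genome: Optional[GenomeSequence] = None
    tracks: Dict[str, CoverageTrack] = field(default_factory=dict)
    starr_reads: Optional[pd.DataFrame] = None


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# peaks

def _place_peaks(cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    """Rejection-sample non-overlapping peaks with a 1-kb exclusion buffer.

    Peak centers are uniform over the genome (minus an edge margin wide
    enough for profile and GC-environment windows); a candidate is rejected
    when it comes within the buffer of an already placed peak, so no two
    peaks of any category overlap and category recovery stays well-defined.
    """
    import bisect

    rng = _rng(seed, "peaks")
    margin = cfg.gc_env_halfwidth + 5_000
    usable = cfg.chrom_length - 2 * margin
    if usable <= 0:
        raise ValueError("chrom_length too small for the edge margin")
    widths = np.clip(
        np.round(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd, cfg.n_peaks)),
        100, 4 * cfg.peak_width_mean,
    ).astype(int)
    # conservative center-to-center floor: two maximal widths plus the buffer
    min_dist = int(4 * cfg.peak_width_mean + _EXCLUSION_BUFFER)
    centers_by_chrom: Dict[str, list] = {c: [] for c in cfg.chrom_names}
    placed = []
    max_attempts = 200 * cfg.n_peaks
    attempts = 0
    while len(placed) < cfg.n_peaks:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "peak placement failed: genome too crowded; lower the peak "
                "counts or enlarge the genome"
            )
        chrom = cfg.chrom_names[int(rng.integers(cfg.n_chroms))]
        center = int(rng.integers(margin, cfg.chrom_length - margin))
        lst = centers_by_chrom[chrom]
        pos = bisect.bisect_left(lst, center)
        if pos > 0 and center - lst[pos - 1] < min_dist:
            continue
        if pos < len(lst) and lst[pos] - center < min_dist:
            continue
        bisect.insort(lst, center)
        placed.append((chrom, center))

    categories = np.array(
        ["shared"] * cfg.n_shared
        + ["A_specific"] * cfg.n_a_specific
        + ["B_specific"] * cfg.n_b_specific
    )
    rng.shuffle(categories)
    closed = np.zeros(cfg.n_peaks, dtype=bool)
    b_idx = np.flatnonzero(categories == "B_specific")
    n_closed = int(round(cfg.frac_b_closed * len(b_idx)))
    closed[rng.choice(b_idx, size=n_closed, replace=False)] = True

    rows = []
    for i, (chrom, center) in enumerate(placed):
        w = int(widths[i])
        start = max(center - w // 2, 0)
        rows.append(
            {
                "peak_id": f"P{i:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + w,
                "center": (2 * start + w) // 2,
                "category": categories[i],
                "closed": bool(closed[i]),
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def _truth_peakset(truth_peaks: pd.DataFrame, mask=None, label: str = "") -> PeakSet:
    sub = truth_peaks if mask is None else truth_peaks[mask]
    return PeakSet(
        (
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.peak_id)
            for r in sub.itertuples(index=False)
        ),
        label=label,
    )


def _replicates(
    truth_peaks: pd.DataFrame, cfg: SimulationConfig, seed: int
) -> Dict[str, Tuple[PeakSet, PeakSet]]:
    rng = _rng(seed, "replicates")
    out: Dict[str, Tuple[PeakSet, PeakSet]] = {}
    for factor, cats in (("A", ("shared", "A_specific")), ("B", ("shared", "B_specific"))):
        sub = truth_peaks[truth_peaks["category"].isin(cats)]
        reps = []
        for rep in (1, 2):
            ivs = []
            for r in sub.itertuples(index=False):
                if rng.random() < cfg.replicate_dropout:
                    continue
                ds = int(round(rng.normal(0, cfg.replicate_jitter_sd)))
                de = int(round(rng.normal(0, cfg.replicate_jitter_sd)))
                start = max(int(r.start) + ds, 0)
                end = min(int(r.end) + de, cfg.chrom_length)
                if end <= start:
                    end = start + 50
                ivs.append(GenomicInterval(r.chrom, start, end, name=r.peak_id))
            reps.append(PeakSet(ivs, label=f"{factor}_rep{rep}"))
        out[factor] = (reps[0], reps[1])
    return out


# ---------------------------------------------------------------------------
# genome & motifs

def _make_genome(truth_peaks: pd.DataFrame, cfg: SimulationConfig, seed: int) -> GenomeSequence:
    rng = _rng(seed, "genome")
    seqs: Dict[str, str] = {}
    hw = cfg.gc_env_halfwidth
    for chrom in cfg.chrom_names:
        L = cfg.chrom_length
        p = np.full(L, cfg.baseline_gc, dtype=np.float32)
        sub = truth_peaks[truth_peaks["chrom"] == chrom]
        for delta, cat in ((cfg.gc_delta_a, "A_specific"), (cfg.gc_delta_b, "B_specific")):
            for c in sub.loc[sub["category"] == cat, "center"]:
                p[max(int(c) - hw, 0): int(c) + hw] = cfg.baseline_gc + delta
        is_gc = rng.random(L, dtype=np.float32) < p
        del p
        pick = rng.integers(0, 2, L, dtype=np.uint8)
        codes = np.where(
            is_gc,
            np.where(pick == 0, np.uint8(ord("G")), np.uint8(ord("C"))),
            np.where(pick == 0, np.uint8(ord("A")), np.uint8(ord("T"))),
        )
        seqs[chrom] = codes.tobytes().decode("ascii")
    return GenomeSequence(seqs, validate=False)


def plant_motifs(
    genome: GenomeSequence,
    truth_peaks: pd.DataFrame,
    catalog: Sequence[PWM],
    rates: Mapping[str, Mapping[str, float]],
    seed: int,
    max_offset: int = 100,
) -> Tuple[GenomeSequence, pd.DataFrame]:
    """Write motif consensus strings into peak sequences.

    For each peak of category ``c`` and each ``(motif_id, rate)`` in
    ``rates[c]``, with probability ``rate`` the motif's consensus is written
    at a uniform random start within ``[center - max_offset, center +
    max_offset)`` on a uniform random strand. Returns the modified genome
    and the plant ledger (peak_id, motif_id, offset, strand).
    """
    rng = _rng(seed, "motifs")
    by_id = {p.identifier: p for p in catalog}
    buffers = {c: bytearray(s, "ascii") for c, s in genome.seqs.items()}
    rows = []
    for r in truth_peaks.itertuples(index=False):
        for motif_id, rate in rates.get(r.category, {}).items():
            if rng.random() >= rate:
                continue
            pwm = by_id[motif_id]
            consensus = pwm.consensus
            offset = int(r.center) - max_offset + int(rng.integers(0, 2 * max_offset))
            strand = "+" if rng.random() < 0.5 else "-"
            written = consensus if strand == "+" else reverse_complement(consensus)
            L = len(buffers[r.chrom])
            if offset < 0 or offset + len(written) > L:
                continue
            buffers[r.chrom][offset: offset + len(written)] = written.encode("ascii")
            rows.append(
                {"peak_id": r.peak_id, "motif_id": motif_id, "offset": offset,
                 "strand": strand}
            )
    new_genome = GenomeSequence(
        {c: b.decode("ascii") for c, b in buffers.items()}, validate=False
    )
    ledger = pd.DataFrame(rows, columns=["peak_id", "motif_id", "offset", "strand"])
    return new_genome, ledger


# ---------------------------------------------------------------------------
# coverage

def _add_bumps(
    arr: np.ndarray,
    centers: np.ndarray,
    amps: np.ndarray,
    bin_width: int,
    sd: float = 200.0,
    halfspan: int = 1_000,
) -> None:
    n = len(arr)
    for c, a in zip(centers, amps):
        i0 = max((int(c) - halfspan) // bin_width, 0)
        i1 = min((int(c) + halfspan) // bin_width + 1, n)
        pos = (np.arange(i0, i1) + 0.5) * bin_width
        arr[i0:i1] += a * np.exp(-((pos - c) ** 2) / (2 * sd**2))


def _coverage_tracks(
    truth_peaks: pd.DataFrame, cfg: SimulationConfig, seed: int
) -> Dict[str, CoverageTrack]:
    rng = _rng(seed, "coverage")
    n = len(truth_peaks)
    atac_amp = np.clip(rng.normal(cfg.atac_amp_mean, cfg.atac_amp_sd, n), 0.5, None)
    atac_amp = np.where(truth_peaks["closed"], atac_amp * cfg.atac_closed_attenuation, atac_amp)
    gain_amp = np.clip(rng.normal(cfg.atac_amp_mean / 2, cfg.atac_amp_sd, n), 0.5, None)
    chip_amp = {
        f: np.clip(rng.normal(cfg.chip_amp_mean, cfg.chip_amp_sd, n), 1.0, None)
        for f in ("A", "B")
    }
    ac_amp = np.clip(rng.normal(5.0, 1.0, n), 0.5, None)

    bound = {
        "A": truth_peaks["category"].isin(["shared", "A_specific"]).to_numpy(),
        "B": truth_peaks["category"].isin(["shared", "B_specific"]).to_numpy(),
    }
    open_mask = ~truth_peaks["closed"].to_numpy()

    def blank() -> Dict[str, np.ndarray]:
        nb = -(-cfg.chrom_length // cfg.track_bin)
        return {
            c: rng.poisson(cfg.coverage_noise, nb).astype(float)
            for c in cfg.chrom_names
        }

    specs = {
        "atac_basal": (np.ones(n, dtype=bool), atac_amp),
        "atac_hormone_A": (np.ones(n, dtype=bool), atac_amp + np.where(bound["A"], gain_amp, 0.0)),
        "atac_hormone_B": (np.ones(n, dtype=bool), atac_amp + np.where(bound["B"], gain_amp, 0.0)),
        "chip_A": (bound["A"], chip_amp["A"]),
        "chip_B": (bound["B"], chip_amp["B"]),
        "h3k27ac_basal": (open_mask, ac_amp),
    }
    for f in ("A", "B"):
        gain = 3.0 if f in cfg.h3k27ac_gain_factors else 1.0
        specs[f"h3k27ac_hormone_{f}"] = (
            open_mask | bound[f], np.where(bound[f], ac_amp * gain, ac_amp)
        )

    centers = truth_peaks["center"].to_numpy()
    chrom_arr = truth_peaks["chrom"].to_numpy()
    tracks = {}
    for name, (mask, amps) in specs.items():
        vals = blank()
        for chrom in cfg.chrom_names:
            sel = mask & (chrom_arr == chrom)
            _add_bumps(vals[chrom], centers[sel], amps[sel], cfg.track_bin)
        tracks[name] = CoverageTrack(vals, cfg.track_bin, cfg.chrom_lengths)
    return tracks


# ---------------------------------------------------------------------------
# expression

def _expression(
    truth_peaks: pd.DataFrame, cfg: SimulationConfig, seed: int
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, pd.DataFrame]]:
    rng = _rng(seed, "expression")
    n_linked = {c: int(round(f * cfg.n_genes)) for c, f in cfg.frac_genes_linked.items()}
    if sum(n_linked.values()) > cfg.n_genes:
        raise ValueError("frac_genes_linked sums beyond 1")
    records = []
    for cat, k in n_linked.items():
        pool = truth_peaks.index[truth_peaks["category"] == cat].to_numpy()
        if k > len(pool):
            raise ValueError(f"not enough {cat} peaks to link {k} genes")
        chosen = rng.choice(pool, size=k, replace=False)
        for pi in chosen:
            pk = truth_peaks.loc[pi]
            tss = int(pk["center"]) + int(
                rng.integers(-cfg.tss_max_offset, cfg.tss_max_offset + 1)
            )
            tss = int(np.clip(tss, 0, cfg.chrom_length - 1))
            records.append(
                {"chrom": pk["chrom"], "tss": tss, "linked_category": cat,
                 "linked_peak_id": pk["peak_id"]}
            )
    n_null = cfg.n_genes - len(records)
    for _ in range(n_null):
        chrom = cfg.chrom_names[int(rng.integers(cfg.n_chroms))]
        records.append(
            {"chrom": chrom, "tss": int(rng.integers(cfg.chrom_length)),
             "linked_category": None, "linked_peak_id": None}
        )
    order = rng.permutation(len(records))
    genes = pd.DataFrame([records[i] for i in order])
    genes.insert(0, "gene_id", [f"G{i:04d}" for i in range(len(genes))])
    genes["strand"] = np.where(rng.random(len(genes)) < 0.5, "+", "-")

    # planted log2 fold changes: effects where linked, correlated nulls elsewhere
    latent = rng.normal(0.0, cfg.null_log2fc_sd, len(genes))
    lfc = {}
    for factor, cats in (("A", ("shared", "A_specific")), ("B", ("shared", "B_specific"))):
        has_effect = genes["linked_category"].isin(cats).to_numpy()
        effect = rng.normal(cfg.effect_log2fc_mean, cfg.effect_log2fc_sd, len(genes))
        noise = rng.normal(0.0, cfg.null_factor_noise_sd, len(genes))
        lfc[factor] = np.where(has_effect, effect, latent + noise)
    genes["true_log2fc_A"] = lfc["A"]
    genes["true_log2fc_B"] = lfc["B"]

    de_tables = {}
    for factor in ("A", "B"):
        z = np.abs(lfc[factor]) / cfg.de_standard_error
        p = 2.0 * stats.norm.sf(z)
        padj = stats.false_discovery_control(np.clip(p, 1e-300, 1.0), method="bh")
        de_tables[factor] = pd.DataFrame(
            {"gene_id": genes["gene_id"], "log2fc": lfc[factor], "padj": padj}
        )
    tss = genes[["gene_id", "chrom", "tss", "strand"]].copy()
    return genes, tss, de_tables


# ---------------------------------------------------------------------------
# STARR

_UMI_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_umis(rng: np.random.Generator, n: int, length: int) -> List[str]:
    codes = _UMI_BASES[rng.integers(0, 4, size=(n, length))]
    buf = codes.tobytes()
    return [buf[i * length:(i + 1) * length].decode("ascii") for i in range(n)]


def simulate_starr(
    truth_peaks: pd.DataFrame, cfg: SimulationConfig, seed: int
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """STARR reads with UMIs and PCR duplicates for all four samples.

    Per sample, each region emits ``Poisson(base_rate x multiplier)`` true
    fragments (the hormone multiplier comes from the per-category activation
    table); a large uniform background of fragments outside any planted
    activation keeps library-size normalization realistic. Duplicates
    re-emit existing reads (expected fraction = ``duplication_rate``).

    Returns ``(reads, starr_truth, library_truth)``.
    """
    rng = _rng(seed, "starr")
    frames = []
    act_rows = []
    lib_rows = []
    n_regions = len(truth_peaks)
    activation = {
        cat: dict(m) for cat, m in cfg.starr_activation.items()
    }
    for r in truth_peaks.itertuples(index=False):
        act_rows.append(
            {
                "peak_id": r.peak_id,
                "category": r.category,
                "activation_A": activation.get(r.category, {}).get("A", 1.0),
                "activation_B": activation.get(r.category, {}).get("B", 1.0),
            }
        )
    starr_truth = pd.DataFrame(act_rows)

    chrom_names = cfg.chrom_names
    for factor in ("A", "B"):
        mult = starr_truth[f"activation_{factor}"].to_numpy()
        for cond in ("vehicle", "hormone"):
            sample = f"{factor}_{cond}"
            rates = cfg.starr_base_rate * (mult if cond == "hormone" else np.ones(n_regions))
            counts = rng.poisson(rates)
            total_peak = int(counts.sum())
            centers = np.repeat(truth_peaks["center"].to_numpy(), counts)
            chroms = np.repeat(truth_peaks["chrom"].to_numpy(), counts)
            # background fragments, uniform over the genome
            n_bg = cfg.starr_background_fragments
            bg_chrom_idx = rng.integers(0, cfg.n_chroms, n_bg)
            bg_centers = rng.integers(300, cfg.chrom_length - 300, n_bg)
            all_centers = np.concatenate([centers, bg_centers])
            all_chroms = np.concatenate(
                [chroms, np.array(chrom_names, dtype=object)[bg_chrom_idx]]
            )
            n_total = len(all_centers)
            widths = np.clip(
                np.round(rng.normal(350, 50, n_total)), 100, 600
            ).astype(np.int64)
            offsets = rng.integers(-200, 201, n_total)
            starts = np.clip(all_centers + offsets - widths // 2, 0, None)
            ends = np.minimum(starts + widths, cfg.chrom_length)
            strands = np.where(rng.random(n_total) < 0.5, "+", "-")
            umis = _random_umis(rng, n_total, cfg.umi_length)
            df = pd.DataFrame(
                {
                    "chrom": all_chroms,
                    "start": starts.astype(np.int64),
                    "end": ends.astype(np.int64),
                    "strand": strands,
                    "umi": umis,
                    "sample": sample,
                }
            )
            lib_rows.append({"sample": sample, "n_true_fragments": n_total})
            starr_truth[f"n_true_{sample}"] = counts
            # PCR duplicates: re-emit existing reads
            d = cfg.duplication_rate
            if d > 0:
                n_extra = rng.binomial(n_total, d / (1.0 - d)) if d < 1 else 0
                if n_extra:
                    dup_idx = rng.integers(0, n_total, n_extra)
                    df = pd.concat([df, df.iloc[dup_idx]], ignore_index=True)
            frames.append(df)
    reads = pd.concat(frames, ignore_index=True)
    return reads, starr_truth, pd.DataFrame(lib_rows)


# ---------------------------------------------------------------------------
# top level

def generate(
    config: Optional[SimulationConfig] = None,
    seed: int = 1,
    outdir: Optional[Union[str, Path]] = None,
    with_sequence: bool = True,
    with_coverage: bool = True,
    with_starr: bool = True,
) -> SyntheticDataset:
    """Generate a full synthetic bundle (deterministic per seed).

    The heavyweight components — genome sequence, coverage tracks, STARR
    reads — can be switched off for analyses that only need the cistrome
    and expression layers. With ``outdir`` the bundle is also written to
    disk as FASTA / BED / bedGraph / TSV files plus the truth ledger.
    """
    cfg = config or SimulationConfig()
    truth_peaks = _place_peaks(cfg, seed)
    rep_peaks = _replicates(truth_peaks, cfg, seed)
    accessible_calls = _truth_peakset(
        truth_peaks, ~truth_peaks["closed"], label="accessible_calls"
    )
    genes, tss, de_tables = _expression(truth_peaks, cfg, seed)

    genome = None
    motif_ledger = pd.DataFrame(columns=["peak_id", "motif_id", "offset", "strand"])
    if with_sequence:
        genome = _make_genome(truth_peaks, cfg, seed)
        genome, motif_ledger = plant_motifs(
            genome, truth_peaks, builtin_motifs(), cfg.motif_plant_rate, seed
        )

    tracks: Dict[str, CoverageTrack] = {}
    if with_coverage:
        tracks = _coverage_tracks(truth_peaks, cfg, seed)

    starr_reads = None
    starr_truth = pd.DataFrame()
    starr_library = pd.DataFrame(columns=["sample", "n_true_fragments"])
    if with_starr:
        starr_reads, starr_truth, starr_library = simulate_starr(truth_peaks, cfg, seed)

    truth = SyntheticTruth(
        peaks=truth_peaks,
        motifs=motif_ledger,
        genes=genes,
        starr=starr_truth,
        starr_library=starr_library,
    )
    ds = SyntheticDataset(
        config=cfg,
        seed=seed,
        truth=truth,
        chrom_lengths=cfg.chrom_lengths,
        rep_peaks=rep_peaks,
        accessible_calls=accessible_calls,
        tss=tss,
        de_tables=de_tables,
        genome=genome,
        tracks=tracks,
        starr_reads=starr_reads,
    )
    if outdir is not None:
        write_bundle(ds, outdir)
    return ds


def write_bundle(ds: SyntheticDataset, outdir: Union[str, Path]) -> None:
    """Write every generated component plus the truth ledger to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for factor, (rep1, rep2) in ds.rep_peaks.items():
        write_bed(rep1, out / f"peaks_{factor}_rep1.bed")
        write_bed(rep2, out / f"peaks_{factor}_rep2.bed")
    write_bed(ds.accessible_calls, out / "accessible_calls.bed")
    write_tss_table(ds.tss, out / "tss.tsv")
    for factor, table in ds.de_tables.items():
        write_de_table(table, out / f"de_{factor}.tsv")
    if ds.genome is not None:
        write_fasta(ds.genome, out / "genome.fa")
    for name, track in ds.tracks.items():
        write_bedgraph(track, out / f"{name}.bedgraph")
    if ds.starr_reads is not None:
        write_fragment_table(ds.starr_reads, out / "starr_reads.tsv")
    ds.truth.peaks.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
    ds.truth.motifs.to_csv(out / "truth_motifs.tsv", sep="\t", index=False)
    ds.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    if len(ds.truth.starr):
        ds.truth.starr.to_csv(out / "truth_starr.tsv", sep="\t", index=False)
    ds.truth.starr_library.to_csv(out / "truth_starr_library.tsv", sep="\t", index=False)
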