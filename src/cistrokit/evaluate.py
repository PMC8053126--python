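"""Parameter recovery: run the pipeline on a synthetic dataset and score it
against the generator's truth ledger.

Each function here exercises the public analysis operations end to end —
replicate reproducibility and categorization, accessibility stratification,
GC-landscape comparison, peak-to-gene Fisher enrichment, motif enrichment,
and STARR activation — and measures how well the planted structure is
recovered. Category recall is conditional on replicate detection: a truth
peak dropped from one factor's replicates cannot be categorized at all, so
it is excluded from the denominator; this isolates the categorization step
from detection loss.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import PeakSet
from .linkage import (
    assign_peaks,
    binding_fractions,
    classify_genes,
    disambiguate,
    enrichment_tests,
    gene_binding_profile,
    tss_windows,
)
from .motifs import builtin_motifs, extract_peak_sequences, log_odds, motif_enrichment, scan, shuffle_background
from .peaks import (
    CistromeCategories,
    accessibility_subsets,
    categorize,
    rank_by_signal,
    remove_excluded,
    reproducible_peaks,
)
from .signal import compare_region_gc, gc_track
from .simulate import SyntheticDataset, _truth_peakset
from .starr import region_activity, activation_summary, umi_dedup

__all__ = [
    "build_cistrome",
    "category_recall",
    "closed_peak_recovery",
    "gc_recovery",
    "linkage_analysis",
    "motif_recovery",
    "starr_recovery",
]


def build_cistrome(ds: SyntheticDataset) -> CistromeCategories:
    """Reproducible-peak extraction, exclusion filtering and categorization."""
    final = {}
    for factor in ("A", "B"):
        rep1, rep2 = ds.rep_peaks[factor]
        final[factor] = remove_excluded(reproducible_peaks(rep1, rep2))
    return categorize(final["A"], final["B"])


def category_recall(ds: SyntheticDataset, cats: CistromeCategories) -> float:
    """Fraction of detected truth peaks assigned their true category.

    A truth peak is 'detected' by a factor when it survives both of that
    factor's replicates; shared truth peaks enter the denominator only when
    detected by both factors.
    """
    det = {}
    for factor in ("A", "B"):
        rep1, rep2 = ds.rep_peaks[factor]
        det[factor] = {iv.name for iv in reproducible_peaks(rep1, rep2)}
    names = {
        "shared": {iv.name for iv in cats.shared},
        "A_specific": {iv.name for iv in cats.a_specific},
        "B_specific": {iv.name for iv in cats.b_specific},
    }
    correct = eligible = 0
    for r in ds.truth.peaks.itertuples(index=False):
        if r.category == "shared":
            if r.peak_id not in det["A"] or r.peak_id not in det["B"]:
                continue
        elif r.category == "A_specific":
            if r.peak_id not in det["A"]:
                continue
        else:
            if r.peak_id not in det["B"]:
                continue
        eligible += 1
        correct += r.peak_id in names[r.category]
    return correct / eligible if eligible else float("nan")


def closed_peak_recovery(
    ds: SyntheticDataset,
    cats: CistromeCategories,
    rank_halfwidth: int = 250,
    k_high: Optional[int] = None,
) -> Dict[str, float]:
    """Recall of planted closed-chromatin peaks in the low-accessibility cut.

    B-specific peaks are ranked by basal accessibility; the bottom cut size
    equals the number of truth-closed peaks among them, and peaks
    overlapping accessible-chromatin calls are then removed — mirroring the
    bottom-k extraction with open-peak cleanup.
    """
    closed_ids = set(
        ds.truth.peaks.loc[ds.truth.peaks["closed"], "peak_id"]
    ) & {iv.name for iv in cats.b_specific}
    ranked = rank_by_signal(cats.b_specific, ds.tracks["atac_basal"], rank_halfwidth)
    k_low = len(closed_ids)
    if k_high is None:
        k_high = max(len(ranked) // 4, 1)
    low, high = accessibility_subsets(ranked, k_low, k_high, ds.accessible_calls)
    low_ids = {iv.name for iv in low}
    recall = len(low_ids & closed_ids) / len(closed_ids) if closed_ids else float("nan")
    return {
        "recall": recall,
        "n_closed_detected": len(closed_ids),
        "n_low": len(low),
        "n_high": len(high),
    }


def gc_recovery(
    ds: SyntheticDataset, cats: CistromeCategories, halfwidth: int = 5_000
) -> Dict[str, float]:
    """GC contrast between factor-specific peaks, and planted-delta recovery.

    The Mann-Whitney comparison uses the pipeline's detected categories; the
    planted GC deltas are recovered as the mean GC over +/-halfwidth of
    truth-specific peak centers minus the same quantity at shared truth
    peaks, whose environment was left at the genomic baseline.
    """
    gc = gc_track(ds.genome, 50)
    comp = compare_region_gc(cats.a_specific, cats.b_specific, gc, halfwidth, labels=("A", "B"))
    from .signal import _region_means

    tp = ds.truth.peaks
    base = _region_means(_truth_peakset(tp, tp["category"] == "shared"), gc, halfwidth).mean()
    mean_b = _region_means(_truth_peakset(tp, tp["category"] == "B_specific"), gc, halfwidth).mean()
    mean_a = _region_means(_truth_peakset(tp, tp["category"] == "A_specific"), gc, halfwidth).mean()
    return {
        "pvalue": comp.pvalue,
        "direction": comp.direction,
        "mean_gc_a": comp.mean_x,
        "mean_gc_b": comp.mean_y,
        "delta_b_recovered": float(mean_b - base),
        "delta_a_recovered": float(mean_a - base),
    }


def linkage_analysis(
    ds: SyntheticDataset,
    cats: CistromeCategories,
    cfg: Optional[PipelineConfig] = None,
) -> Dict[str, pd.DataFrame]:
    """Gene categorization, window assignment, fractions and Fisher tests."""
    cfg = cfg or PipelineConfig()
    categories = classify_genes(ds.de_tables["A"], ds.de_tables["B"], cfg)
    windows = tss_windows(ds.tss, cfg.tss_window)
    peaks_by_label = {
        "shared": cats.shared,
        "A_specific": cats.a_specific,
        "B_specific": cats.b_specific,
    }
    ledger = assign_peaks(peaks_by_label, windows, ds.tss, categories)
    ledger = disambiguate(ledger, ds.tss, categories)
    profile = gene_binding_profile(ledger, categories)
    fractions = binding_fractions(profile)
    enrichment = enrichment_tests(profile)
    return {
        "categories": categories,
        "ledger": ledger,
        "profile": profile,
        "fractions": fractions,
        "enrichment": enrichment,
    }


def motif_recovery(
    ds: SyntheticDataset,
    cats: CistromeCategories,
    cfg: Optional[PipelineConfig] = None,
) -> Dict[str, object]:
    """Enrichment of the planted motif at A-specific peaks, plus plant recall.

    Foreground = A-specific peak sequences; background = their
    dinucleotide-preserving shuffles. Plant recall scans each truth peak
    carrying a planted motif at the 80% relative-score threshold.
    """
    cfg = cfg or PipelineConfig()
    fg = extract_peak_sequences(ds.genome, cats.a_specific, cfg.motif_flank)
    bg = shuffle_background(fg, seed=ds.seed)
    catalog = builtin_motifs()
    enr = motif_enrichment(fg, bg, catalog, cfg.evalue_threshold)

    loms = {p.identifier: log_odds(p) for p in catalog}
    tp = ds.truth.peaks.set_index("peak_id")
    found = total = 0
    for r in ds.truth.motifs.itertuples(index=False):
        pk = tp.loc[r.peak_id]
        c = int(pk["center"])
        seq = ds.genome.fetch(pk["chrom"], c - cfg.motif_flank, c + cfg.motif_flank)
        hits = scan(seq, loms[r.motif_id], cfg.rel_score_threshold)
        want_offset = int(r.offset) - (c - cfg.motif_flank)
        total += 1
        found += any(h.offset == want_offset for h in hits)
    return {
        "enrichment": enr,
        "plant_recall": found / total if total else float("nan"),
        "n_plants": total,
    }


def starr_recovery(ds: SyntheticDataset) -> Dict[str, pd.DataFrame]:
    """Dedup STARR reads and summarize hormone activation per peak category."""
    dedup = umi_dedup(ds.starr_reads)
    regions = _truth_peakset(ds.truth.peaks, label="truth_peaks")
    cat_of = dict(zip(ds.truth.peaks["peak_id"], ds.truth.peaks["category"]))
    out: Dict[str, pd.DataFrame] = {"dedup": dedup}
    for factor in ("A", "B"):
        veh = dedup[dedup["sample"] == f"{factor}_vehicle"]
        hor = dedup[dedup["sample"] == f"{factor}_hormone"]
        act_v = region_activity(veh, regions, condition="vehicle")
        act_h = region_activity(hor, regions, condition="hormone")
        per_region, per_cat = activation_summary(act_v, act_h, cat_of)
        out[f"per_region_{factor}"] = per_region
        out[f"summary_{factor}"] = per_cat
    return out
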