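"""Linking transcription-factor binding to gene regulation.

Genes are categorized from two factors' differential-expression tables
(factor-specific, shared, non-regulated), peaks are assigned to genes whose
TSS-centered window they overlap, peaks touching windows of more than one
gene category are re-assigned to the nearest gene, and per-category binding
is tested against the non-regulated reference group with Fisher's exact
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .intervals import GenomicInterval, PeakSet

__all__ = [
    "GENE_CATEGORIES",
    "PEAK_LABELS",
    "classify_genes",
    "tss_windows",
    "assign_peaks",
    "disambiguate",
    "gene_binding_profile",
    "binding_fractions",
    "fisher_exact",
    "enrichment_tests",
]

GENE_CATEGORIES = ("A_specific", "B_specific", "shared", "non_regulated", "other")
PEAK_LABELS = ("shared", "A_specific", "B_specific")
REGULATED_CATEGORIES = ("shared", "A_specific", "B_specific")


# ---------------------------------------------------------------------------
# Gene categories

def classify_genes(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    cfg: Optional[PipelineConfig] = None,
    joint_nonregulated: bool = True,
) -> pd.DataFrame:
    """Categorize genes from two factors' DE tables.

    A gene is up for factor X when ``padj_X < up_padj`` and ``log2fc_X >
    up_log2fc``; "shared" = up in both, "A_specific"/"B_specific" = up in one
    only. "non_regulated" requires ``padj < nr_padj`` and ``0 < log2fc <
    nr_log2fc_hi`` — jointly for both factors by default
    (``joint_nonregulated=False`` accepts either factor). Everything else
    (including significant down-regulation) is "other". Missing padj never
    satisfies any criterion; the gene universe is the outer join of the two
    tables, with the absent side treated as non-significant.
    """
    cfg = cfg or PipelineConfig()
    merged = de_a.merge(de_b, on="gene_id", how="outer", suffixes=("_A", "_B"))

    def _up(lfc, padj):
        return (padj < cfg.up_padj) & (lfc > cfg.up_log2fc)

    def _nr(lfc, padj):
        return (padj < cfg.nr_padj) & (lfc > 0) & (lfc < cfg.nr_log2fc_hi)

    lfc_a = merged["log2fc_A"]
    lfc_b = merged["log2fc_B"]
    padj_a = merged["padj_A"]
    padj_b = merged["padj_B"]
    up_a = _up(lfc_a, padj_a).fillna(False)
    up_b = _up(lfc_b, padj_b).fillna(False)
    nr_a = _nr(lfc_a, padj_a).fillna(False)
    nr_b = _nr(lfc_b, padj_b).fillna(False)
    nr = (nr_a & nr_b) if joint_nonregulated else (nr_a | nr_b)

    category = np.where(
        up_a & up_b,
        "shared",
        np.where(
            up_a,
            "A_specific",
            np.where(up_b, "B_specific", np.where(nr, "non_regulated", "other")),
        ),
    )
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "category": category,
            "log2fc_A": lfc_a,
            "padj_A": padj_a,
            "log2fc_B": lfc_b,
            "padj_B": padj_b,
        }
    )
    return out.sort_values("gene_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSS windows and peak assignment

def tss_windows(tss: pd.DataFrame, window: int = 60_000) -> PeakSet:
    """Symmetric windows ``[tss - window/2, tss + window/2)``, clipped at 0.

    Strand is ignored (the window is symmetric); one interval per gene,
    named by gene_id. Genes sharing a TSS keep separate, identical windows.
    """
    if window <= 0 or window % 2:
        raise ValueError("window must be even and positive")
    half = window // 2
    ivs = [
        GenomicInterval(
            str(row.chrom), max(int(row.tss) - half, 0), int(row.tss) + half,
            name=str(row.gene_id),
        )
        for row in tss.itertuples(index=False)
    ]
    return PeakSet(ivs, label="tss_windows")


def assign_peaks(
    peaks_by_label: Mapping[str, PeakSet],
    windows: PeakSet,
    tss: pd.DataFrame,
    categories: pd.DataFrame,
) -> pd.DataFrame:
    """All (gene, peak) assignments: peak overlaps the gene's window >= 1 bp.

    Returns the assignment ledger (one row per assignment, before nearest-gene
    disambiguation) with columns: label, peak_index, chrom, peak_start,
    peak_end, peak_center, gene_id, gene_category, tss, distance.
    """
    window_genes = {iv.name for iv in windows}
    known = set(categories["gene_id"])
    missing = window_genes - known
    if missing:
        raise ValueError(f"genes in windows absent from categories: {sorted(missing)[:5]}")
    cat_of = dict(zip(categories["gene_id"], categories["category"]))
    tss_of = dict(zip(tss["gene_id"], tss["tss"]))

    win_by_chrom: Dict[str, list] = {}
    for iv in windows:
        win_by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in win_by_chrom:
        win_by_chrom[chrom].sort(key=lambda iv: iv.start)

    rows = []
    for label, peaks in peaks_by_label.items():
        for pi, pk in enumerate(peaks):
            wins = win_by_chrom.get(pk.chrom, ())
            if not wins:
                continue
            starts = np.array([w.start for w in wins], dtype=np.int64)
            hi = int(np.searchsorted(starts, pk.end, side="left"))
            for w in wins[:hi]:
                if w.end > pk.start:
                    gid = w.name
                    rows.append(
                        {
                            "label": label,
                            "peak_index": pi,
                            "chrom": pk.chrom,
                            "peak_start": pk.start,
                            "peak_end": pk.end,
                            "peak_center": pk.center,
                            "gene_id": gid,
                            "gene_category": cat_of[gid],
                            "tss": int(tss_of[gid]),
                            "distance": abs(pk.center - int(tss_of[gid])),
                        }
                    )
    cols = [
        "label", "peak_index", "chrom", "peak_start", "peak_end",
        "peak_center", "gene_id", "gene_category", "tss", "distance",
    ]
    return pd.DataFrame(rows, columns=cols)


def disambiguate(
    ledger: pd.DataFrame, tss: pd.DataFrame, categories: pd.DataFrame
) -> pd.DataFrame:
    """Nearest-gene re-assignment for category-ambiguous peaks.

    For each peak whose assigned genes span more than one gene category, only
    the assignment(s) to the gene minimizing ``|peak_center - tss|`` survive;
    distance ties break by lexicographically smallest gene_id. Peaks whose
    assigned genes all share one category are untouched. Never grows the
    ledger and never removes single-category assignments.
    """
    if ledger.empty:
        return ledger.copy()
    keep_parts = []
    for (_, _), grp in ledger.groupby(["label", "peak_index"], sort=False):
        if grp["gene_category"].nunique() <= 1:
            keep_parts.append(grp)
            continue
        best = grp.sort_values(["distance", "gene_id"]).iloc[0]
        keep_parts.append(grp[grp["gene_id"] == best["gene_id"]])
    return pd.concat(keep_parts, ignore_index=True)


def gene_binding_profile(
    ledger: pd.DataFrame,
    categories: pd.DataFrame,
    labels: Sequence[str] = PEAK_LABELS,
) -> pd.DataFrame:
    """Per-gene presence flags for each peak label (after disambiguation).

    One row per gene in ``categories``; a gene with no flags at all has
    display class ``no_peaks`` downstream.
    """
    flags = pd.DataFrame(
        False, index=categories["gene_id"], columns=[f"has_{lab}" for lab in labels]
    )
    if not ledger.empty:
        for lab in labels:
            genes = ledger.loc[ledger["label"] == lab, "gene_id"].unique()
            flags.loc[flags.index.intersection(genes), f"has_{lab}"] = True
    out = flags.reset_index()
    out.insert(1, "category", categories.set_index("gene_id").loc[out["gene_id"], "category"].values)
    return out


def binding_fractions(
    profile: pd.DataFrame,
    categories: Optional[pd.DataFrame] = None,
    precedence: Sequence[str] = PEAK_LABELS,
    gene_categories: Sequence[str] = ("shared", "A_specific", "B_specific", "non_regulated"),
) -> pd.DataFrame:
    """Stacked-bar fractions of binding display classes per gene category.

    Each gene maps to exactly one display class by precedence (default
    shared > A_specific > B_specific), falling through to ``no_peaks``.
    Fractions within each gene category sum to 1. Genes in the "other"
    category are excluded.
    """
    classes = list(precedence) + ["no_peaks"]

    def display_class(row) -> str:
        for lab in precedence:
            if row[f"has_{lab}"]:
                return lab
        return "no_peaks"

    sub = profile[profile["category"].isin(gene_categories)].copy()
    sub["display_class"] = sub.apply(display_class, axis=1)
    counts = (
        sub.groupby("category")["display_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=classes, fill_value=0)
    )
    counts = counts.reindex([c for c in gene_categories if c in counts.index])
    fracs = counts.div(counts.sum(axis=1), axis=0)
    fracs.insert(0, "n_genes", counts.sum(axis=1))
    return fracs


# ---------------------------------------------------------------------------
# Fisher enrichment

def fisher_exact(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table of counts.

    Returns ``(odds_ratio, p)`` with the sample odds ratio
    ``n11 * n22 / (n12 * n21)`` (inf when only the denominator is 0; 1 when
    both are 0). The p-value sums hypergeometric probabilities of all
    margin-fixed tables at most as probable as the observed one (relative
    tolerance 1 + 1e-7 on the comparison).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    num = float(t[0, 0]) * float(t[1, 1])
    den = float(t[0, 1]) * float(t[1, 0])
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return odds, float(min(p, 1.0))


def enrichment_tests(
    profile: pd.DataFrame,
    labels: Sequence[str] = PEAK_LABELS,
    reference_category: str = "non_regulated",
    categories_tested: Sequence[str] = REGULATED_CATEGORIES,
) -> pd.DataFrame:
    """Fisher enrichment of peak-label presence per regulated gene category.

    For each (gene category c, peak label L) the 2x2 table compares genes in
    c vs the non-regulated reference: rows {c, reference}, columns {has >= 1
    L peak, has none}. Presence flags are per-label (a gene may count as
    "has" for several labels). Headline p-values are raw Fisher p (no
    cross-test correction); a Benjamini-Hochberg column is added alongside
    for convenience.
    """
    ref = profile[profile["category"] == reference_category]
    if len(ref) == 0:
        raise ValueError(f"no genes in reference category {reference_category!r}")
    rows = []
    for cat in categories_tested:
        grp = profile[profile["category"] == cat]
        if len(grp) == 0:
            continue
        for lab in labels:
            col = f"has_{lab}"
            n11 = int(grp[col].sum())
            n12 = len(grp) - n11
            n21 = int(ref[col].sum())
            n22 = len(ref) - n21
            odds, p = fisher_exact([[n11, n12], [n21, n22]])
            rows.append(
                {
                    "gene_category": cat,
                    "peak_label": lab,
                    "n_with": n11,
                    "n_without": n12,
                    "ref_with": n21,
                    "ref_without": n22,
                    "odds_ratio": odds,
                    "pvalue": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = stats.false_discovery_control(out["pvalue"], method="bh")
    return out
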