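"""Gene categorization, TSS-window assignment and Fisher enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from cistrokit.intervals import GenomicInterval, PeakSet
from cistrokit.linkage import (
    assign_peaks,
    binding_fractions,
    classify_genes,
    disambiguate,
    enrichment_tests,
    fisher_exact,
    gene_binding_profile,
    tss_windows,
)


def de(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])


class TestClassifyGenes:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((2.0, 0.001), (0.1, 0.9), "A_specific"),
            ((2.0, 0.001), (1.8, 0.01), "shared"),
            ((0.1, 0.9), (2.0, 0.001), "B_specific"),
            ((0.2, 0.3), (0.1, 0.4), "non_regulated"),
            ((-2.0, 0.001), (0.1, 0.4), "other"),
            ((2.0, 0.001), (1.0, 0.01), "A_specific"),  # B in the 0.5-1.5 gap
        ],
    )
    def test_threshold_rules(self, a, b, expected):
        cats = classify_genes(de([("g", *a)]), de([("g", *b)]))
        assert cats.loc[0, "category"] == expected

    def test_missing_padj_never_qualifies(self):
        cats = classify_genes(de([("g", 2.0, np.nan)]), de([("g", 0.2, 0.3)]))
        assert cats.loc[0, "category"] == "other"

    def test_outer_join_universe(self):
        cats = classify_genes(de([("g1", 2.0, 0.001)]), de([("g2", 2.0, 0.001)]))
        assert set(cats["gene_id"]) == {"g1", "g2"}
        assert (
            cats.set_index("gene_id").loc["g1", "category"] == "A_specific"
        )

    def test_either_factor_nonregulated_option(self):
        a, b = de([("g", 0.2, 0.3)]), de([("g", 0.7, 0.3)])
        joint = classify_genes(a, b, joint_nonregulated=True)
        either = classify_genes(a, b, joint_nonregulated=False)
        assert joint.loc[0, "category"] == "other"
        assert either.loc[0, "category"] == "non_regulated"


class TestTssWindows:
    def test_symmetric_window(self):
        tss = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [50_000], "strand": ["+"]}
        )
        w = tss_windows(tss, 60_000)
        assert (w[0].start, w[0].end) == (20_000, 80_000)

    def test_clipped_at_zero(self):
        tss = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [10_000], "strand": ["-"]}
        )
        w = tss_windows(tss, 60_000)
        assert (w[0].start, w[0].end) == (0, 40_000)

    def test_shared_tss_keeps_both_windows(self):
        tss = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "chrom": ["chr1"] * 2,
             "tss": [50_000] * 2, "strand": ["+", "-"]}
        )
        assert len(tss_windows(tss, 60_000)) == 2


def _toy_linkage(peak_spans, genes):
    """genes: list of (gene_id, tss, category)."""
    tss = pd.DataFrame(
        {"gene_id": [g[0] for g in genes], "chrom": "chr1",
         "tss": [g[1] for g in genes], "strand": "+"}
    )
    categories = pd.DataFrame(
        {"gene_id": [g[0] for g in genes], "category": [g[2] for g in genes],
         "log2fc_A": 0.0, "padj_A": 1.0, "log2fc_B": 0.0, "padj_B": 1.0}
    )
    peaks = {
        lab: PeakSet(GenomicInterval("chr1", s, e) for s, e in spans)
        for lab, spans in peak_spans.items()
    }
    windows = tss_windows(tss, 60_000)
    return peaks, windows, tss, categories


class TestAssignPeaks:
    def test_boundary_overlap_is_half_open(self):
        peaks, windows, tss, cats = _toy_linkage(
            {"shared": [(79_950, 80_050), (80_000, 80_100)]},
            [("g", 50_000, "non_regulated")],
        )
        ledger = assign_peaks(peaks, windows, tss, cats)
        assert len(ledger) == 1
        assert ledger.loc[0, "peak_start"] == 79_950

    def test_gene_missing_from_categories_raises(self):
        peaks, windows, tss, cats = _toy_linkage(
            {"shared": [(0, 100)]}, [("g", 1_000, "shared")]
        )
        with pytest.raises(ValueError, match="absent"):
            assign_peaks(peaks, windows, tss, cats.iloc[0:0])

    def test_matches_all_pairs_quadratic_oracle(self, rng):
        for _ in range(30):
            n_genes, n_peaks = 15, 40
            genes = [
                (f"g{i}", int(rng.integers(0, 300_000)),
                 ["shared", "A_specific", "non_regulated"][i % 3])
                for i in range(n_genes)
            ]
            spans = sorted(
                (int(s), int(s + rng.integers(50, 400)))
                for s in rng.integers(0, 300_000, n_peaks)
            )
            peaks, windows, tss, cats = _toy_linkage({"shared": spans}, genes)
            ledger = assign_peaks(peaks, windows, tss, cats)
            got = {(r.gene_id, r.peak_start) for r in ledger.itertuples()}
            want = set()
            for gid, t, _ in genes:
                lo, hi = max(t - 30_000, 0), t + 30_000
                for s, e in spans:
                    if s < hi and lo < e:
                        want.add((gid, s))
            assert got == want


class TestDisambiguate:
    def test_nearest_gene_wins_across_categories(self):
        peaks, windows, tss, cats = _toy_linkage(
            {"shared": [(9_950, 10_050)]},
            [("geneX", 9_000, "non_regulated"), ("geneY", 15_000, "A_specific")],
        )
        ledger = disambiguate(assign_peaks(peaks, windows, tss, cats), tss, cats)
        assert list(ledger["gene_id"]) == ["geneX"]

    def test_distance_tie_breaks_by_gene_id(self):
        peaks, windows, tss, cats = _toy_linkage(
            {"shared": [(9_950, 10_050)]},
            [("b_gene", 5_000, "non_regulated"), ("a_gene", 15_000, "A_specific")],
        )
        ledger = disambiguate(assign_peaks(peaks, windows, tss, cats), tss, cats)
        assert list(ledger["gene_id"]) == ["a_gene"]

    def test_single_category_assignments_untouched(self):
        peaks, windows, tss, cats = _toy_linkage(
            {"shared": [(9_950, 10_050)]},
            [("g1", 9_000, "A_specific"), ("g2", 15_000, "A_specific")],
        )
        raw = assign_peaks(peaks, windows, tss, cats)
        out = disambiguate(raw, tss, cats)
        assert len(out) == len(raw) == 2

    def test_never_grows_ledger(self, rng):
        genes = [
            (f"g{i}", int(rng.integers(0, 100_000)),
             ["shared", "B_specific", "non_regulated", "other"][i % 4])
            for i in range(20)
        ]
        spans = [
            (int(s), int(s) + 200) for s in rng.integers(0, 100_000, 30)
        ]
        peaks, windows, tss, cats = _toy_linkage({"A_specific": spans}, genes)
        raw = assign_peaks(peaks, windows, tss, cats)
        out = disambiguate(raw, tss, cats)
        assert len(out) <= len(raw)
        single = raw.groupby("peak_index").filter(
            lambda g: g["gene_category"].nunique() == 1
        )
        merged = single.merge(out, how="inner")
        assert len(merged) == len(single)


class TestBindingFractions:
    def _profile(self, rows):
        df = pd.DataFrame(
            rows, columns=["gene_id", "category", "has_shared", "has_A_specific",
                           "has_B_specific"]
        )
        return df

    def test_precedence_shared_first(self):
        prof = self._profile([("g", "shared", True, True, False)])
        fr = binding_fractions(prof)
        assert fr.loc["shared", "shared"] == 1.0

    def test_no_flags_is_no_peaks(self):
        prof = self._profile([("g", "non_regulated", False, False, False)])
        fr = binding_fractions(prof)
        assert fr.loc["non_regulated", "no_peaks"] == 1.0

    def test_fractions_sum_to_one(self):
        prof = self._profile(
            [("g1", "shared", True, False, False),
             ("g2", "shared", True, True, False),
             ("g3", "shared", False, True, False),
             ("g4", "shared", False, False, False)]
        )
        fr = binding_fractions(prof)
        row = fr.loc["shared"]
        assert row["shared"] == 0.5 and row["A_specific"] == 0.25
        assert row["no_peaks"] == 0.25
        assert row[["shared", "A_specific", "B_specific", "no_peaks"]].sum() == 1.0


def fisher_oracle(table):
    """Exact two-sided Fisher p by full margin-fixed enumeration (rationals)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def pmf(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return Fraction(0)
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = pmf(a)
    gamma = Fraction(10**7 + 1, 10**7)
    total = Fraction(0)
    for k in range(0, min(r1, c1) + 1):
        pk = pmf(k)
        if pk <= p_obs * gamma:
            total += pk
    return float(min(total, 1))


class TestFisherExact:
    def test_fully_separated_five_by_five(self):
        odds, p = fisher_exact([[5, 0], [0, 5]])
        assert math.isinf(odds)
        assert p == pytest.approx(2 / 252)

    def test_degenerate_column(self):
        odds, p = fisher_exact([[0, 10], [0, 10]])
        assert odds == 1.0 and p == 1.0

    def test_odds_ratio_definition(self):
        odds, _ = fisher_exact([[4, 1], [1, 4]])
        assert odds == 16.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 2]])

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(400):
            n = int(rng.integers(1, 49))
            cells = rng.multinomial(n, [0.25] * 4)
            table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
            _, p = fisher_exact(table)
            assert p == pytest.approx(fisher_oracle(table), rel=1e-6, abs=1e-12)


class TestEnrichmentTests:
    def _profile(self, cat_counts):
        """cat_counts: {category: (n_with_flag, n_total)} for label 'shared'."""
        rows = []
        for cat, (k, n) in cat_counts.items():
            for i in range(n):
                rows.append((f"{cat}_{i}", cat, i < k, False, False))
        return pd.DataFrame(
            rows, columns=["gene_id", "category", "has_shared", "has_A_specific",
                           "has_B_specific"]
        )

    def test_worked_example_odds_ratio_19(self):
        prof = self._profile({"shared": (10, 20), "non_regulated": (10, 200)})
        res = enrichment_tests(prof).set_index(["gene_category", "peak_label"])
        row = res.loc[("shared", "shared")]
        assert row["odds_ratio"] == pytest.approx((10 * 190) / (10 * 10))
        assert row["pvalue"] == pytest.approx(
            fisher_oracle([[10, 10], [10, 190]])
        )

    def test_no_flags_anywhere_gives_p_one(self):
        prof = self._profile({"shared": (0, 15), "non_regulated": (0, 40)})
        res = enrichment_tests(prof)
        assert (res["pvalue"] == 1.0).all()

    def test_empty_reference_raises(self):
        prof = self._profile({"shared": (3, 10)})
        with pytest.raises(ValueError):
            enrichment_tests(prof)


class TestGeneBindingProfile:
    def test_flags_follow_ledger(self):
        peaks, windows, tss, cats = _toy_linkage(
            {"shared": [(9_950, 10_050)], "A_specific": [(200_000, 200_100)],
             "B_specific": []},
            [("g1", 10_000, "shared"), ("g2", 400_000, "non_regulated")],
        )
        ledger = assign_peaks(peaks, windows, tss, cats)
        prof = gene_binding_profile(ledger, cats).set_index("gene_id")
        assert prof.loc["g1", "has_shared"]
        assert not prof.loc["g1", "has_A_specific"]
        assert not prof.loc["g2"].drop("category").any()
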