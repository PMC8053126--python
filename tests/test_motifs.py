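"""PWM parsing, log-odds scanning, shuffling and enrichment."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from cistrokit.intervals import GenomicInterval, PeakSet
from cistrokit.io import GenomeSequence
from cistrokit.motifs import (
    PWM,
    builtin_motifs,
    extract_peak_sequences,
    log_odds,
    motif_enrichment,
    read_jaspar,
    reverse_complement,
    scan,
    shuffle_background,
    write_jaspar,
)

TOY_JASPAR = """>MA0001.1 toy1
A  [ 10  0 ]
C  [ 0  10 ]
G  [ 0  0 ]
T  [ 0  0 ]
>MA0002.1 toy2
A  [ 1 2 3 ]
C  [ 4 3 2 ]
G  [ 0 1 0 ]
T  [ 5 4 5 ]
"""


class TestReadJaspar:
    def test_parses_widths_and_counts(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(TOY_JASPAR)
        pwms = read_jaspar(p)
        assert [m.width for m in pwms] == [2, 3]
        assert pwms[0].consensus == "AC"

    def test_round_trip(self, tmp_path):
        path = tmp_path / "rt.jaspar"
        write_jaspar(builtin_motifs(), path)
        back = read_jaspar(path)
        for a, b in zip(builtin_motifs(), back):
            assert a.identifier == b.identifier
            np.testing.assert_allclose(a.counts, b.counts)

    def test_unequal_row_lengths_rejected(self, tmp_path):
        p = tmp_path / "bad.jaspar"
        p.write_text(">M1 bad\nA [ 1 2 ]\nC [ 1 ]\nG [ 1 2 ]\nT [ 1 2 ]\n")
        with pytest.raises(ValueError):
            read_jaspar(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PWM("x", "x", np.array([[1.0, -1.0], [1, 1], [1, 1], [1, 1]]))


class TestLogOdds:
    def test_uniform_column_scores_zero(self):
        pwm = PWM("u", "u", np.full((4, 3), 5.0))
        lom = log_odds(pwm)
        np.testing.assert_allclose(lom.scores, 0.0)

    def test_single_base_column_value(self):
        # column (10,0,0,0): score_A = log2(((10 + 0.8*0.25) / 10.8) / 0.25)
        pwm = PWM("s", "s", np.array([[10.0], [0], [0], [0]]))
        lom = log_odds(pwm, pseudocount=0.8)
        assert lom.scores[0, 0] == pytest.approx(
            math.log2((10.2 / 10.8) / 0.25)
        )
        assert lom.scores[0, 0] == pytest.approx(1.9175, abs=1e-4)

    def test_max_score_is_consensus_score(self):
        pwm = builtin_motifs()[0]
        lom = log_odds(pwm)
        hits = scan(pwm.consensus.replace("N", "A"), lom, rel_threshold=0.0,
                    both_strands=False)
        assert max(h.score for h in hits) == pytest.approx(lom.max_score)

    def test_bad_background_rejected(self):
        pwm = PWM("u", "u", np.full((4, 2), 5.0))
        with pytest.raises(ValueError):
            log_odds(pwm, background=[0.5, 0.5, 0.0, 0.0])


class TestScan:
    def test_consensus_has_relative_score_one(self):
        pwm = builtin_motifs()[1]  # DR3
        lom = log_odds(pwm)
        seq = "TT" + pwm.consensus.replace("N", "G") + "TT"
        hits = scan(seq, lom, rel_threshold=0.8)
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.offset == 2 for h in plus)
        best = max(plus, key=lambda h: h.rel_score)
        assert best.rel_score > 0.95

    def test_reverse_complement_reported_on_minus_strand(self):
        pwm = builtin_motifs()[1]
        lom = log_odds(pwm)
        site = pwm.consensus.replace("N", "G")
        seq = "AA" + reverse_complement(site) + "CC"
        hits = scan(seq, lom, rel_threshold=0.95)
        assert hits and all(h.strand == "-" for h in hits)
        assert hits[0].offset == 2

    def test_too_short_sequence_yields_no_hits(self):
        lom = log_odds(builtin_motifs()[0])
        assert scan("ACGT", lom, 0.0) == []

    def test_dimer_pwm_matches_exhaustive_oracle(self):
        pwm = PWM("d", "d", np.array([[8.0, 1], [1, 1], [1, 7], [2, 3]]))
        lom = log_odds(pwm)
        ext = lom.scores
        for dimer in ("".join(p) for p in itertools.product("ACGT", repeat=2)):
            hits = scan(dimer, lom, rel_threshold=0.0)
            idx = {"A": 0, "C": 1, "G": 2, "T": 3}
            fwd = ext[idx[dimer[0]], 0] + ext[idx[dimer[1]], 1]
            rc = reverse_complement(dimer)
            rev = ext[idx[rc[0]], 0] + ext[idx[rc[1]], 1]
            got = {(h.strand, round(h.score, 9)) for h in hits}
            assert got == {("+", round(fwd, 9)), ("-", round(rev, 9))} or (
                # same score on both strands collapses to two entries anyway
                fwd == rev and got == {("+", round(fwd, 9)), ("-", round(rev, 9))}
            )

    def test_hit_set_invariant_under_reverse_complement(self, rng):
        pwm = builtin_motifs()[1]
        lom = log_odds(pwm)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 300)])
        seq = seq[:100] + pwm.consensus.replace("N", "C") + seq[100:]
        fwd_hits = scan(seq, lom, 0.8)
        rc_hits = scan(reverse_complement(seq), lom, 0.8)
        n = len(seq)
        w = pwm.width
        mapped = {(n - h.offset - w, {"+": "-", "-": "+"}[h.strand],
                   round(h.score, 9)) for h in rc_hits}
        assert {(h.offset, h.strand, round(h.score, 9)) for h in fwd_hits} == mapped

    def test_n_bases_score_column_minimum(self):
        pwm = PWM("n", "n", np.array([[10.0], [0], [0], [0]]))
        lom = log_odds(pwm)
        hit_n = scan("N", lom, rel_threshold=0.0)
        assert hit_n[0].score == pytest.approx(lom.min_score)
        assert hit_n[0].rel_score == 0.0


class TestShuffleBackground:
    def test_homopolymer_unchanged(self):
        assert shuffle_background(["AAAA"], seed=1) == ["AAAA"]

    def test_dinucleotide_multiset_preserved(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 120)]) for _ in range(10)]
        out = shuffle_background(seqs, seed=9)
        for s, o in zip(seqs, out):
            assert len(o) == len(s)
            assert Counter(zip(o, o[1:])) == Counter(zip(s, s[1:]))

    def test_deterministic_per_seed(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 80)]) for _ in range(5)]
        assert shuffle_background(seqs, seed=4) == shuffle_background(seqs, seed=4)


class TestExtractPeakSequences:
    def test_window_and_clipping(self):
        genome = GenomeSequence({"chr1": "ACGT" * 250})  # 1000 bp
        peaks = PeakSet(
            [GenomicInterval("chr1", 290, 310), GenomicInterval("chr1", 90, 110)]
        )
        seqs = extract_peak_sequences(genome, peaks, flank=250)
        # sorted order: center 100 first (clipped to [0, 350)), then center 300
        assert len(seqs[0]) == 350
        assert seqs[1] == genome.seqs["chr1"][50:550]

    def test_matches_direct_slicing_oracle(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 5000)])
        genome = GenomeSequence({"chr1": seq})
        peaks = PeakSet(
            GenomicInterval("chr1", int(s), int(s) + 40)
            for s in rng.integers(300, 4600, 20)
        )
        for iv, got in zip(peaks, extract_peak_sequences(genome, peaks, 100)):
            c = (iv.start + iv.end) // 2
            assert got == seq[c - 100: c + 100]

    def test_missing_chromosome_raises(self):
        genome = GenomeSequence({"chr1": "ACGT" * 100})
        with pytest.raises(KeyError):
            extract_peak_sequences(genome, PeakSet([GenomicInterval("chr2", 0, 10)]), 5)


class TestMotifEnrichment:
    def _random_seqs(self, rng, n, length=150):
        bases = np.array(list("ACGT"))
        return ["".join(bases[rng.integers(0, 4, length)]) for _ in range(n)]

    def test_fg_equal_bg_not_enriched(self, rng):
        seqs = self._random_seqs(rng, 40)
        res = motif_enrichment(seqs, list(seqs), builtin_motifs(), 1e-30)
        assert not res["enriched"].any()
        assert (res["pvalue"] > 0.4).all()

    def test_planted_consensus_dominates_catalog(self, rng):
        pwm = builtin_motifs()[1]  # DR3
        site = pwm.consensus.replace("N", "T")
        fg = [
            s[:60] + site + s[60 + len(site):] for s in self._random_seqs(rng, 200)
        ]
        bg = shuffle_background(fg, seed=11)
        res = motif_enrichment(fg, bg, builtin_motifs(), 1e-30)
        assert res.iloc[0]["motif_id"] == "DR3"
        assert res.iloc[0]["pvalue"] < 1e-10
        assert bool(res.iloc[0]["enriched"])

    def test_single_motif_evalue_equals_p(self, rng):
        seqs = self._random_seqs(rng, 10)
        res = motif_enrichment(seqs, seqs, [builtin_motifs()[0]], 1e-30)
        assert res.loc[0, "evalue"] == res.loc[0, "pvalue"]

    def test_reciprocal_design_flags_only_planted_side(self, rng):
        dr3, ir3 = builtin_motifs()[1], builtin_motifs()[0]
        site_a = dr3.consensus.replace("N", "T")
        site_b = ir3.consensus.replace("N", "T")
        fg = [s[:50] + site_a + s[50 + 15:] for s in self._random_seqs(rng, 120)]
        bg = [s[:50] + site_b + s[50 + 15:] for s in self._random_seqs(rng, 120)]
        fwd = motif_enrichment(fg, bg, [dr3, ir3], 1e-10).set_index("motif_id")
        rev = motif_enrichment(bg, fg, [dr3, ir3], 1e-10).set_index("motif_id")
        assert fwd.loc["DR3", "pvalue"] < 1e-10
        assert rev.loc["DR3", "pvalue"] > 0.5
        assert rev.loc["IR3", "pvalue"] < 1e-10


class TestBuiltinMotifs:
    def test_inverted_repeat_width_15(self):
        ir3 = builtin_motifs()[0]
        assert ir3.identifier == "IR3" and ir3.width == 15

    def test_consensus_scan_single_plus_hit(self):
        ir3 = builtin_motifs()[0]
        lom = log_odds(ir3)
        hits = scan("AGAACAGGGTGTTCT", lom, rel_threshold=0.8)
        assert len(hits) >= 1
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1 and plus[0].offset == 0

    def test_dr3_not_its_own_reverse_complement(self):
        dr3 = builtin_motifs()[1]
        core = dr3.consensus.replace("N", "A")
        assert reverse_complement(core) != core
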