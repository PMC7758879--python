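"""Consensus and PWM motif scanning against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifmc.motif_scan import (
    Motif,
    count_occurrences,
    match_consensus,
    pwm_score_distribution,
    pwm_score_threshold,
    read_consensus_motifs,
    read_meme_motifs,
    scan_pwm,
)
from conftest import (
    enumeration_tail,
    naive_consensus_offsets,
    random_sequence,
    revcomp,
)


class FakePromoter:
    def __init__(self, gene_id, sequence):
        self.gene_id = gene_id
        self.sequence = sequence


class TestMatchConsensus:
    def test_palindromic_consensus_counted_once(self):
        # ACGT is self-reverse-complementary: each occurrence matches on
        # both strands but is one physical site
        assert match_consensus("AACGTACGT", "ACGT") == [(1, "+"), (5, "+")]

    def test_n_matches_everywhere(self):
        assert len(match_consensus("GATTACA", "N", both_strands=False)) == 7

    def test_no_match(self):
        assert match_consensus("CCCC", "ACGT") == []

    def test_reverse_strand_match_reported(self):
        # CCACG occurs only as reverse complement (CGTGG) here
        seq = "TTCGTGGTT"
        assert match_consensus(seq, "CCACG") == [(2, "-")]
        assert match_consensus(seq, "CCACG", both_strands=False) == []

    def test_overlapping_matches_all_reported(self):
        assert match_consensus("AAAA", "AA", both_strands=False) == \
            [(0, "+"), (1, "+"), (2, "+")]

    def test_invalid_iupac_code(self):
        with pytest.raises(ValueError, match="IUPAC"):
            match_consensus("ACGT", "AXG")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_agrees_with_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, 60)
        consensus = ["ACGT", "CCACG", "RCGTG", "TGACGTGG"][seed % 4]
        assert match_consensus(seq, consensus) == \
            naive_consensus_offsets(seq, consensus)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_strand_closure(self, seed):
        """Total count is invariant under reverse complement of the
        sequence when both strands are scanned."""
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, 80)
        for consensus in ("ACGT", "CCACG", "GGACGTCA"):
            assert len(match_consensus(seq, consensus)) == \
                len(match_consensus(revcomp(seq), consensus))


class TestPwmThreshold:
    def test_length_one_closed_form(self):
        """For a single-position indicator PWM with uniform background, a
        0.25 cutoff admits exactly the best base (tail = 0.25)."""
        motif = Motif("m", "pwm", matrix=[[1.0, 0.0, 0.0, 0.0]],
                      pvalue_threshold=0.25)
        thr = pwm_score_threshold(motif)
        scores, probs = pwm_score_distribution(motif)
        admitted = probs[scores >= thr].sum()
        assert admitted == pytest.approx(0.25)
        assert thr == pytest.approx(scores[-1])  # only the top score

    def test_uniform_matrix_admits_nothing(self):
        motif = Motif("m", "pwm", matrix=np.full((3, 4), 0.25),
                      pvalue_threshold=0.5)
        thr = pwm_score_threshold(motif)
        assert thr > 0.0
        scores, probs = pwm_score_distribution(motif)
        assert probs[scores >= thr].sum() == 0.0

    def test_distribution_sums_to_one(self, rng):
        matrix = rng.dirichlet(np.ones(4), size=6)
        motif = Motif("m", "pwm", matrix=matrix)
        _, probs = pwm_score_distribution(motif)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("length", [1, 2, 4, 6, 8])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_dp_tail_matches_enumeration(self, length, seed):
        """DP tail probability at the threshold equals exhaustive
        enumeration over all 4^L words (within the discretization bin)."""
        rng = np.random.default_rng(seed)
        matrix = rng.dirichlet(np.ones(4) * 0.5, size=length)
        bg = rng.dirichlet(np.ones(4) * 5)
        motif = Motif("m", "pwm", matrix=matrix, background=bg,
                      pvalue_threshold=0.01)
        thr = pwm_score_threshold(motif)
        scores, probs = pwm_score_distribution(motif)
        dp_tail = probs[scores >= thr].sum()
        assert dp_tail <= 0.01
        assert dp_tail == pytest.approx(enumeration_tail(motif, thr),
                                        abs=1e-9)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            pwm_score_threshold(Motif("m", "pwm",
                                      matrix=[[1.0, 0.0, 0.0, 0.0]],
                                      background=[0.5, 0.5, 0.0, 0.0]))


def indicator_pwm(word: str, pvalue: float) -> Motif:
    eye = np.eye(4)
    idx = ["ACGT".index(c) for c in word]
    return Motif(word, "pwm", matrix=eye[idx], pvalue_threshold=pvalue)


class TestScanPwm:
    def test_indicator_pwm_reproduces_consensus(self, rng):
        """A PWM that is the indicator of a word, thresholded to admit only
        that word, hits exactly where the consensus matcher does."""
        for word in ("ACGT", "CCACG"):
            motif = indicator_pwm(word, 4.0 ** -len(word) + 1e-12)
            for _ in range(20):
                seq = random_sequence(rng, 70)
                hits = [(h.offset, h.strand)
                        for h in scan_pwm(seq, motif)]
                assert hits == match_consensus(seq, word)

    def test_all_n_sequence_yields_no_hits(self):
        motif = indicator_pwm("ACGT", 0.005)
        assert scan_pwm("N" * 50, motif) == []

    def test_sequence_shorter_than_motif(self):
        assert scan_pwm("AC", indicator_pwm("ACGT", 0.005)) == []

    def test_all_scores_reach_threshold(self, rng):
        matrix = rng.dirichlet(np.ones(4) * 0.3, size=5)
        motif = Motif("m", "pwm", matrix=matrix, pvalue_threshold=0.05)
        thr = pwm_score_threshold(motif)
        hits = scan_pwm(random_sequence(rng, 500), motif)
        assert hits  # 0.05 cutoff on 500 bp: hits essentially certain
        assert all(h.score >= thr - 1e-9 for h in hits)

    def test_strand_closure(self, rng):
        matrix = rng.dirichlet(np.ones(4) * 0.3, size=5)
        motif = Motif("m", "pwm", matrix=matrix, pvalue_threshold=0.05)
        seq = random_sequence(rng, 300)
        assert len(scan_pwm(seq, motif)) == len(scan_pwm(revcomp(seq),
                                                         motif))


class TestCountOccurrences:
    def test_zero_hit_promoters_present(self):
        promoters = [FakePromoter("p1", "AACGTACGTA"),
                     FakePromoter("p2", "CCCCCCCCCC"),
                     FakePromoter("p3", "TTACGTTTTT")]
        table = count_occurrences(promoters,
                                  [Motif("core", "consensus",
                                         consensus="ACGT")])
        assert table.loc["p1", "core"] == 2
        assert table.loc["p2", "core"] == 0
        assert table.loc["p3", "core"] == 1
        assert table["core"].sum() == 3

    def test_duplicate_promoter_id_rejected(self):
        promoters = [FakePromoter("p1", "ACGT"), FakePromoter("p1", "ACGT")]
        with pytest.raises(ValueError, match="duplicate"):
            count_occurrences(promoters, [Motif("m", "consensus",
                                                consensus="ACGT")])

    def test_counts_match_naive_oracle(self, rng):
        promoters = [FakePromoter(f"p{i}", random_sequence(rng, 200))
                     for i in range(100)]
        motifs = [Motif(n, "consensus", consensus=c) for n, c in [
            ("ACGT_core", "ACGT"), ("CCACG_box", "CCACG"),
            ("UPREA_like", "GATGACGTGK"), ("UPREB_like", "ATTGCA")]]
        table = count_occurrences(promoters, motifs)
        for p in promoters:
            for m in motifs:
                expected = len(naive_consensus_offsets(p.sequence,
                                                       m.consensus))
                assert table.loc[p.gene_id, m.name] == expected


class TestMotifIO:
    def test_consensus_file_round_trip(self, tmp_path):
        p = tmp_path / "motifs.tsv"
        p.write_text("# illustrative motifs\nACGT_core\tACGT\n"
                     "UPREA_like\tGATGACGTGK\n")
        motifs = read_consensus_motifs(p)
        assert [(m.name, m.consensus) for m in motifs] == \
            [("ACGT_core", "ACGT"), ("UPREA_like", "GATGACGTGK")]

    def test_meme_minimal_format(self, tmp_path):
        p = tmp_path / "motifs.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
            "MOTIF toy\nletter-probability matrix: alength= 4 w= 3 "
            "nsites= 20 E= 0\n"
            " 0.90 0.05 0.03 0.02\n 0.05 0.80 0.10 0.05\n"
            " 0.10 0.10 0.10 0.70\n")
        (motif,) = read_meme_motifs(p)
        assert motif.kind == "pwm" and motif.length == 3
        assert motif.matrix[0, 0] == pytest.approx(0.9, abs=1e-6)
        assert np.allclose(motif.matrix.sum(axis=1), 1.0)
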