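"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's scanning code paths:
consensus matching is re-done by per-character comparison, PWM tail
probabilities by exhaustive enumeration over all 4^L words, and overlap /
coverage counts by explicit double loops.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from motifmc.motif_scan import IUPAC_CODES, Motif, _log_odds_quantized

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def naive_consensus_offsets(sequence: str, consensus: str,
                            both_strands: bool = True
                            ) -> list[tuple[int, str]]:
    """Quadratic character-by-character IUPAC matcher (test oracle).

    Matches the consensus at every offset on the forward strand and, for
    both_strands, matches it against the reverse complement of each window;
    a self-reverse-complementary window matching both ways counts once.
    """
    L = len(consensus)
    hits = []
    for o in range(len(sequence) - L + 1):
        window = sequence[o:o + L]
        fwd = all(b in IUPAC_CODES[c] for b, c in zip(window, consensus))
        if fwd:
            hits.append((o, "+"))
        if both_strands:
            rc_window = revcomp(window)
            rev = all(b in IUPAC_CODES[c]
                      for b, c in zip(rc_window, consensus))
            if rev and not (fwd and window == rc_window):
                hits.append((o, "-"))
    return sorted(hits)


def enumeration_tail(motif: Motif, threshold_bits: float) -> float:
    """P(score >= threshold) by summing over all 4^L words (test oracle)."""
    q = _log_odds_quantized(motif)
    L = q.shape[0]
    bg = motif.background
    tail = 0.0
    for word in itertools.product(range(4), repeat=L):
        score = sum(q[i, b] for i, b in enumerate(word)) * motif.bin_width
        if score >= threshold_bits - 1e-12:
            tail += float(np.prod([bg[b] for b in word]))
    return tail


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_genome_files(tmp_path):
    """A hand-built two-contig genome + annotation on disk."""
    rng = np.random.default_rng(7)
    chr1 = random_sequence(rng, 3000)
    chr2 = random_sequence(rng, 2000)
    fasta = tmp_path / "genome.fasta"
    with open(fasta, "w") as fh:
        fh.write(f">chrI test contig\n{chr1}\n>chrII\n{chr2}\n")
    gff = tmp_path / "genes.gff3"
    rows = [
        "chrI\t.\tgene\t1001\t2000\t.\t+\t.\tID=g1",
        "chrI\t.\tgene\t2301\t2900\t.\t-\t.\tID=g2",
        "chrII\t.\tgene\t501\t1700\t.\t+\t.\tID=g3",
        "chrII\t.\tmRNA\t501\t1700\t.\t+\t.\tID=t3",
        "chrII\t.\tgene\t1850\t1949\t.\t+\t.\tID=g4_short",
    ]
    gff.write_text("##gff-version 3\n" + "\n".join(rows) + "\n")
    return fasta, gff, {"chrI": chr1, "chrII": chr2}
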