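"""Motif occurrence scanning in promoter sequences.

Two motif representations are supported:

* IUPAC consensus strings, matched exactly (with ambiguity codes) on both
  strands; overlapping matches are all reported.
* Position weight matrices (PWMs) scored by log-odds against a background
  model, with the score threshold derived from a match p-value cutoff the way
  FIMO does it: the exact distribution of log-odds scores of random words
  under the background model is computed by dynamic programming over
  discretized per-position scores, and the threshold is the smallest score
  whose tail probability does not exceed the cutoff (default 1e-4).

Palindrome convention: an occurrence whose window sequence is its own reverse
complement and which therefore matches identically on both strands is
reported once, with strand '+'.  This prevents self-complementary motifs such
as the ACGT core from being double-counted when both strands are scanned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_BIN_WIDTH = 0.01  # bits; discretization granularity of the score DP
DEFAULT_PVALUE = 1e-4     # FIMO's default match p-value cutoff

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _revcomp_iupac(consensus: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(consensus))


@dataclass
class Motif:
    """A named motif: IUPAC consensus or PWM with background model.

    ``matrix`` is an (L, 4) array of per-position base probabilities in
    A,C,G,T order; ``background`` is the length-4 background distribution.
    ``pvalue_threshold`` is the match p-value cutoff used to derive the PWM
    score threshold.
    """

    name: str
    kind: str  # "consensus" | "pwm"
    consensus: str | None = None
    matrix: np.ndarray | None = None
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pvalue_threshold: float = DEFAULT_PVALUE
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(
                self.background.sum(), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.name}: background must be 4 "
                             f"probabilities summing to 1")
        if self.kind == "consensus":
            if not self.consensus:
                raise ValueError(f"motif {self.name}: consensus required")
            bad = set(self.consensus.upper()) - set(IUPAC_CODES)
            if bad:
                raise ValueError(
                    f"motif {self.name}: invalid IUPAC codes {sorted(bad)}")
            self.consensus = self.consensus.upper()
        elif self.kind == "pwm":
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 \
                    or self.matrix.shape[0] < 1:
                raise ValueError(f"motif {self.name}: matrix must be (L, 4)")
            if np.any(self.matrix < 0) or np.any(self.matrix > 1):
                raise ValueError(
                    f"motif {self.name}: probabilities outside [0,1]")
            if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(
                    f"motif {self.name}: matrix rows must sum to 1")
        else:
            raise ValueError(f"motif {self.name}: kind must be 'consensus' "
                             f"or 'pwm', got {self.kind!r}")

    @property
    def length(self) -> int:
        if self.kind == "consensus":
            return len(self.consensus)
        return self.matrix.shape[0]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence within a promoter sequence.

    ``offset`` is the 0-based start within the promoter; ``strand`` is
    relative to the promoter orientation; ``score`` is the log-odds score in
    bits (0.0 for consensus matches).
    """

    promoter_id: str
    motif_name: str
    offset: int
    strand: str
    score: float = 0.0


def match_consensus(sequence: str, consensus: str,
                    both_strands: bool = True) -> list[tuple[int, str]]:
    """All (offset, strand) occurrences of an IUPAC consensus.

    Overlapping matches are all reported.  With ``both_strands`` the reverse
    complement of the consensus is also matched against the forward sequence;
    a window that is its own reverse complement and matches on both strands
    is reported once, with strand '+'.
    """
    consensus = consensus.upper()
    bad = set(consensus) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC codes {sorted(bad)}")
    sequence = sequence.upper()
    fwd = set(_regex_offsets(sequence, consensus))
    hits = [(o, "+") for o in fwd]
    if both_strands:
        L = len(consensus)
        for o in _regex_offsets(sequence, _revcomp_iupac(consensus)):
            window = sequence[o:o + L]
            if o in fwd and window == reverse_complement(window):
                continue  # identical occurrence on both strands
            hits.append((o, "-"))
    return sorted(hits)


def _regex_offsets(sequence: str, consensus: str) -> list[int]:
    # lookahead so overlapping occurrences are all found; N in the sequence
    # never matches (ambiguity codes apply to the pattern only)
    pattern = "(?=" + "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + IUPAC_CODES[c] + "]"
        for c in consensus) + ")"
    return [m.start() for m in re.finditer(pattern, sequence)]


def _log_odds_quantized(motif: Motif) -> np.ndarray:
    """Per-position integer log-odds scores in units of ``bin_width`` bits.

    Pseudocount is added to each matrix probability and rows renormalized
    before taking log2 odds, so no entry is -inf for positive background.
    """
    if np.any(motif.background <= 0):
        raise ValueError(
            f"motif {motif.name}: background probabilities must be positive "
            f"for log-odds scoring")
    p = motif.matrix + motif.pseudocount
    p = p / p.sum(axis=1, keepdims=True)
    lo = np.log2(p / motif.background)
    return np.rint(lo / motif.bin_width).astype(np.int64)


def pwm_score_distribution(motif: Motif
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Exact background distribution of quantized log-odds scores.

    Returns ``(scores_bits, probs)``: every achievable quantized total score
    (in bits, ascending) of a random L-mer drawn i.i.d. from the background,
    with its exact probability.  Computed by dynamic programming
    (convolution of the per-position discrete score distributions), not by
    sampling.
    """
    q = _log_odds_quantized(motif)
    lo_min = int(q.min(axis=1).sum())
    lo_max = int(q.max(axis=1).sum())
    dist = np.zeros(lo_max - lo_min + 1)
    dist[0] = 1.0
    base = 0  # dist[i] = P(partial sum == base + i); base tracks the minima
    for i in range(q.shape[0]):
        qmin = int(q[i].min())
        new = np.zeros_like(dist)
        for b in range(4):
            shift = int(q[i, b]) - qmin
            contrib = dist * motif.background[b]
            new[shift:] += contrib[:len(dist) - shift] if shift else contrib
        dist = new
        base += qmin
    support = np.nonzero(dist)[0]
    scores_int = base + support
    return scores_int * motif.bin_width, dist[support]


def pwm_score_threshold(motif: Motif,
                        pvalue_threshold: float | None = None) -> float:
    """Smallest quantized score s* with background tail P(score >= s*) <=
    the p-value cutoff.

    If even the maximum achievable score has tail probability above the
    cutoff, one bin above the maximum is returned (no word admitted).
    """
    if pvalue_threshold is None:
        pvalue_threshold = motif.pvalue_threshold
    scores, probs = pwm_score_distribution(motif)
    # tail[i] = P(score >= scores[i])
    tail = probs[::-1].cumsum()[::-1]
    admissible = np.nonzero(tail <= pvalue_threshold)[0]
    if len(admissible) == 0:
        return scores[-1] + motif.bin_width
    return float(scores[admissible[0]])


_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Quantized log-odds score of every window; windows with N get -inf."""
    L = q.shape[0]
    # 5th column: N scores -inf so such windows are never reported
    q5 = np.hstack([q.astype(float), np.full((L, 1), -np.inf)])
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    return q5[np.arange(L), win].sum(axis=1)


def scan_pwm(sequence: str, motif: Motif, both_strands: bool = True,
             threshold: float | None = None,
             promoter_id: str = "") -> list[MotifHit]:
    """All windows whose log-odds score reaches the motif's threshold.

    Scores are quantized to the motif's bin width, consistently with the
    threshold computed by :func:`pwm_score_threshold`.  Windows containing N
    never match.  A self-reverse-complementary window passing on both
    strands is reported once, with strand '+'.
    """
    if motif.kind != "pwm":
        raise ValueError(f"motif {motif.name} is not a PWM")
    L = motif.length
    if len(sequence) < L:
        return []
    if threshold is None:
        threshold = pwm_score_threshold(motif)
    thr_int = int(round(threshold / motif.bin_width))
    q = _log_odds_quantized(motif)
    codes = _encode(sequence)
    fwd_scores = _window_scores(codes, q)
    hits: list[MotifHit] = []
    fwd_pass = np.nonzero(fwd_scores >= thr_int)[0]
    for o in fwd_pass:
        hits.append(MotifHit(promoter_id, motif.name, int(o), "+",
                             float(fwd_scores[o]) * motif.bin_width))
    if both_strands:
        # a '-' hit means the reverse complement of the window matches the
        # motif, i.e. the window scores high under the reversed-complemented
        # matrix
        rc_scores = _window_scores(codes, q[::-1, ::-1])
        fwd_set = set(int(o) for o in fwd_pass)
        for o in np.nonzero(rc_scores >= thr_int)[0]:
            o = int(o)
            if o in fwd_set:
                window = codes[o:o + L]
                if np.array_equal(window, (3 - window)[::-1]):
                    continue  # palindromic double match, already counted
            hits.append(MotifHit(promoter_id, motif.name, o, "-",
                                 float(rc_scores[o]) * motif.bin_width))
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def scan_motif(sequence: str, motif: Motif, both_strands: bool = True,
               promoter_id: str = "") -> list[MotifHit]:
    """Dispatch on motif kind; returns all occurrences as MotifHits."""
    if motif.kind == "consensus":
        return [MotifHit(promoter_id, motif.name, o, s, 0.0)
                for o, s in match_consensus(sequence, motif.consensus,
                                            both_strands)]
    return scan_pwm(sequence, motif, both_strands, promoter_id=promoter_id)


def count_occurrences(promoters, motifs: list[Motif],
                      both_strands: bool = True) -> pd.DataFrame:
    """Per-promoter, per-motif occurrence counts.

    Rows are promoter/gene ids, columns motif names; promoters with zero
    hits appear with count 0.  PWM thresholds are computed once per motif.
    """
    ids = [p.gene_id for p in promoters]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate promoter ids: {dupes}")
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names")
    counts = np.zeros((len(ids), len(motifs)), dtype=np.int64)
    for j, motif in enumerate(motifs):
        thr = pwm_score_threshold(motif) if motif.kind == "pwm" else None
        for i, p in enumerate(promoters):
            if motif.kind == "pwm":
                hits = scan_pwm(p.sequence, motif, both_strands,
                                threshold=thr, promoter_id=p.gene_id)
            else:
                hits = scan_motif(p.sequence, motif, both_strands,
                                  promoter_id=p.gene_id)
            counts[i, j] = len(hits)
    return pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"),
                        columns=names)


def read_consensus_motifs(path: str | Path,
                          pvalue_threshold: float = DEFAULT_PVALUE
                          ) -> list[Motif]:
    """Read `name<TAB>IUPAC` consensus motifs; '#' comments allowed."""
    out: list[Motif] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"'name<TAB>consensus'")
            name, consensus = parts
            out.append(Motif(name=name, kind="consensus",
                             consensus=consensus,
                             pvalue_threshold=pvalue_threshold))
    return out


def read_meme_motifs(path: str | Path,
                     pvalue_threshold: float = DEFAULT_PVALUE
                     ) -> list[Motif]:
    """Read PWMs from MEME minimal-format text via Biopython."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
        out: list[Motif] = []
        for rec in records:
            L = rec.length
            matrix = np.array([[rec.pwm[b][i] for b in "ACGT"]
                               for i in range(L)])
            bg = np.array([rec.background[b] for b in "ACGT"])
            bg = bg / bg.sum()
            # minimal-format probability rows can be rounded; renormalize
            matrix = matrix / matrix.sum(axis=1, keepdims=True)
            out.append(Motif(name=rec.name, kind="pwm", matrix=matrix,
                             background=bg,
                             pvalue_threshold=pvalue_threshold))
    return out


def write_hits_bed(hits: list[MotifHit], path: str | Path,
                   motif_lengths: dict[str, int]) -> None:
    """BED-like hit output: promoter_id, start, end, motif, score, strand."""
    with open(path, "w") as fh:
        for h in hits:
            end = h.offset + motif_lengths[h.motif_name]
            fh.write(f"{h.promoter_id}\t{h.offset}\t{end}\t{h.motif_name}\t"
                     f"{h.score:.4f}\t{h.strand}\n")


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_count_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
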