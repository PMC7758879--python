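"""Genome sequence / annotation input and strand-aware promoter extraction.

Promoters are windows around the transcription start site (TSS), by default
100 bp upstream + 100 bp downstream (200 bp total).  The TSS is the 5' end of
the annotated gene feature: ``start`` for plus-strand genes, ``end`` for
minus-strand genes.  Minus-strand promoter sequences are reverse-complemented
so that every returned sequence reads 5'->3' relative to its gene.

Coordinate conventions: GFF3 input is 1-based inclusive; everything internal
is 0-based half-open.  The conversion happens once, at the parser boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised on malformed FASTA input."""


class GFFParseError(ValueError):
    """Raised when a GFF3 file cannot be parsed at all."""


class GFFRowError(ValueError):
    """Raised when individual GFF3 rows are invalid; carries per-row messages."""

    def __init__(self, row_errors: list[str]):
        self.row_errors = list(row_errors)
        super().__init__(
            "invalid GFF3 rows:\n" + "\n".join(self.row_errors)
        )


@dataclass
class GenomeSequence:
    """Nucleotide sequences keyed by contig name, alphabet {A,C,G,T,N}."""

    contigs: dict[str, str]

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class GeneRecord:
    """A gene feature with 1-based inclusive coordinates, as in GFF3."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss0(self) -> int:
        """0-based position of the TSS (5' end of the feature)."""
        return self.start - 1 if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PromoterRegion:
    """A strand-aware promoter window.

    ``window_start``/``window_end`` are 0-based half-open *genomic*
    coordinates; ``sequence`` is in transcription orientation (already
    reverse-complemented for minus-strand genes).  ``clipped`` flags windows
    truncated at a contig edge under ``edge_policy="clip"``.
    """

    gene_id: str
    contig: str
    strand: str
    window_start: int
    window_end: int
    sequence: str
    clipped: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    Headers are truncated at the first whitespace; sequences are uppercased.
    Characters outside {A,C,G,T,N} raise :class:`FastaParseError`.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FastaParseError(
                f"{path}: line 1: expected FASTA header starting with '>'"
            )
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        seq = str(record.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {name!r} has empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FastaParseError(
                f"{path}: record {name!r} contains invalid characters "
                f"{sorted(bad)}"
            )
        if name in contigs:
            raise FastaParseError(f"{path}: duplicate contig name {name!r}")
        contigs[name] = seq
    if not contigs:
        raise FastaParseError(f"{path}: no FASTA records found")
    return GenomeSequence(contigs)


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write (name, sequence) pairs as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_gff_genes(path: str | Path, feature_type: str = "gene"
                   ) -> list[GeneRecord]:
    """Read gene features from a GFF3 file.

    Keeps rows whose type column equals ``feature_type``; ``gene_id`` comes
    from the ``ID`` attribute.  Rows with inverted coordinates or a missing
    ID are collected and reported together in a :class:`GFFRowError`.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    row_errors: list[str] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(fields)}"
                )
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, \
                attrs = fields
            if ftype != feature_type:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                row_errors.append(
                    f"line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}")
                continue
            gene_id = _gff_attribute(attrs, "ID")
            if gene_id is None:
                row_errors.append(f"line {lineno}: missing ID attribute")
                continue
            if start > end:
                row_errors.append(
                    f"line {lineno}: gene {gene_id}: start {start} > end {end}")
                continue
            if strand not in ("+", "-"):
                row_errors.append(
                    f"line {lineno}: gene {gene_id}: strand {strand!r}")
                continue
            if gene_id in seen_ids:
                row_errors.append(f"line {lineno}: duplicate gene id {gene_id}")
                continue
            seen_ids.add(gene_id)
            genes.append(GeneRecord(gene_id, contig, strand, start, end))
    if row_errors:
        raise GFFRowError(row_errors)
    return genes


def _gff_attribute(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            value = part[len(key) + 1:]
            return value or None
    return None


def filter_by_length(genes: list[GeneRecord], min_length: int = 500
                     ) -> list[GeneRecord]:
    """Keep genes strictly longer than ``min_length`` bp, preserving order.

    The strict inequality excludes the abundant very short worm genes that
    would otherwise bias the random-set background.
    """
    kept = [g for g in genes if g.length > min_length]
    logger.info("length filter >%d bp: kept %d of %d genes",
                min_length, len(kept), len(genes))
    return kept


def extract_promoters(genome: GenomeSequence,
                      genes: list[GeneRecord],
                      upstream: int = 100,
                      downstream: int = 100,
                      edge_policy: str = "drop",
                      ) -> tuple[list[PromoterRegion], list[tuple[str, str]]]:
    """Extract strand-aware promoter windows around each gene's TSS.

    For a plus-strand gene the genomic window is
    ``[TSS - upstream, TSS + downstream)`` (0-based half-open, TSS = 0-based
    start); a minus-strand window mirrors it around TSS = 0-based end and the
    sequence is reverse-complemented.  Windows extending past contig bounds
    are dropped (``edge_policy="drop"``, the default, so all promoters share
    one length) or clipped and flagged (``edge_policy="clip"``).

    Returns ``(promoters, dropped)`` where ``dropped`` is a list of
    ``(gene_id, reason)`` pairs.
    """
    if edge_policy not in ("drop", "clip"):
        raise ValueError(f"edge_policy must be 'drop' or 'clip', "
                         f"got {edge_policy!r}")
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be nonnegative")
    promoters: list[PromoterRegion] = []
    dropped: list[tuple[str, str]] = []
    for gene in genes:
        if gene.contig not in genome:
            raise KeyError(
                f"gene {gene.gene_id} references unknown contig "
                f"{gene.contig!r}")
        contig_seq = genome[gene.contig]
        tss = gene.tss0
        if gene.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream + 1, tss + upstream + 1
        clipped = False
        if lo < 0 or hi > len(contig_seq):
            if edge_policy == "drop":
                dropped.append(
                    (gene.gene_id,
                     f"window [{lo},{hi}) outside contig "
                     f"{gene.contig} (length {len(contig_seq)})"))
                continue
            lo, hi = max(lo, 0), min(hi, len(contig_seq))
            clipped = True
        seq = contig_seq[lo:hi]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        promoters.append(PromoterRegion(
            gene_id=gene.gene_id, contig=gene.contig, strand=gene.strand,
            window_start=lo, window_end=hi, sequence=seq, clipped=clipped))
    if dropped:
        logger.info("extract_promoters: dropped %d of %d genes at contig "
                    "edges", len(dropped), len(genes))
    return promoters, dropped


def write_dropped_report(dropped: list[tuple[str, str]],
                         path: str | Path) -> None:
    """Write the dropped-gene report as tab-separated (gene_id, reason)."""
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for gene_id, reason in dropped:
            fh.write(f"{gene_id}\t{reason}\n")
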