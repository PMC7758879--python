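"""Synthetic genomes, gene sets and behavioral records with known truth.

The genome generator lays genes head-to-tail on one contig, on alternating
strands (which exercises reverse-complement promoter extraction by
construction), separated by intergenic spacers wide enough that promoter
windows never collide.  Background sequence is i.i.d. from a configurable
base composition.  Motif instances are planted into promoter windows at
Poisson-distributed per-promoter rates that differ between a designated
target gene set and the background; every plant is recorded, so per-promoter
motif counts have exact ground truth whenever the motif's random-match
probability is negligible.

Behavioral generators emulate the assay readouts: a food-leaving log where
each remaining worm leaves independently each minute with a fixed hazard
(absorbing within the window), and an exploration track produced by a lazy
random walk on the plate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from motifmc.behavior_stats import ExplorationGrid, LeavingEventLog
from motifmc.genome_io import GeneRecord, GenomeSequence
from motifmc.mc_enrichment import GeneSet
from motifmc.motif_scan import IUPAC_CODES, Motif

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticGenomeSpec:
    """Parameters of a synthetic genome with planted motifs.

    Planting rates are expected motif instances per promoter (Poisson).
    ``intergenic_length`` must be at least ``upstream + downstream`` so that
    adjacent promoter windows cannot overlap.
    """

    n_genes: int = 2000
    gene_length: int = 1000
    intergenic_length: int = 200
    base_composition: tuple[float, float, float, float] = (
        0.25, 0.25, 0.25, 0.25)
    motifs: list[Motif] = field(default_factory=list)
    planting_rate_background: float = 0.5
    planting_rate_target: float = 2.0
    target_set_size: int = 200
    upstream: int = 100
    downstream: int = 100
    seed: int = 0
    contig_name: str = "chrS"

    def __post_init__(self):
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0, atol=1e-9):
            raise ValueError("base_composition must be 4 probabilities "
                             "summing to 1")
        if self.planting_rate_background < 0 or self.planting_rate_target < 0:
            raise ValueError("planting rates must be >= 0")
        if self.target_set_size > self.n_genes:
            raise ValueError("target_set_size exceeds n_genes")
        if self.intergenic_length < self.upstream + self.downstream:
            raise ValueError(
                "intergenic_length must be >= upstream + downstream so "
                "promoter windows never collide")
        if self.gene_length < self.downstream:
            raise ValueError("gene_length must be >= downstream")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated genome.

    ``plants`` records every planted instance as
    (gene_id, motif_name, offset-within-promoter, strand); offsets are in
    transcription orientation, matching scanner output.
    """

    target_set: GeneSet
    plants: list[tuple[str, str, int, str]]
    expected_mean_target: float
    expected_mean_background: float

    def plant_counts(self) -> dict[tuple[str, str], int]:
        """Planted instances per (gene_id, motif_name)."""
        out: dict[tuple[str, str], int] = {}
        for gene_id, motif_name, _o, _s in self.plants:
            key = (gene_id, motif_name)
            out[key] = out.get(key, 0) + 1
        return out


@dataclass
class SyntheticBehaviorSpec:
    """Parameters of synthetic behavioral records."""

    n_worms: int = 20
    per_minute_leaving_prob: float = 0.05
    duration: int = 15
    grid_shape: tuple[int, int] = (21, 21)
    walk_steps: int = 200
    stay_prob: float = 1.0 / 9.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.per_minute_leaving_prob <= 1.0:
            raise ValueError("per_minute_leaving_prob must be in [0,1]")
        if not 0.0 <= self.stay_prob < 1.0:
            raise ValueError("stay_prob must be in [0,1)")


def _realize_motif(motif: Motif, rng: np.random.Generator) -> str:
    """One concrete instance of a motif to plant.

    Consensus: ambiguity codes resolved uniformly at random.  PWM: the
    per-position maximum-probability base, which is guaranteed to score at
    or above any threshold that admits some word.
    """
    if motif.kind == "consensus":
        return "".join(
            c if len(IUPAC_CODES[c]) == 1
            else IUPAC_CODES[c][rng.integers(len(IUPAC_CODES[c]))]
            for c in motif.consensus)
    return "".join("ACGT"[i] for i in motif.matrix.argmax(axis=1))


def _place_nonoverlapping(window_len: int, lengths: list[int],
                          rng: np.random.Generator) -> list[int]:
    """Random non-overlapping offsets for instances of given lengths.

    Constructive gap sampling: instances are laid out in random order along
    the window with the free space distributed via sorted uniform draws, so
    placement succeeds whenever the instances fit at all.
    """
    k = len(lengths)
    free = window_len - sum(lengths)
    if free < 0:
        raise RuntimeError(
            f"cannot place {k} instances totalling {sum(lengths)} bp in a "
            f"{window_len} bp window")
    order = rng.permutation(k)
    starts = np.sort(rng.integers(0, free + 1, size=k))
    offsets = [0] * k
    cum = 0
    for slot, idx in enumerate(order):
        offsets[idx] = int(starts[slot]) + cum
        cum += lengths[idx]
    return offsets


def generate_genome(spec: SyntheticGenomeSpec
                    ) -> tuple[GenomeSequence, list[GeneRecord],
                               SyntheticTruth]:
    """Generate a genome, its gene annotation, and the planting truth."""
    rng = np.random.default_rng(spec.seed)
    unit = spec.gene_length + spec.intergenic_length
    total = spec.n_genes * unit + spec.intergenic_length
    codes = rng.choice(4, size=total,
                       p=np.asarray(spec.base_composition, dtype=float))
    seq = _BASES[codes].copy()

    genes: list[GeneRecord] = []
    for i in range(spec.n_genes):
        start0 = spec.intergenic_length + i * unit
        end0 = start0 + spec.gene_length - 1
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneRecord(
            gene_id=f"g{i + 1:05d}", contig=spec.contig_name, strand=strand,
            start=start0 + 1, end=end0 + 1))

    gene_ids = [g.gene_id for g in genes]
    target_ids = rng.choice(gene_ids, size=spec.target_set_size,
                            replace=False)
    target = GeneSet("target", target_ids)

    window_len = spec.upstream + spec.downstream
    plants: list[tuple[str, str, int, str]] = []
    for gene in genes:
        rate = (spec.planting_rate_target if gene.gene_id in target
                else spec.planting_rate_background)
        requested: list[tuple[Motif, str]] = []
        for motif in spec.motifs:
            for _ in range(rng.poisson(rate)):
                requested.append((motif, _realize_motif(motif, rng)))
        if not requested:
            continue
        offsets = _place_nonoverlapping(
            window_len, [len(inst) for _, inst in requested], rng)
        tss = gene.tss0
        if gene.strand == "+":
            win_lo = tss - spec.upstream
        else:
            win_hi = tss + spec.upstream + 1
        for (motif, instance), offset in zip(requested, offsets):
            if gene.strand == "+":
                g_lo = win_lo + offset
                planted = instance
            else:
                g_lo = win_hi - offset - len(instance)
                planted = _revcomp(instance)
            seq[g_lo:g_lo + len(instance)] = np.frombuffer(
                planted.encode(), dtype=np.uint8)
            plants.append((gene.gene_id, motif.name, offset, "+"))

    genome = GenomeSequence({spec.contig_name: seq.tobytes().decode()})
    truth = SyntheticTruth(
        target_set=target, plants=plants,
        expected_mean_target=spec.planting_rate_target,
        expected_mean_background=spec.planting_rate_background)
    return genome, genes, truth


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def generate_leaving_log(spec: SyntheticBehaviorSpec,
                         rng: np.random.Generator | None = None,
                         timepoint_h: float = 0.0) -> LeavingEventLog:
    """Simulate a food-leaving assay with a constant per-minute hazard.

    Each remaining worm leaves in each minute independently with
    ``per_minute_leaving_prob``; leaving is absorbing.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    worms = spec.n_worms
    minutes: list[tuple[int, int]] = []
    for _ in range(spec.duration):
        leavers = int(rng.binomial(worms, spec.per_minute_leaving_prob)) \
            if worms > 0 else 0
        minutes.append((worms, leavers))
        worms -= leavers
    return LeavingEventLog(minutes=minutes, timepoint_h=timepoint_h)


_MOVES = np.array([(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)])


def generate_track(spec: SyntheticBehaviorSpec,
                   rng: np.random.Generator | None = None
                   ) -> ExplorationGrid:
    """Simulate an exploration track as a lazy random walk from the patch.

    At each step the worm stays with ``stay_prob`` and otherwise moves to a
    uniformly chosen 8-neighbor; moves off the plate are clamped to the
    boundary.  Occupancy marks every visited square.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    occupancy = np.zeros((rows, cols), dtype=bool)
    r, c = rows // 2, cols // 2
    patch = (r, c)
    occupancy[r, c] = True
    for _ in range(spec.walk_steps):
        if rng.random() < spec.stay_prob:
            continue
        dr, dc = _MOVES[rng.integers(len(_MOVES))]
        r = min(max(r + int(dr), 0), rows - 1)
        c = min(max(c + int(dc), 0), cols - 1)
        occupancy[r, c] = True
    return ExplorationGrid(occupancy=occupancy, patch_center=patch)


def write_gff3(genes: list[GeneRecord], path: str | Path,
               source: str = "motifmc") -> None:
    """Write gene records as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.contig}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Tab-separated planting manifest (gene_id, motif, offset, strand)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tmotif\toffset\tstrand\n")
        for gene_id, motif_name, offset, strand in truth.plants:
            fh.write(f"{gene_id}\t{motif_name}\t{offset}\t{strand}\n")
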