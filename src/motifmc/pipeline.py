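"""In-memory composition of the enrichment pipeline on synthetic genomes.

One call generates a genome with planted motifs, extracts promoters, counts
occurrences and runs the Monte Carlo test against the target set — the
simulation loop used for power and calibration studies.
"""

from __future__ import annotations

from motifmc.genome_io import extract_promoters, filter_by_length
from motifmc.mc_enrichment import (
    GeneSet,
    MCConfig,
    MonteCarloResult,
    run_mc_test,
)
from motifmc.motif_scan import Motif, count_occurrences
from motifmc.synthetic_data import SyntheticGenomeSpec, generate_genome


def run_simulated_study(genome_spec: SyntheticGenomeSpec,
                        n_random_sets: int = 500,
                        random_set_size: int | None = None,
                        min_gene_length: int = 500,
                        mc_seed: int | None = None) -> MonteCarloResult:
    """Full pipeline on one synthetic genome; returns the test result for
    the planted motif against the generated target set.

    The null-set size defaults to the target-set size; the Monte Carlo seed
    defaults to the genome seed + 1 so the two random streams differ.
    """
    if len(genome_spec.motifs) != 1:
        raise ValueError("run_simulated_study expects exactly one motif")
    motif = genome_spec.motifs[0]
    genome, genes, truth = generate_genome(genome_spec)
    kept = filter_by_length(genes, min_gene_length)
    promoters, _ = extract_promoters(
        genome, kept, upstream=genome_spec.upstream,
        downstream=genome_spec.downstream)
    table = count_occurrences(promoters, [motif])
    universe = GeneSet("universe", [p.gene_id for p in promoters])
    cfg = MCConfig(
        universe=universe, n_random_sets=n_random_sets,
        random_set_size=random_set_size or genome_spec.target_set_size,
        min_gene_length=min_gene_length,
        seed=mc_seed if mc_seed is not None else genome_spec.seed + 1)
    (result,) = run_mc_test(table, truth.target_set, [motif.name], cfg)
    return result
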