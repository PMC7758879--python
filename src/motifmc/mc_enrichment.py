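"""Monte Carlo promoter-motif enrichment test and gene-set overlap accounting.

The test statistic is the mean number of motif occurrences per promoter over
a gene set.  The observed set's mean is compared with the means of random
gene sets (default 2000 sets of 750 genes) sampled uniformly without
replacement from a background universe of genes passing the length filter.
The empirical p-value is the proportion of random sets with a strictly
higher mean count; the conservative (k+1)/(R+1) estimator is reported
alongside because the strict proportion can be exactly zero.  One shared
family of null sets is used across all motifs, matching a single family of
null cumulative curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids."""

    name: str
    gene_ids: frozenset[str]

    def __init__(self, name: str, gene_ids):
        ids = list(gene_ids)
        fs = frozenset(ids)
        if not fs:
            raise ValueError(f"gene set {name!r} is empty")
        if len(fs) != len(ids):
            raise ValueError(f"gene set {name!r} has duplicate ids")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "gene_ids", fs)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


@dataclass
class MCConfig:
    """Monte Carlo test configuration.

    Defaults follow the published procedure: 2000 random sets of 750 genes,
    background restricted to genes longer than 500 bp.
    """

    universe: GeneSet
    n_random_sets: int = 2000
    random_set_size: int = 750
    min_gene_length: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_random_sets < 1:
            raise ValueError("n_random_sets must be >= 1")
        if self.random_set_size > len(self.universe):
            raise ValueError(
                f"random_set_size {self.random_set_size} exceeds universe "
                f"size {len(self.universe)}")
        if self.random_set_size < 1:
            raise ValueError("random_set_size must be >= 1")


@dataclass
class MonteCarloResult:
    """Result of the Monte Carlo test for one (motif, gene set) pair.

    ``curve`` is the empirical CDF of the null means scaled to percent:
    sorted (mean, cumulative percentage) pairs ending at exactly 100%.
    """

    motif_name: str
    set_name: str
    observed_mean: float
    null_means: np.ndarray
    empirical_p: float
    empirical_p_conservative: float
    curve: list[tuple[float, float]]
    n_random_sets: int
    random_set_size: int
    seed: int


@dataclass
class OverlapReport:
    """Intersection counts of up/down query sets with a reference set."""

    query_up_name: str
    query_down_name: str
    reference_name: str
    n_reference: int
    n_up_overlap: int
    n_down_overlap: int


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene set from text: one gene id per line, '#' comments."""
    path = Path(path)
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line)
    return GeneSet(name or path.stem, ids)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(gene_set.gene_ids):
            fh.write(gid + "\n")


def mean_count(table: pd.DataFrame, gene_set: GeneSet,
               motif_name: str) -> float:
    """Arithmetic mean motif count per promoter over the set's genes."""
    if motif_name not in table.columns:
        raise KeyError(f"motif {motif_name!r} not in count table")
    missing = sorted(gene_set.gene_ids - set(table.index))
    if missing:
        raise KeyError(
            f"gene set {gene_set.name!r}: genes absent from count table: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    return float(table.loc[sorted(gene_set.gene_ids), motif_name].mean())


def sample_null_sets(universe: GeneSet, config: MCConfig,
                     rng: np.random.Generator | None = None
                     ) -> list[GeneSet]:
    """Draw ``n_random_sets`` gene sets of ``random_set_size`` genes each.

    Sampling is uniform without replacement within a set and independent
    across sets, fully reproducible from the config seed.
    """
    if config.random_set_size > len(universe):
        raise ValueError("random_set_size exceeds universe size")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids = np.array(sorted(universe.gene_ids))
    return [
        GeneSet(f"null_{i}", rng.choice(ids, size=config.random_set_size,
                                        replace=False))
        for i in range(config.n_random_sets)
    ]


def empirical_p(observed_mean: float, null_means) -> tuple[float, float]:
    """Strict and conservative empirical p-values.

    Strict: proportion of null means strictly greater than the observed mean
    (ties count as "not higher").  Conservative: (k+1)/(R+1), which cannot
    be exactly zero.
    """
    null_means = np.asarray(null_means, dtype=float)
    if null_means.size == 0:
        raise ValueError("null_means is empty")
    k = int(np.sum(null_means > observed_mean))
    r = null_means.size
    return k / r, (k + 1) / (r + 1)


def null_curve(null_means) -> list[tuple[float, float]]:
    """Empirical CDF of null means as sorted (mean, cumulative %) pairs."""
    sorted_means = np.sort(np.asarray(null_means, dtype=float))
    r = sorted_means.size
    pct = 100.0 * np.arange(1, r + 1) / r
    return list(zip(sorted_means.tolist(), pct.tolist()))


def run_mc_test(table: pd.DataFrame, observed_set: GeneSet,
                motif_names: list[str], config: MCConfig
                ) -> list[MonteCarloResult]:
    """Run the Monte Carlo enrichment test for one observed gene set.

    A single family of null sets (one sampling pass) is shared across all
    motifs.  Null-set means are computed on the same count table as the
    observed mean.
    """
    missing = sorted(config.universe.gene_ids - set(table.index))
    if missing:
        raise KeyError(f"universe genes absent from count table: "
                       f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    for m in motif_names:
        if m not in table.columns:
            raise KeyError(f"motif {m!r} not in count table")
    rng = np.random.default_rng(config.seed)
    universe_ids = np.array(sorted(config.universe.gene_ids))
    pos = {g: i for i, g in enumerate(table.index)}
    universe_pos = np.array([pos[g] for g in universe_ids])
    # (R, set_size) matrix of row positions into the count table
    idx = np.stack([
        universe_pos[rng.choice(len(universe_ids),
                                size=config.random_set_size, replace=False)]
        for _ in range(config.n_random_sets)
    ])
    counts = table[motif_names].to_numpy(dtype=float)
    results: list[MonteCarloResult] = []
    for j, motif in enumerate(motif_names):
        null_means = counts[:, j][idx].mean(axis=1)
        observed = mean_count(table, observed_set, motif)
        p_strict, p_cons = empirical_p(observed, null_means)
        results.append(MonteCarloResult(
            motif_name=motif, set_name=observed_set.name,
            observed_mean=observed, null_means=null_means,
            empirical_p=p_strict, empirical_p_conservative=p_cons,
            curve=null_curve(null_means),
            n_random_sets=config.n_random_sets,
            random_set_size=config.random_set_size, seed=config.seed))
    return results


def overlap_counts(query_up: GeneSet, query_down: GeneSet,
                   reference: GeneSet) -> OverlapReport:
    """Exact intersection sizes of up/down query sets with a reference list.

    Warns if the up and down sets are not disjoint.
    """
    common = query_up.gene_ids & query_down.gene_ids
    if common:
        warnings.warn(
            f"query sets {query_up.name!r} and {query_down.name!r} share "
            f"{len(common)} genes", stacklevel=2)
    return OverlapReport(
        query_up_name=query_up.name,
        query_down_name=query_down.name,
        reference_name=reference.name,
        n_reference=len(reference),
        n_up_overlap=len(query_up.gene_ids & reference.gene_ids),
        n_down_overlap=len(query_down.gene_ids & reference.gene_ids),
    )


def write_mc_results(results: list[MonteCarloResult],
                     path: str | Path) -> None:
    """Tab-separated result table, one row per (motif, set)."""
    with open(path, "w") as fh:
        fh.write("motif\tset\tobserved_mean\tp_strict\tp_conservative\t"
                 "R\tset_size\tseed\n")
        for r in results:
            fh.write(f"{r.motif_name}\t{r.set_name}\t{r.observed_mean:.6f}\t"
                     f"{r.empirical_p:.6g}\t"
                     f"{r.empirical_p_conservative:.6g}\t"
                     f"{r.n_random_sets}\t{r.random_set_size}\t{r.seed}\n")


def write_curves(results: list[MonteCarloResult], path: str | Path) -> None:
    """Tab-separated null cumulative curves (motif, mean, cumulative %)."""
    with open(path, "w") as fh:
        fh.write("motif\tmean_count\tcumulative_pct\n")
        for r in results:
            for mean, pct in r.curve:
                fh.write(f"{r.motif_name}\t{mean:.6f}\t{pct:.4f}\n")


def plot_null_curves(results: list[MonteCarloResult], path: str | Path
                     ) -> None:
    """Cumulative-percentage-vs-mean-count plot with observed means marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for r in results:
        xs, ys = zip(*r.curve)
        line, = ax.plot(xs, ys, label=r.motif_name)
        ax.plot([r.observed_mean], [50.0], marker="s", linestyle="none",
                color=line.get_color())
    ax.axhline(95.0, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("mean motif occurrences per promoter")
    ax.set_ylabel("cumulative % of random gene sets")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
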