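# Methods

## Promoter definition and coordinates

GFF3 input is 1-based inclusive; all internal arithmetic is 0-based
half-open, converted once at the parser boundary. The transcription start
site is the 5′ end of the annotated *gene* feature — `start` for +, `end`
for −. Annotations rarely say which transcript isoform defined a promoter;
anchoring on the gene feature avoids an isoform choice and keeps the
definition configurable (the feature type is a reader parameter). A
promoter is the window `[TSS − u, TSS + d)` in genomic coordinates for a
plus-strand gene (defaults u = d = 100 bp) and its mirror image for a
minus-strand gene, whose sequence is reverse-complemented so that every
promoter reads 5′→3′ relative to its gene.

Windows that would cross a contig edge are **dropped** by default rather
than clipped, so that all promoters share one length and mean counts per
promoter remain comparable across sets; `edge_policy="clip"` keeps them,
flagged, for callers who prefer completeness. Dropped genes are reported
(gene id + reason).

The gene length filter keeps genes **strictly** longer than the cutoff
(default 500 bp), reading "longer than" literally.

## Motif matching

Consensus motifs use the full IUPAC alphabet; matching is exact per
position, overlapping occurrences are all counted (occurrence counting,
not parsing), and `N` in the *sequence* never matches. With both strands
scanned, an occurrence whose window is its own reverse complement matches
identically on both strands and is counted **once** (strand +). Without
this rule the self-complementary ACGT core would be double-counted at
every site.

PWM scanning scores windows by log-odds against the background model, in
bits. A pseudocount (default 0.01) is added to matrix probabilities before
log-odds so no score is infinite. The match threshold is derived from a
p-value cutoff (default 1e−4, the common default of FIMO-style scanners):
scores are discretized to a fixed bin width (default 0.01 bits), the exact
distribution of the total score of a random background L-mer is computed
by dynamic programming (iterated convolution of the per-position discrete
score distributions — never by sampling), and the threshold is the
smallest achievable score whose tail probability does not exceed the
cutoff. Window scores at scan time use the same quantized matrix, so the
scanner and the threshold are exactly consistent; tests verify the DP tail
against exhaustive enumeration over all 4^L words. The same
palindrome-dedup rule applies to PWM hits, which makes an indicator PWM
reproduce consensus counts exactly.

Motif definitions are external configuration (`name<TAB>IUPAC` text or
MEME minimal format). The shipped examples are labelled illustrative: the
UPRE-element matrices used in the enrichment literature are cited to
external references and are not reproduced here.

## The Monte Carlo enrichment test

Test statistic: mean motif occurrences per promoter over a gene set. Null:
R random gene sets (default 2000) of fixed size (default 750) drawn
uniformly without replacement from the universe of genes passing the
length filter; a single sampling pass is shared across all motifs, giving
one family of null curves per run. The strict empirical p-value counts
null means **strictly greater** than the observed mean (ties are "not
higher"); because it can be exactly 0, the conservative (k+1)/(R+1)
estimator is always reported alongside. Per-motif p-values carry no
multiple-testing correction — the test is a descriptive enrichment screen.

Two deliberate asymmetries are documented rather than "fixed":

* Observed sets may have sizes different from the null-set size (e.g. 761
  or 734 observed vs 750 random). The statistic is a per-promoter mean, so
  its expectation is size-invariant; only its variance depends on set
  size, making the comparison slightly conservative for larger observed
  sets and slightly anticonservative for smaller ones at these scales.
* The sampling universe defaults to *all* genes passing the length filter.
  Whether the background should instead be, say, only neuronally expressed
  genes is a scientific choice; the universe is a config field.

With R random sets the p-value granularity is 1/R (0.0005 at R = 2000);
any smaller printed p-value can only be the strict estimator's exact zero.

Reproducibility: one top-level seed feeds `numpy.random.default_rng`; the
genome generator and the null sampler use separate streams (documented
offsets), and identical inputs + seed give bit-identical results,
asserted in tests.

## Behavioral statistics

**Food-leaving probability** = mean over minutes of
(leavers in minute m) / (worms at start of minute m), over a 15-min window.
Minutes that start with zero worms are excluded from the mean: the ratio
is undefined there, and exclusion keeps assays where all worms leave early
well-defined (a hazard-1 assay scores exactly 1). Leaving is modelled as
absorbing within the window; an optional returns column restores worms for
generality. The log validates conservation
(worms(m+1) = worms(m) − leavers(m) + returns(m)).

**Off-food exploration.** The plate is a grid of 0.25 cm² squares anchored
at the food patch. Square scores follow concentric Chebyshev shells: score
1 inside the 3×3 core around the patch, score k for the shell of the
(2k+1)×(2k+1) square, capped at 5 beyond the outermost ring. This is the
only self-consistent reading of "nearest … next … outside the previous
area": true annuli around a 3×3 core have sizes 9, 16, 24, 32, 40, whereas
the conventionally quoted sizes 9, 25, 49, 81, 121 are the *full* nested
squares 3², 5², 7², 9², 11². Both bookkeepings are available
(`geometry="shell"` vs `"literal"`); the square→score assignment (smallest
containing square) is identical in both, only the reported ring membership
counts differ. The per-worm aggregate of square scores is selectable
(sum — default, max, mean) and echoed in output, since published plots do
not state the aggregation. The patch's own square is excluded from
scoring; partial edge squares count as whole squares.

**On-food exploration** = 100 × occupied squares / total plate squares.

## Synthetic data

The generator is the package's ground-truth instrument, not a genome
simulator: genes of fixed length (default 1000 bp, comfortably above the
500 bp filter) lie head-to-tail on one contig on alternating strands —
which forces the reverse-complement extraction path to be exercised — with
intergenic spacers (default 200 bp) at least `upstream + downstream` wide
so promoter windows can never collide. Sequence is i.i.d. from a
configurable base composition (default uniform). Each promoter receives a
Poisson number of planted motif instances (target-set rate vs background
rate; defaults 2.0 vs 0.5 per promoter, a strong-but-plausible contrast
for power studies), placed non-overlappingly by constructive gap sampling
(instances in random order, free space distributed by sorted uniform
draws), so placement always succeeds when the instances fit and the
planted count equals the countable occurrences. Consensus ambiguity codes
are realized uniformly; PWM plants use the per-position argmax word.

What the generator does *not* emulate: real base composition and isochore
structure, operons, overlapping genes, transcript isoforms, chromatin
context, or correlated motif co-occurrence. Passing tests therefore
demonstrate the correctness and calibration of the *statistics* under
their stated model, not biological conclusions about any real genome.

The behavioral generators likewise implement exactly the estimators'
assumed models — constant per-minute hazard with absorbing leaving; a lazy
8-neighbor random walk (default stay probability 1/9, boundary moves
clamped) for exploration tracks — so estimator consistency and
monotonicity can be checked against known parameters.

## Numerical and scale choices

* PWM score bin width 0.01 bits: tail probabilities are exact for the
  quantized scores; quantization error only moves scores by < bin/2.
* Simulation scale for calibration/power studies: 2000-gene universes,
  200-gene target sets, 500 null sets per study, 100 studies — chosen to
  give binomially tight checks (the 99% interval around a 5% false-positive
  rate is roughly [1%, 11%] at 100 studies) while one study runs in a
  fraction of a second.
* The acceptance script's single showcase study uses the default
  published-scale null sampling (2000 sets of 750) on a 2000-gene synthetic
  universe.
* Degenerate inputs are errors, not silent results: empty gene sets,
  oversized null sets, zero-worm logs, zero-square plates, zero background
  probabilities with positive matrix mass.

## Known limitations

* The TSS is the annotated gene 5′ end; isoform-resolved promoters are out
  of scope.
* No GC- or length-matched null sampling beyond the single length filter,
  and no FDR across motifs — matching the descriptive design of the test.
* Consensus matching treats the motif as hard; graded affinity requires
  the PWM route.
* The literal grid geometry reproduces the quoted ring sizes only as
  cumulative nested-square memberships; a genuinely annular reading of
  those sizes does not exist geometrically.
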