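# Methods

## Cluster identification

Family members are genomic intervals on scaffolds; all coordinates are
normalized to 0-based half-open at parse time (BED verbatim, GFF3 shifted
by one). The physical distance between two genes on one scaffold is the
**intergenic gap** — `max(0, max(start_i, start_j) − min(end_i, end_j))` —
so overlapping or nested genes are at distance 0. Genes on different
scaffolds have no defined physical distance and are never chained.

Clustering is single-linkage chaining: per scaffold, genes sorted by
`(start, end, gene_id)` are joined whenever the gap between *consecutive*
genes is ≤ *g*. Maximal chains with *n* ≥ 2 members become clusters,
numbered left to right; single genes are singletons. Because each of the
*n* − 1 consecutive gaps is ≤ *g*, the sum of gaps inside a cluster is
bounded by *C*<sub>L</sub> = *g*(*n* − 1), with equality exactly when every
gap sits at *g*. The gap definition (rather than start-to-start or
midpoint distance) makes the threshold interpretable as "DNA between
copies"; it is recorded in the run metadata of every output.

*Choice of g.* Thresholds are family- and genome-specific. The default is
*g* = 100 kb, a conventional scale in arthropod chemoreceptor cluster
studies; alternatively the user supplies a null probability *p* and *g* is
derived (below). The two parameters are mutually exclusive on the command
line and the derived one is always materialized in the output metadata.

## The Poisson null

The null hypothesis is that the *N* family members are placed uniformly at
random on the genome of *G* bp, i.e. positions form a homogeneous Poisson
process with rate λ = *N*/*G*. Adjacent inter-member gaps are then
exponential(λ), and the probability that a given adjacent pair lies within
*g* is

    p = 1 − exp(−λ g),        g = −ln(1 − p) / λ.

This is an approximation to the exact finite-*N* spacing distribution
(1 − (1 − g/G)^N); for any realistic *N* ≪ *G*/*g* the two differ by less
than 10⁻⁶, and the package ships a uniform-placement Monte-Carlo oracle
(`adjacent_gap_fraction`) that ties the closed form to simulation — the
acceptance suite requires agreement within 3 Monte-Carlo standard errors
on a 3×3 grid of (*N*, *g*) with 10⁵ placements per cell. When
λ·*g* > 50 the CDF saturates numerically and *p* is reported as 1 with a
warning. p-values are reported raw, one family at a time; no
multiple-testing correction is applied.

## Evolutionary distances and C_ST

Evolutionary distances are **patristic**: the sum of branch lengths along
the unique leaf-to-leaf path of a phylogeny whose branch lengths are in
amino-acid replacements per site. They are independent of root placement,
which the tests verify by rerooting random trees. The tree is either
supplied as Newick (any rooting, multifurcations allowed, branch lengths
mandatory) or inferred by external programs (MAFFT alignment, then
FastTree, or IQ-TREE with its fast search under JTT) driven as
subprocesses; the package never reimplements alignment or tree inference,
and every downstream statistic works from a user-supplied tree alone.

For a scope (one scaffold, or the whole genome):

* *D*<sub>T</sub> — mean patristic distance over **all** unordered pairs of
  in-scope genes. For the genome scope this includes cross-scaffold pairs:
  evolutionary distance is defined for every pair even when physical
  distance is not.
* *D*<sub>C</sub> — mean over pairs whose two genes share one cluster,
  **pooled across clusters**. Pooling weights clusters by their pair count;
  the alternative (average of per-cluster means) weights clusters equally.
  Pooling was chosen because the within-cluster pair sample is also what
  the rank test consumes; the convention is stated in the output metadata.
* *C*<sub>ST</sub> = (*D*<sub>T</sub> − *D*<sub>C</sub>)/*D*<sub>T</sub>,
  reported as missing (with a reason code) when *D*<sub>T</sub> = 0, when
  the scope has no within-cluster pair, or fewer than two genes.

The Mann–Whitney U test compares the within-cluster pair sample against
**all remaining pairs** — singleton–singleton, singleton–clustered and
cross-cluster alike (the most inclusive reading; also recorded in
metadata). The test is two-sided by default with a one-sided option. The
implementation delegates to scipy, which uses the exact distribution for
small tie-free samples and the tie-corrected normal approximation
otherwise; the test suite pins it against an independent enumeration
oracle over all C(n+m, n) rank assignments.

**Calibration caveat.** Pairwise distances are not independent — pairs
sharing a gene are correlated — so the rank test on them is only
approximately calibrated. Within-pairs drawn from clusters of size ≥ 3
share leaves with each other and push the test anticonservative, while
size-2 clusters (leaf-disjoint within-pairs) pull it conservative. This is
a property of applying a two-sample rank test to a distance matrix, not of
this implementation. Users should read borderline p-values with this in
mind.

## Joint two-family analysis

Each family is clustered independently with its own *g* (the per-family
results are bit-identical to single-family runs); the joint step only
intersects cluster spans on shared scaffolds, reporting `overlap_bp` and
the number of genes of one family falling strictly inside the other
family's cluster span. No merged cross-family clusters are formed and no
co-clustering enrichment statistic is computed — the mode is exploratory.

## Synthetic data generator

The generator produces the two inputs with unambiguous ground truth.

*Physical layout* (`simulate_family`): elements (clusters of given sizes,
then singletons) are distributed round-robin over scaffolds and laid out
left to right. Within-cluster gaps are uniform on [1 kb, *g*<sub>truth</sub>];
gaps between elements are uniform on (2 *g*<sub>truth</sub>,
4 *g*<sub>truth</sub>]; gene lengths uniform on [1, 5] kb. By construction,
chaining at *g*<sub>truth</sub> recovers the generating partition exactly,
which the tests assert. Defaults: 50 Mb genome, 2 scaffolds, cluster sizes
(2, 2, 2, 3), 12 singletons, *g*<sub>truth</sub> = 100 kb — a medium-sized
family of 21 members. Infeasible placements (layout exceeding scaffold
length) raise before any file is written.

*Trees* (`simulate_tree`): each cluster's members hang as pendants of
length *s·b*/2 from a per-cluster hub at depth (1 − *s*)·*b*/2 below the
root; singletons hang from the root at depth *b*/2. Expected within-cluster
patristic distance is therefore *s·b* and every other expected pairwise
distance is *b* (*b* = 1.0 replacements/site by default — a strongly
diverged family; *s* ∈ (0, 1] is the within-cluster shrink, default 0.2).
Every branch is multiplied by independent mean-one lognormal jitter
(σ = 0.35). At *s* = 1 the cluster hubs collapse into the root and the
physical partition carries no evolutionary signal — the null for the
detection experiments.

The default cluster-size mix (2, 2, 2, 3) was chosen so that the
within-cluster pair sample is dominated by leaf-disjoint pairs: under this
design the rank test's null rejection rate at α = 0.05 is ≈ 0.047
(conservative size-2 and anticonservative size-3 contributions roughly
cancel) and its null p-values pass a Kolmogorov–Smirnov uniformity check.
With many large clusters the test would be anticonservative (see the
calibration caveat above) — a deliberate limitation to document, not to
hide.

*What the generator does not emulate:* realistic sequence evolution (no
substitution model; the FASTA proteins are random placeholders for wiring
tests of the external-tool stage), non-uniform gene density (repeats,
centromeres), variable gene lengths beyond a narrow uniform band, or
annotation noise. Passing tests demonstrate correctness of the statistics
under the stated model, not robustness to assembly or annotation artefacts.

## Numerical and engineering conventions

* Sorting ties (identical starts) break by (end, gene_id); all outputs are
  byte-deterministic for a fixed seed, including figures (image metadata
  carries no timestamps).
* `1 − exp(−x)` is computed as `−expm1(−x)` and its inverse with `log1p`
  to keep precision at small *p*.
* Strand is parsed and reported but never used in distances or chaining.
* A GFF3 gene split over multiple rows with one ID is collapsed to its
  minimal covering interval, with a warning.
* Distance matrices are written as TSV with a `gene_id` header row/column;
  cross-scaffold physical entries are `NA`, never a number.
* The HTML report embeds all figures base64 and opens without network
  access; a missing artefact produces an inline warning block and a
  non-zero exit.
* Measurement sizes in the shipped checks (500 oracle instances, 10⁵
  placements per calibration cell, 200 power and 1000 null replicates)
  were sized so each Monte-Carlo standard error is small against the
  property being checked while the whole suite stays fast.

## Known limitations

* The Poisson null assumes uniform gene density genome-wide; clustering
  p-values on genomes with strong density heterogeneity are optimistic.
* The rank test's calibration degrades as clusters grow (dependence among
  within-pairs); C_ST itself is a descriptive ratio and unaffected.
* No cross-scaffold cluster joining, no GTF input, no bootstrap support on
  externally inferred trees.
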