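# famcluster

Identification, statistical characterization and visualization of physically
clustered gene-family members in chromosome-level genome assemblies.

Gene families — homologous genes born by duplication, often lying in tandem
arrays — are a major component of eukaryotic genomes, and whether family
members sit physically together on a chromosome carries information about
how they arose (unequal crossing-over, segmental duplication) and how they
evolve (concerted evolution, gene conversion, independent divergence).
`famcluster` takes the coordinates of one or two gene families (BED or
GFF3) plus the genome size, decides which members form clusters and which
are singletons, quantifies how surprising the clustering is under a uniform
null, and — when a phylogeny of the members is available — relates physical
proximity to evolutionary divergence. It is aimed at researchers studying
medium-to-large gene families (chemoreceptors, detoxification enzymes,
immune genes, …) in chromosome-level assemblies.

## Model and statistics

**Cluster detection.** Genes on one scaffold, sorted by position, are
chained whenever the intergenic gap between consecutive genes is at most a
threshold *g*; a maximal chain of *n* ≥ 2 genes is a cluster. The genomic
span of such a cluster can never exceed

&nbsp;&nbsp;&nbsp;&nbsp;*C<sub>L</sub>* = *g*(*n* − 1).

**Null model for *g*.** Under uniform random placement of the *N* family
members on a genome of *G* bp, positions form a Poisson process with rate
λ = *N*/*G* and adjacent gaps are exponential; the probability that a given
adjacent pair falls within *g* is *p* = 1 − e<sup>−λg</sup>. The tool
converts in both directions (*g* → *p*, *p* → *g*), so the user can fix
either the physical scale or the false-positive probability.

**Physical vs evolutionary distance.** Evolutionary distances are patristic
distances (sums of branch lengths, in amino-acid replacements per site) on
a phylogeny of the family — supplied as Newick, or built from the member
proteins via MAFFT + FastTree/IQ-TREE subprocesses. With *D<sub>T</sub>*
the mean pairwise distance over all members in scope and *D<sub>C</sub>*
the mean over pairs sharing a cluster,

&nbsp;&nbsp;&nbsp;&nbsp;*C<sub>ST</sub>* = (*D<sub>T</sub>* − *D<sub>C</sub>*) / *D<sub>T</sub>*

measures the proportion of the family's genetic distance attributable to
unclustered genes: ≈ 0 when clustering carries no evolutionary signal, → 1
when clustered copies are near-identical. A Mann–Whitney U test compares
within-cluster against all remaining pairwise distances. Both are computed
per scaffold and genome-wide.

## Worked example

The package ships a seeded generator so a full run needs no external data:

```bash
famcluster simulate --seed 7 --outdir demo/fixture
famcluster evolve demo/fixture/simfam.bed --tree demo/fixture/simfam.nwk \
    --genome-size-mb 50 --family-label simfam --outdir demo/out
```

`demo/out/clusters.tsv` (excerpt):

```
cluster_id       scaffold  n  first_start  last_end  span_bp  gap_span_bp  max_len_CL
simfam_scf1_c1   scf1      2  194490       260345    65855    58251        100000
simfam_scf2_c2   scf2      3  353019       505359    152340   143774       200000
```

Four clusters are found at the default *g* = 100 kb; every cluster's sum of
consecutive gaps (`gap_span_bp`) respects its *C<sub>L</sub>* bound
(`max_len_CL`). `demo/out/cst.tsv`:

```
scope   n_genes  n_clusters  D_T     D_C     C_ST    U    p
scf1    10       2           0.909   0.200   0.780   0.0  2.0e-03
scf2    11       2           0.868   0.165   0.810   0.0  5.9e-06
genome  21       4           0.909   0.177   0.806   0.0  1.8e-11
```

This fixture was generated with within-cluster divergence shrunk to 20% of
the family-wide level, and the analysis recovers exactly that signal:
clustered pairs are far more similar than the family at large
(*C<sub>ST</sub>* ≈ 0.8), and the rank test rejects the null at every
scope. `demo/out/report.html` bundles these tables with the cluster-size
spectrum, per-scaffold triangular heatmaps (physical distances in the lower
triangle, evolutionary in the upper, clusters boxed on the diagonal) and
the physical-vs-evolutionary scatter as one self-contained file.

Two families can be analysed jointly (`famcluster joint a.bed b.bed …`),
each with its own *g*; clusters are then compared spatially and overlapping
cluster pairs reported.

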