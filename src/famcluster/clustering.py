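"""Physical clustering of gene-family members.

A family of N members annotated on a genome of size G is screened for
physical clusters by single-linkage chaining: genes on one scaffold, sorted
by position, are joined whenever the intergenic gap between consecutive
genes is at most a threshold ``g``. A maximal chain of n >= 2 genes is a
cluster, whose genomic span can never exceed the cutoff

    C_L = g * (n - 1).

The significance of a chosen ``g`` is assessed under a null in which the N
members are placed uniformly at random, i.e. positions form a homogeneous
Poisson process with rate lambda = N / G; adjacent gaps are then exponential
and the probability that a given adjacent pair falls within ``g`` is

    p = 1 - exp(-lambda * g).

Physical distance between two genes is the intergenic gap (end-to-start),
clamped at zero for overlapping genes; genes on different scaffolds have no
defined physical distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coords import FamilyTable, GeneRecord, GenomeInfo
from .errors import InputError

#: default chaining threshold (bp) when neither g nor p is supplied;
#: a conventional scale for arthropod chemoreceptor cluster studies.
DEFAULT_G_BP = 100_000

#: regime where the exponential CDF saturates numerically
_LAMBDA_G_SATURATION = 50.0


def gap_bp(a: GeneRecord, b: GeneRecord) -> int:
    """Intergenic gap between two genes on one scaffold (0 if they overlap)."""
    if a.scaffold != b.scaffold:
        raise ValueError("gap undefined across scaffolds")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


# ---------------------------------------------------------------------------
# null model

def gap_pvalue(g: int, family_size: int, genome: GenomeInfo) -> float:
    """Null probability that an adjacent pair of members lies within ``g`` bp.

    Under uniform placement of ``family_size`` members on a genome of
    ``genome.size_bp`` bases, adjacent gaps are approximately exponential
    with rate lambda = N / G, so p = 1 - exp(-lambda * g).
    """
    if family_size < 2:
        raise InputError(f"family size must be >= 2, got {family_size}")
    if g < 0:
        raise InputError(f"g must be non-negative, got {g}")
    if g >= genome.size_bp:
        raise InputError(
            f"g = {g} bp must be smaller than the genome ({genome.size_bp} bp)"
        )
    lam_g = family_size / genome.size_bp * g
    if lam_g > _LAMBDA_G_SATURATION:
        warnings.warn(
            f"lambda*g = {lam_g:.1f} saturates the null model; p reported as 1",
            stacklevel=2,
        )
        return 1.0
    return -math.expm1(-lam_g)


def g_from_pvalue(p: float, family_size: int, genome: GenomeInfo) -> int:
    """Gap threshold (bp) whose null probability equals ``p`` (inverse of gap_pvalue)."""
    if not 0.0 < p < 1.0:
        raise InputError(f"p must be in (0, 1), got {p}")
    if family_size < 2:
        raise InputError(f"family size must be >= 2, got {family_size}")
    lam = family_size / genome.size_bp
    return round(-math.log1p(-p) / lam)


@dataclass
class ClusterParams:
    """Chaining threshold with its null p-value; one is derived from the other."""

    g: int
    p_value: float
    genome: GenomeInfo
    family_size: int

    @classmethod
    def from_g(cls, g: int, family_size: int, genome: GenomeInfo) -> "ClusterParams":
        if g <= 0:
            raise InputError(f"g must be positive, got {g}")
        return cls(g, gap_pvalue(g, family_size, genome), genome, family_size)

    @classmethod
    def from_pvalue(cls, p: float, family_size: int, genome: GenomeInfo) -> "ClusterParams":
        g = g_from_pvalue(p, family_size, genome)
        if g <= 0:
            raise InputError(f"p = {p} implies a non-positive threshold g = {g} bp")
        return cls(g, p, genome, family_size)


# ---------------------------------------------------------------------------
# clusters

def cluster_length_cutoff(g: int, n: int) -> int:
    """Maximum genomic span C_L = g(n-1) permitted for an n-member cluster."""
    if n < 2:
        raise InputError(f"a cluster needs >= 2 copies, got n = {n}")
    if g <= 0:
        raise InputError(f"g must be positive, got {g}")
    return g * (n - 1)


@dataclass
class Cluster:
    cluster_id: str
    scaffold: str
    members: list[str]  # gene_ids ordered by start
    first_start: int
    last_end: int
    gap_span_bp: int  # sum of consecutive intergenic gaps

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def span_bp(self) -> int:
        """Genomic extent from first member start to last member end."""
        return self.last_end - self.first_start


@dataclass
class ClusterSet:
    """Partition of a family's genes into clusters and singletons."""

    family: str
    params: ClusterParams
    clusters: list[Cluster] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)

    @property
    def n_clustered_genes(self) -> int:
        return sum(c.n for c in self.clusters)

    @property
    def n_genes(self) -> int:
        return self.n_clustered_genes + len(self.singletons)

    def membership(self) -> dict[str, str | None]:
        """gene_id -> cluster_id (None for singletons)."""
        out: dict[str, str | None] = {gid: None for gid in self.singletons}
        for cl in self.clusters:
            for gid in cl.members:
                out[gid] = cl.cluster_id
        return out

    def clusters_on(self, scaffold: str) -> list[Cluster]:
        return [c for c in self.clusters if c.scaffold == scaffold]


def find_clusters(table: FamilyTable, params: ClusterParams) -> ClusterSet:
    """Chain genes into clusters per scaffold under the gap threshold.

    Genes sorted by start are joined whenever the intergenic gap between
    consecutive genes is <= g; maximal chains of n >= 2 become clusters
    (numbered left to right per scaffold), chains of one gene are singletons.
    """
    g = params.g
    clusters: list[Cluster] = []
    singletons: list[str] = []
    for scaffold, genes in table.by_scaffold().items():
        chains: list[list[GeneRecord]] = []
        current = [genes[0]]
        for prev, cur in zip(genes, genes[1:]):
            if gap_bp(prev, cur) <= g:
                current.append(cur)
            else:
                chains.append(current)
                current = [cur]
        chains.append(current)
        k = 0
        for chain in chains:
            if len(chain) == 1:
                singletons.append(chain[0].gene_id)
                continue
            k += 1
            gaps = sum(gap_bp(a, b) for a, b in zip(chain, chain[1:]))
            clusters.append(
                Cluster(
                    cluster_id=f"{table.family}_{scaffold}_c{k}",
                    scaffold=scaffold,
                    members=[r.gene_id for r in chain],
                    first_start=chain[0].start,
                    last_end=max(r.end for r in chain),
                    gap_span_bp=gaps,
                )
            )
    return ClusterSet(table.family, params, clusters, singletons)


# ---------------------------------------------------------------------------
# physical distance matrix

@dataclass
class PhysDistMatrix:
    """Symmetric pairwise intergenic distances in bp.

    Cross-scaffold entries are undefined: ``values`` holds NaN there and
    ``same_scaffold`` is False.
    """

    gene_ids: list[str]
    values: np.ndarray  # float, NaN where undefined
    same_scaffold: np.ndarray  # bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def pairwise_physical_distances(table: FamilyTable) -> PhysDistMatrix:
    """All pairwise intergenic gaps within scaffolds, in genomic order."""
    if not table.records:
        raise InputError("empty family table")
    recs = table.records
    n = len(recs)
    starts = np.array([r.start for r in recs], dtype=float)
    ends = np.array([r.end for r in recs], dtype=float)
    scaffs = np.array([r.scaffold for r in recs])
    same = scaffs[:, None] == scaffs[None, :]
    gaps = np.maximum(
        0.0, np.maximum(starts[:, None], starts[None, :])
        - np.minimum(ends[:, None], ends[None, :])
    )
    np.fill_diagonal(gaps, 0.0)
    gaps[~same] = np.nan
    return PhysDistMatrix([r.gene_id for r in recs], gaps, same)


# ---------------------------------------------------------------------------
# summaries

def cluster_size_spectrum(cs: ClusterSet, table: FamilyTable) -> pd.DataFrame:
    """Cluster-size frequency spectrum per scaffold and genome-wide.

    Singletons appear as the size-1 class; the gene table supplies their
    scaffolds. Columns: scope, size, count; pooled rows carry scope
    ``genome``. Counts weighted by size sum to the family size.
    """
    singleton_ids = set(cs.singletons)
    rows: dict[tuple[str, int], int] = {}
    for cl in cs.clusters:
        rows[(cl.scaffold, cl.n)] = rows.get((cl.scaffold, cl.n), 0) + 1
    for rec in table.records:
        if rec.gene_id in singleton_ids:
            rows[(rec.scaffold, 1)] = rows.get((rec.scaffold, 1), 0) + 1
    pooled: dict[int, int] = {}
    for (_, size), c in rows.items():
        pooled[size] = pooled.get(size, 0) + c
    out = [(s, size, c) for (s, size), c in sorted(rows.items())]
    out += [("genome", size, c) for size, c in sorted(pooled.items())]
    return pd.DataFrame(out, columns=["scope", "size", "count"])


def write_cluster_table(cs: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tscaffold\tn\tfirst_start\tlast_end\tspan_bp\t"
            "gap_span_bp\tmax_len_CL\tmember_ids\n"
        )
        for cl in cs.clusters:
            fh.write(
                f"{cl.cluster_id}\t{cl.scaffold}\t{cl.n}\t{cl.first_start}\t"
                f"{cl.last_end}\t{cl.span_bp}\t{cl.gap_span_bp}\t"
                f"{cluster_length_cutoff(cs.params.g, cl.n)}\t"
                f"{','.join(cl.members)}\n"
            )


def write_spectrum(spectrum: pd.DataFrame, path: str | Path) -> None:
    spectrum.to_csv(path, sep="\t", index=False)
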