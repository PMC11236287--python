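"""Evolutionary distances and the cluster differentiation statistic C_ST.

Pairwise evolutionary distances between family members are patristic
distances — sums of branch lengths along the tree path between two leaves —
measured in amino-acid replacements per site. Given a physical clustering,
the statistic

    C_ST = (D_T - D_C) / D_T

compares D_T, the mean pairwise distance over all family copies in scope,
with D_C, the mean pairwise distance over pairs sharing a cluster (pooled
across clusters). C_ST near 1 indicates clustered copies are much more
similar to each other than the family at large (recent tandem expansion or
concerted evolution); C_ST near 0 indicates no physical-evolutionary
association. A Mann-Whitney U test compares within-cluster pairwise
distances against all remaining pairs. Both are computed per scaffold and
genome-wide.

The tree may be supplied directly as Newick, or built from the member
proteins with external programs (MAFFT alignment, then FastTree or IQ-TREE);
those programs are orchestrated as subprocesses, never reimplemented, and
the whole evolutionary stage is optional.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterSet
from .coords import FamilyTable
from .errors import ConsistencyError, ExternalToolError, InputError, ParseError

GENOME_SCOPE = "genome"


# ---------------------------------------------------------------------------
# trees

def parse_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree (string or file path) with branch lengths.

    Quoted labels, scientific-notation lengths and multifurcations are
    accepted. Duplicate leaf labels or missing branch lengths are errors.
    """
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if "(" not in text:  # no Newick structure: treat as a file path
            if not Path(text).is_file():
                raise ParseError(f"no such tree file: {text}")
            text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ParseError(f"duplicate leaf labels: {dupes}")
    if len(labels) == 0:
        raise ParseError("tree has no leaves")
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is tree.seed_node:
            continue  # root edge may legitimately lack a length
        if edge.length is None:
            label = head.taxon.label if head.taxon else "<internal>"
            raise ParseError(f"missing branch length on edge above {label!r}")
        if edge.length < 0:
            raise ParseError(f"negative branch length {edge.length}")
    return tree


@dataclass
class EvolDistMatrix:
    """Symmetric patristic distance matrix in replacements per site."""

    gene_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    def reorder(self, gene_ids: Sequence[str]) -> "EvolDistMatrix":
        """Return the matrix restricted/permuted to ``gene_ids``."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ConsistencyError(f"genes absent from the distance matrix: {missing}")
        order = [idx[g] for g in gene_ids]
        return EvolDistMatrix(list(gene_ids), self.values[np.ix_(order, order)])


def patristic_matrix(tree: dendropy.Tree) -> EvolDistMatrix:
    """Pairwise path-length distances between all leaves of ``tree``.

    Independent of root placement: rerooting changes no leaf-to-leaf path.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise InputError("patristic distances need at least two leaves")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in leaves)
    taxa = {t.label: t for t in pdm.taxon_iter()}
    n = len(labels)
    values = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            values[i, j] = values[j, i] = d
    return EvolDistMatrix(labels, values)


# ---------------------------------------------------------------------------
# statistics

def mann_whitney_u(
    within: Sequence[float],
    between: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Rank-sum test of within-cluster vs remaining pairwise distances.

    Returns ``(U, p)`` where U counts (within, between) pairs with
    within > between. The exact null distribution is used for small
    tie-free samples, the tie-corrected normal approximation otherwise
    (scipy's automatic policy).
    """
    if len(within) == 0 or len(between) == 0:
        raise InputError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        within, between, alternative=alternative, method="auto"
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class CstResult:
    """C_ST and its rank test for one scope (a scaffold, or the whole genome)."""

    scope: str
    n_genes: int
    n_clusters: int
    d_t: float | None
    d_c: float | None
    c_st: float | None
    mwu_u: float | None
    mwu_p: float | None
    n_within: int
    n_other: int
    missing_reason: str | None = None


def _pair_samples(
    matrix: EvolDistMatrix, membership: dict[str, str | None], gene_ids: list[str]
) -> tuple[list[float], list[float]]:
    m = matrix.reorder(gene_ids)
    within: list[float] = []
    other: list[float] = []
    for i, gi in enumerate(gene_ids):
        ci = membership.get(gi)
        for j in range(i + 1, len(gene_ids)):
            cj = membership.get(gene_ids[j])
            d = m.values[i, j]
            if ci is not None and ci == cj:
                within.append(d)
            else:
                other.append(d)
    return within, other


def compute_cst(
    matrix: EvolDistMatrix,
    clusters: ClusterSet,
    table: FamilyTable,
    alternative: str = "two-sided",
) -> list[CstResult]:
    """C_ST per scaffold and genome-wide.

    D_T averages over all unordered pairs of in-scope genes (for the genome
    scope this includes cross-scaffold pairs — evolutionary distance is
    defined for every pair). D_C pools all within-cluster pairs across the
    scope's clusters. Scopes where D_T = 0 or with no within-cluster pair
    yield a missing C_ST with a reason code.
    """
    membership = clusters.membership()
    have = set(matrix.gene_ids)
    absent = [g for g in table.gene_ids if g not in have]
    if absent:
        raise ConsistencyError(
            f"genes missing from the evolutionary distance matrix: {absent}"
        )
    results: list[CstResult] = []
    scopes: list[tuple[str, list[str]]] = [
        (sc, [r.gene_id for r in recs]) for sc, recs in table.by_scaffold().items()
    ]
    scopes.append((GENOME_SCOPE, table.gene_ids))
    for scope, gene_ids in scopes:
        n_clusters = (
            len(clusters.clusters)
            if scope == GENOME_SCOPE
            else len(clusters.clusters_on(scope))
        )
        if len(gene_ids) < 2:
            results.append(
                CstResult(scope, len(gene_ids), n_clusters, None, None, None,
                          None, None, 0, 0, "fewer_than_two_genes")
            )
            continue
        within, other = _pair_samples(matrix, membership, gene_ids)
        all_pairs = within + other
        d_t = float(np.mean(all_pairs))
        if not within:
            results.append(
                CstResult(scope, len(gene_ids), n_clusters, d_t, None, None,
                          None, None, 0, len(other), "no_within_cluster_pairs")
            )
            continue
        d_c = float(np.mean(within))
        if d_t == 0.0:
            results.append(
                CstResult(scope, len(gene_ids), n_clusters, d_t, d_c, None,
                          None, None, len(within), len(other),
                          "zero_total_distance")
            )
            continue
        c_st = (d_t - d_c) / d_t
        if other:
            u, p = mann_whitney_u(within, other, alternative=alternative)
        else:
            u = p = None
        results.append(
            CstResult(scope, len(gene_ids), n_clusters, d_t, d_c, c_st,
                      u, p, len(within), len(other),
                      None if other else "no_between_pairs")
        )
    return results


def cst_table(results: list[CstResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "scope": r.scope, "n_genes": r.n_genes, "n_clusters": r.n_clusters,
            "D_T": r.d_t, "D_C": r.d_c, "C_ST": r.c_st,
            "U": r.mwu_u, "p": r.mwu_p,
            "n_within_pairs": r.n_within, "n_other_pairs": r.n_other,
            "missing_reason": r.missing_reason or "",
        })
    return pd.DataFrame(rows)


def write_cst_table(results: list[CstResult], path: str | Path) -> None:
    cst_table(results).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# external phylogeny orchestration

def run_external_phylogeny(
    proteins: str | Path,
    engine: str = "mafft+fasttree",
    workdir: str | Path = ".",
    expected_ids: Sequence[str] | None = None,
    extra_args: Sequence[str] = (),
) -> dendropy.Tree:
    """Align proteins and infer a tree with external programs.

    ``engine`` is ``mafft+fasttree`` or ``mafft+iqtree`` (IQ-TREE runs with
    its fast search). Never required: a user-supplied Newick tree bypasses
    this entirely.
    """
    proteins = Path(proteins)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if engine not in ("mafft+fasttree", "mafft+iqtree"):
        raise InputError(f"unknown engine {engine!r}")
    if expected_ids is not None:
        fasta_ids = _fasta_ids(proteins)
        missing = sorted(set(fasta_ids) - set(expected_ids))
        extra = sorted(set(expected_ids) - set(fasta_ids))
        if missing or extra:
            raise ConsistencyError(
                f"FASTA ids not in coordinates: {missing}; "
                f"coordinate ids not in FASTA: {extra}"
            )
    aln = workdir / "alignment.fasta"
    _run_tool(["mafft", "--auto", str(proteins)], stdout=aln, log=workdir / "mafft.log")
    treefile = workdir / "tree.nwk"
    if engine == "mafft+fasttree":
        _run_tool(
            ["fasttree", *extra_args, str(aln)],
            stdout=treefile, log=workdir / "fasttree.log",
        )
    else:
        _run_tool(
            ["iqtree", "-s", str(aln), "-fast", "-m", "JTT",
             "--prefix", str(workdir / "iqtree"), *extra_args],
            stdout=None, log=workdir / "iqtree.log",
        )
        produced = workdir / "iqtree.treefile"
        if not produced.exists():
            raise ExternalToolError("iqtree produced no tree file")
        shutil.copy(produced, treefile)
    return parse_newick(treefile)


def _run_tool(cmd: list[str], stdout: Path | None, log: Path) -> None:
    exe = shutil.which(cmd[0])
    if exe is None:
        raise ExternalToolError(
            f"{cmd[0]} not found on PATH; supply a Newick tree instead"
        )
    with open(log, "w") as lg:
        if stdout is not None:
            with open(stdout, "w") as out:
                proc = subprocess.run(cmd, stdout=out, stderr=lg)
        else:
            proc = subprocess.run(cmd, stdout=lg, stderr=subprocess.STDOUT)
    if proc.returncode != 0:
        raise ExternalToolError(
            f"{cmd[0]} exited with status {proc.returncode}; see {log}"
        )


def _fasta_ids(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                ids.append(line[1:].split()[0].strip())
    return ids
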