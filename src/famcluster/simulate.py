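"""Seeded synthetic genomes, gene families and trees with known ground truth.

The generator builds the two kinds of data every statistic in this package
consumes, with unambiguous ground truth:

* **Physical layout** — clusters are placed with within-cluster intergenic
  gaps drawn at or below a generating threshold ``g_truth``, while distinct
  elements (clusters and singletons) are separated by more than ``2 *
  g_truth``; chaining at ``g_truth`` therefore recovers the generating
  partition exactly. Null layouts place all members uniformly, matching the
  Poisson/exponential gap model.

* **Trees** — each physical cluster becomes a shallow subtree hanging from
  its own hub node, so the expected patristic distance between two members
  of one cluster is ``s * b`` while any other pair has expected distance
  ``b`` (``b`` = base distance in replacements per site, ``s`` = the
  within-cluster shrink in (0, 1]; ``s = 1`` is the null where physical
  clustering carries no evolutionary signal). Branch lengths are jittered
  by mean-one lognormal noise.

Everything is driven by one ``numpy`` generator seeded from ``SimParams``;
the same seed reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import Cluster, ClusterParams, ClusterSet
from .coords import FamilyTable, GeneRecord, GenomeInfo, write_bed, write_gff3
from .errors import InputError

#: default generating gap threshold (bp), matching the clustering default
DEFAULT_G_TRUTH = 100_000


@dataclass
class SimParams:
    """Parameters of one synthetic family.

    Defaults describe a medium-sized family (a handful of small tandem
    arrays plus singletons) on a compact multi-scaffold genome: cluster
    sizes (2, 2, 2, 3) and 12 singletons keep the within-cluster pair
    sample dominated by leaf-disjoint pairs, for which the rank test on
    patristic distances is well calibrated under the null.
    """

    seed: int = 0
    genome_mb: float = 50.0
    n_scaffolds: int = 2
    cluster_sizes: tuple[int, ...] = (2, 2, 2, 3)
    n_singletons: int = 12
    g_truth: int = DEFAULT_G_TRUTH
    min_within_gap_bp: int = 1_000
    gene_len_bp: tuple[int, int] = (1_000, 5_000)
    evol_base_distance: float = 1.0
    within_shrink_s: float = 0.2
    branch_jitter_sigma: float = 0.35
    family: str = "simfam"

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.cluster_sizes):
            raise InputError("cluster sizes must all be >= 2")
        if not 0.0 < self.within_shrink_s <= 1.0:
            raise InputError("within_shrink_s must be in (0, 1]")
        if self.min_within_gap_bp > self.g_truth:
            raise InputError("min_within_gap_bp must not exceed g_truth")

    @property
    def n_genes(self) -> int:
        return sum(self.cluster_sizes) + self.n_singletons

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_family(params: SimParams) -> tuple[FamilyTable, ClusterSet]:
    """Place a clustered family on the genome; return the table and the truth.

    Elements (clusters, then singletons) are distributed round-robin over
    scaffolds and laid out left to right; within-cluster gaps are drawn
    uniformly in ``[min_within_gap_bp, g_truth]`` and inter-element gaps in
    ``(2 g_truth, 4 g_truth]``, so single-linkage chaining at ``g_truth``
    reproduces the generating partition.
    """
    rng = params.rng()
    genome_bp = round(params.genome_mb * 1e6)
    scaffold_len = genome_bp // params.n_scaffolds
    elements: list[int] = list(params.cluster_sizes) + [1] * params.n_singletons
    per_scaffold: dict[str, list[int]] = {
        f"scf{i + 1}": [] for i in range(params.n_scaffolds)
    }
    names = list(per_scaffold)
    for i, size in enumerate(elements):
        per_scaffold[names[i % len(names)]].append(size)

    records: list[GeneRecord] = []
    truth_clusters: list[Cluster] = []
    singleton_ids: list[str] = []
    gene_no = 0
    lo_len, hi_len = params.gene_len_bp
    for scaffold, sizes in per_scaffold.items():
        cursor = int(rng.integers(params.g_truth, 2 * params.g_truth))
        k = 0
        for size in sizes:
            members: list[GeneRecord] = []
            for m in range(size):
                if m > 0:
                    cursor += int(
                        rng.integers(params.min_within_gap_bp, params.g_truth + 1)
                    )
                gene_no += 1
                length = int(rng.integers(lo_len, hi_len + 1))
                rec = GeneRecord(
                    scaffold, cursor, cursor + length,
                    f"{params.family}_g{gene_no:03d}",
                    "+" if rng.random() < 0.5 else "-",
                    params.family,
                )
                members.append(rec)
                cursor = rec.end
            records.extend(members)
            if size >= 2:
                k += 1
                gaps = sum(
                    b.start - a.end for a, b in zip(members, members[1:])
                )
                truth_clusters.append(
                    Cluster(
                        cluster_id=f"{params.family}_{scaffold}_c{k}",
                        scaffold=scaffold,
                        members=[r.gene_id for r in members],
                        first_start=members[0].start,
                        last_end=members[-1].end,
                        gap_span_bp=gaps,
                    )
                )
            else:
                singleton_ids.append(members[0].gene_id)
            cursor += int(rng.integers(2 * params.g_truth + 1, 4 * params.g_truth + 1))
        if cursor > scaffold_len:
            raise InputError(
                f"infeasible placement: scaffold {scaffold} needs {cursor} bp "
                f"but only {scaffold_len} bp are available; increase genome_mb"
            )
    table = FamilyTable(params.family, records)
    genome = GenomeInfo(params.genome_mb, table.scaffolds)
    cp = ClusterParams.from_g(params.g_truth, max(2, len(table)), genome)
    truth = ClusterSet(params.family, cp, truth_clusters, singleton_ids)
    return table, truth


def simulate_tree(truth: ClusterSet, params: SimParams) -> str:
    """Newick tree over the family's genes encoding the cluster shrink.

    Cluster members hang from a per-cluster hub at depth ``(1-s) b/2`` with
    pendant length ``s b/2``; singletons hang from the root at depth
    ``b/2``. All branch lengths are multiplied by independent mean-one
    lognormal jitter, so expected within-cluster patristic distance is
    ``s b`` and any other expected pairwise distance is ``b``.
    """
    if truth.n_genes == 0:
        raise InputError("empty cluster set")
    rng = np.random.default_rng(params.seed + 1_000_003)
    b = params.evol_base_distance
    s = params.within_shrink_s
    sig = params.branch_jitter_sigma

    def jitter() -> float:
        # mean-one lognormal: E[exp(N(-sig^2/2, sig^2))] = 1
        return float(rng.lognormal(-0.5 * sig * sig, sig))

    parts: list[str] = []
    for cl in truth.clusters:
        leaves = ",".join(
            f"{gid}:{(s * b / 2) * jitter():.10g}" for gid in cl.members
        )
        hub_depth = ((1.0 - s) * b / 2) * jitter()
        parts.append(f"({leaves}):{hub_depth:.10g}")
    for gid in truth.singletons:
        parts.append(f"{gid}:{(b / 2) * jitter():.10g}")
    if len(parts) == 1:
        # a single cluster holding every gene: use its hub as the root
        return f"{parts[0].rsplit(':', 1)[0]};"
    return f"({','.join(parts)});"


def uniform_positions(
    n: int, size_bp: int, rng: np.random.Generator
) -> np.ndarray:
    """Sorted positions of ``n`` members placed uniformly on the genome."""
    return np.sort(rng.integers(0, size_bp, size=n))


def adjacent_gap_fraction(
    n: int, size_bp: int, g: int, n_reps: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo oracle for the Poisson-gap null.

    Places ``n`` members uniformly ``n_reps`` times and returns the mean
    per-replicate fraction of adjacent gaps <= ``g`` together with its
    Monte-Carlo standard error (over replicates, which respects the
    within-replicate dependence of gaps).
    """
    pos = rng.integers(0, size_bp, size=(n_reps, n))
    pos.sort(axis=1)
    gaps = np.diff(pos, axis=1)
    frac = (gaps <= g).mean(axis=1)
    return float(frac.mean()), float(frac.std(ddof=1) / np.sqrt(n_reps))


@dataclass
class FixtureFiles:
    bed: Path
    gff3: Path
    proteins: Path
    tree: Path
    truth: Path


def write_fixture_dir(params: SimParams, outdir: str | Path) -> FixtureFiles:
    """Emit a complete fixture: BED + GFF3 coordinates, dummy proteins,
    Newick tree, and the truth partition as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = simulate_family(params)
    files = FixtureFiles(
        bed=outdir / f"{params.family}.bed",
        gff3=outdir / f"{params.family}.gff3",
        proteins=outdir / f"{params.family}.faa",
        tree=outdir / f"{params.family}.nwk",
        truth=outdir / f"{params.family}.truth.tsv",
    )
    write_bed(table, files.bed)
    write_gff3(table, files.gff3)
    _write_dummy_proteins(table, params, files.proteins)
    files.tree.write_text(simulate_tree(truth, params) + "\n")
    member = truth.membership()
    with open(files.truth, "w") as fh:
        fh.write(f"# seed={params.seed} g_truth={params.g_truth}\n")
        fh.write("gene_id\tcluster_id\n")
        for rec in table.records:
            fh.write(f"{rec.gene_id}\t{member.get(rec.gene_id) or ''}\n")
    return files


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _write_dummy_proteins(
    table: FamilyTable, params: SimParams, path: Path
) -> None:
    # random sequences: placeholders for wiring tests of the external
    # phylogeny stage, not products of any substitution model
    rng = np.random.default_rng(params.seed + 2_000_003)
    with open(path, "w") as fh:
        for rec in table.records:
            seq = "".join(rng.choice(_AA, size=120))
            fh.write(f">{rec.gene_id}\n{seq}\n")
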