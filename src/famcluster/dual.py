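"""Joint analysis of two gene families.

Each family is clustered independently (with its own gap threshold); the
joint step only compares the resulting cluster intervals spatially,
reporting same-scaffold cluster pairs whose genomic spans intersect and the
number of genes of one family interleaved inside the other family's
cluster span. No cross-family chaining and no co-clustering statistic is
performed — the joint mode is exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .clustering import ClusterParams, ClusterSet, find_clusters
from .coords import FamilyTable
from .errors import ConsistencyError


@dataclass
class ClusterOverlap:
    cluster_id_a: str
    cluster_id_b: str
    scaffold: str
    overlap_bp: int
    interleaved_a_in_b: int  # family-A genes strictly inside cluster B's span
    interleaved_b_in_a: int


@dataclass
class JointFamilyResult:
    family_a: ClusterSet
    family_b: ClusterSet
    overlaps: list[ClusterOverlap]

    def overlap_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id_a": o.cluster_id_a,
                "cluster_id_b": o.cluster_id_b,
                "scaffold": o.scaffold,
                "overlap_bp": o.overlap_bp,
                "interleaved_a_in_b": o.interleaved_a_in_b,
                "interleaved_b_in_a": o.interleaved_b_in_a,
            }
            for o in self.overlaps
        ]
        return pd.DataFrame(
            rows,
            columns=["cluster_id_a", "cluster_id_b", "scaffold", "overlap_bp",
                     "interleaved_a_in_b", "interleaved_b_in_a"],
        )


def joint_analysis(
    table_a: FamilyTable,
    table_b: FamilyTable,
    params_a: ClusterParams,
    params_b: ClusterParams,
) -> JointFamilyResult:
    """Cluster two families independently and record spatial cluster overlaps.

    Gene identifiers must be disjoint between the families (prefix them with
    the family label upstream if they collide). The per-family cluster sets
    are identical to what single-family runs would produce.
    """
    shared = sorted(set(table_a.gene_ids) & set(table_b.gene_ids))
    if shared:
        raise ConsistencyError(
            f"gene_ids shared between families {table_a.family!r} and "
            f"{table_b.family!r}: {shared}"
        )
    cs_a = find_clusters(table_a, params_a)
    cs_b = find_clusters(table_b, params_b)
    overlaps: list[ClusterOverlap] = []
    genes_a = table_a.by_scaffold()
    genes_b = table_b.by_scaffold()
    for ca in cs_a.clusters:
        for cb in cs_b.clusters_on(ca.scaffold):
            lo = max(ca.first_start, cb.first_start)
            hi = min(ca.last_end, cb.last_end)
            if hi - lo <= 0:
                continue
            a_in_b = sum(
                1 for r in genes_a.get(ca.scaffold, [])
                if cb.first_start < r.start and r.end < cb.last_end
            )
            b_in_a = sum(
                1 for r in genes_b.get(ca.scaffold, [])
                if ca.first_start < r.start and r.end < ca.last_end
            )
            overlaps.append(
                ClusterOverlap(ca.cluster_id, cb.cluster_id, ca.scaffold,
                               hi - lo, a_in_b, b_in_a)
            )
    return JointFamilyResult(cs_a, cs_b, overlaps)


def write_overlap_table(result: JointFamilyResult, path: str | Path) -> None:
    result.overlap_table().to_csv(path, sep="\t", index=False)


def write_combined_gene_table(
    table_a: FamilyTable, table_b: FamilyTable, result: JointFamilyResult,
    path: str | Path,
) -> None:
    """Combined per-gene table for both families, with a family column."""
    rows = []
    for table, cs in ((table_a, result.family_a), (table_b, result.family_b)):
        member = cs.membership()
        sizes = {c.cluster_id: c.n for c in cs.clusters}
        for rec in table.records:
            cid = member.get(rec.gene_id)
            rows.append({
                "family": table.family, "gene_id": rec.gene_id,
                "scaffold": rec.scaffold, "start": rec.start, "end": rec.end,
                "strand": rec.strand,
                "status": "clustered" if cid else "singleton",
                "cluster_id": cid or "",
                "cluster_size": sizes.get(cid, 1),
            })
    df = pd.DataFrame(rows).sort_values(
        ["scaffold", "start", "end", "gene_id"], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False)
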