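"""Gene-family coordinate input/output.

Reads gene-family member coordinates from BED or GFF3 files into a single
normalized representation and writes the tabular summaries. All internal
coordinates are 0-based half-open ``[start, end)``; conversions from the
1-based inclusive GFF3 convention happen once, at parse time.

Strand is recorded for reporting but never used by clustering or distance
computations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gffutils.feature

from .errors import ConsistencyError, ParseError

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One gene-family member as a genomic interval.

    Coordinates are 0-based half-open; ``strand`` is ``+``, ``-`` or ``.``
    (unknown). ``gene_id`` must be unique within its family.
    """

    scaffold: str
    start: int
    end: int
    gene_id: str
    strand: str = "."
    family: str = "family"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeInfo:
    """Total genome size, the only genome-level input the method needs.

    ``size_mb`` is user-supplied (megabases); ``size_bp`` is derived.
    Scaffold names are collected from the coordinate input as a convenience.
    """

    size_mb: float
    scaffold_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.size_mb <= 0:
            raise ValueError(f"genome size must be positive, got {self.size_mb} Mb")

    @property
    def size_bp(self) -> int:
        return round(self.size_mb * 1_000_000)

    def check_against(self, table: "FamilyTable") -> None:
        """Warn when a gene extends past the declared genome size."""
        if not table.records:
            return
        max_end = max(r.end for r in table.records)
        if self.size_bp < max_end:
            warnings.warn(
                f"genome size {self.size_bp} bp is smaller than the largest "
                f"gene end coordinate {max_end} bp",
                stacklevel=2,
            )


def _canonical_sort_key(rec: GeneRecord) -> tuple:
    # ties on identical starts broken by (end, gene_id) for determinism
    return (rec.scaffold, rec.start, rec.end, rec.gene_id)


@dataclass
class FamilyTable:
    """All members of one gene family, in canonical genomic order."""

    family: str
    records: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=_canonical_sort_key)
        seen: dict[str, GeneRecord] = {}
        for rec in self.records:
            if rec.gene_id in seen:
                raise ParseError(
                    f"duplicate gene_id {rec.gene_id!r} in family {self.family!r}"
                )
            seen[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @property
    def scaffolds(self) -> list[str]:
        """Scaffold names in order of first appearance along the sort."""
        out: list[str] = []
        for rec in self.records:
            if rec.scaffold not in out:
                out.append(rec.scaffold)
        return out

    def by_scaffold(self) -> dict[str, list[GeneRecord]]:
        groups: dict[str, list[GeneRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.scaffold, []).append(rec)
        return groups

    def subset(self, scaffold: str) -> "FamilyTable":
        return FamilyTable(
            self.family, [r for r in self.records if r.scaffold == scaffold]
        )


# ---------------------------------------------------------------------------
# BED

def parse_bed(path: str | Path, family_label: str = "family") -> FamilyTable:
    """Parse a BED3/BED4/BED6 file of gene loci.

    Coordinates are taken verbatim (BED is already 0-based half-open).
    Column 4 supplies ``gene_id`` when present; otherwise an identifier
    ``<scaffold>:<start>-<end>`` is synthesized. Column 6 supplies strand.
    Lines starting with ``#`` (and BED ``track``/``browser`` lines) are
    skipped.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields_ = line.split("\t")
            if len(fields_) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(fields_)}"
                )
            scaffold = fields_[0]
            try:
                start, end = int(fields_[1]), int(fields_[2])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"{fields_[1]!r}, {fields_[2]!r}"
                ) from None
            if start >= end or start < 0:
                raise ParseError(
                    f"{path.name}:{lineno}: invalid interval [{start}, {end})"
                )
            gene_id = (
                fields_[3] if len(fields_) >= 4 and fields_[3] not in ("", ".")
                else f"{scaffold}:{start}-{end}"
            )
            strand = fields_[5] if len(fields_) >= 6 and fields_[5] in ("+", "-") else "."
            records.append(
                GeneRecord(scaffold, start, end, gene_id, strand, family_label)
            )
    _check_duplicates(records, path)
    return FamilyTable(family_label, records)


def write_bed(table: FamilyTable, path: str | Path) -> None:
    """Write a family as BED6 (score column is 0). Round-trips with parse_bed."""
    with open(path, "w") as fh:
        for rec in table.records:
            fh.write(
                f"{rec.scaffold}\t{rec.start}\t{rec.end}\t{rec.gene_id}\t0\t{rec.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFF3

def parse_gff3(
    path: str | Path,
    family_label: str = "family",
    feature_type: str = "gene",
    id_attribute: str = "ID",
) -> FamilyTable:
    """Parse a GFF3 file, keeping rows whose feature type matches.

    GFF3 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention (``[start-1, end)``). When several rows carry the
    same identifier (discontinuous annotation) the minimal covering interval
    is used, with a warning.
    """
    path = Path(path)
    kept: dict[str, GeneRecord] = {}
    multi: set[str] = set()
    types_seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            ncols = len(line.split("\t"))
            if ncols != 9:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, got {ncols}"
                )
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            types_seen.add(feat.featuretype)
            if feat.featuretype != feature_type:
                continue
            if id_attribute not in feat.attributes:
                raise ParseError(
                    f"{path.name}:{lineno}: feature lacks the {id_attribute!r} attribute"
                )
            gene_id = feat.attributes[id_attribute][0]
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path.name}:{lineno}: invalid interval {feat.start}..{feat.end}"
                )
            strand = feat.strand if feat.strand in ("+", "-") else "."
            if gene_id in kept:
                prev = kept[gene_id]
                if prev.scaffold != feat.seqid:
                    raise ParseError(
                        f"{path.name}:{lineno}: gene {gene_id!r} appears on both "
                        f"{prev.scaffold!r} and {feat.seqid!r}"
                    )
                multi.add(gene_id)
                kept[gene_id] = replace(
                    prev, start=min(prev.start, start), end=max(prev.end, end)
                )
            else:
                kept[gene_id] = GeneRecord(
                    feat.seqid, start, end, gene_id, strand, family_label
                )
    if not kept:
        raise ParseError(
            f"{path.name}: no rows of feature type {feature_type!r}; "
            f"types seen: {sorted(types_seen)}"
        )
    if multi:
        warnings.warn(
            f"{len(multi)} gene(s) had multiple rows; using minimal covering "
            f"intervals: {sorted(multi)}",
            stacklevel=2,
        )
    return FamilyTable(family_label, list(kept.values()))


def write_gff3(table: FamilyTable, path: str | Path, feature_type: str = "gene") -> None:
    """Write a family as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in table.records:
            strand = rec.strand if rec.strand in ("+", "-") else "."
            fh.write(
                f"{rec.scaffold}\tfamcluster\t{feature_type}\t{rec.start + 1}\t"
                f"{rec.end}\t.\t{strand}\t.\tID={rec.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# tabular output

def write_gene_table(table: FamilyTable, clusters, path: str | Path) -> None:
    """Write the per-gene summary: clustered/singleton status and cluster id.

    ``clusters`` is a :class:`~famcluster.clustering.ClusterSet` covering
    exactly the genes of ``table``.
    """
    membership: dict[str, tuple[str, int]] = {}
    for cl in clusters.clusters:
        for gid in cl.members:
            membership[gid] = (cl.cluster_id, cl.n)
    singles = set(clusters.singletons)
    covered = set(membership) | singles
    missing = [r.gene_id for r in table.records if r.gene_id not in covered]
    if missing:
        raise ConsistencyError(
            f"genes absent from the cluster partition: {missing}"
        )
    with open(path, "w") as fh:
        fh.write("gene_id\tscaffold\tstart\tend\tstrand\tstatus\tcluster_id\tcluster_size\n")
        for rec in table.records:
            if rec.gene_id in membership:
                cid, n = membership[rec.gene_id]
                status, size = "clustered", str(n)
            else:
                cid, status, size = "", "singleton", "1"
            fh.write(
                f"{rec.gene_id}\t{rec.scaffold}\t{rec.start}\t{rec.end}\t"
                f"{rec.strand}\t{status}\t{cid}\t{size}\n"
            )


def _check_duplicates(records: Iterable[GeneRecord], path: Path) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ParseError(f"{path.name}: duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
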