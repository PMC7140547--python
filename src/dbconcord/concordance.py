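"""Rank harmonization and N-database overlap partitions.

Catalogues annotate references at heterogeneous depths (species, strain,
unranked isolates), so they are first harmonized: each record's taxID is
resolved through the merged map and projected to a common rank (species
or genus) by climbing the lineage.  Strain-level comparison is not
attempted — strain ids are collapsed into their species, and records
whose lineage lacks a node at the requested rank are excluded with an
explicit reason, as are deleted and unknown ids.

The harmonized taxon sets are then partitioned: every taxon in the union
of the N catalogues belongs to exactly one cell, keyed by the exact
subset of catalogues that contain it (the Venn/UpSet partition, at most
2^N - 1 non-empty cells).  From the partition follow the exactly-k
aggregates (taxa in precisely k catalogues), per-catalogue coverage of
the union, and the all-N consensus set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .manifest_io import DatabaseManifest
from .taxonomy import Taxonomy

__all__ = [
    "EXCLUSION_REASONS",
    "Exclusion",
    "RankProjection",
    "OverlapPartition",
    "CoveragePercent",
    "project_to_rank",
    "venn_partition",
    "exactly_k_counts",
    "coverage_percent",
    "consensus_set",
    "write_partition_tsv",
    "write_exactly_k_json",
    "write_coverage_json",
    "write_exclusions_tsv",
]

EXCLUSION_REASONS = ("unknown_taxid", "deleted_taxid", "no_ancestor_at_rank")


@dataclass(frozen=True)
class Exclusion:
    """A record left out of a projection, with the reason why."""

    accession: str
    input_taxid: int
    reason: str


@dataclass
class RankProjection:
    """A database's harmonized taxon set at one rank plus its exclusions."""

    database: str
    rank: str
    taxon_set: set[int]
    exclusions: list[Exclusion] = field(default_factory=list)


@dataclass
class OverlapPartition:
    """Assignment of every taxon in the union to its exact catalogue subset.

    ``cells`` maps a canonically ordered non-empty tuple of database labels
    to the set of taxids found in exactly those databases.  Cells are
    pairwise disjoint and cover the union.
    """

    databases: list[str]
    cells: dict[tuple[str, ...], set[int]]
    union_size: int

    def __post_init__(self) -> None:
        order = {d: i for i, d in enumerate(self.databases)}
        seen: set[int] = set()
        total = 0
        for key, members in self.cells.items():
            if not key:
                raise ValueError("partition cell with empty database subset")
            if list(key) != sorted(key, key=order.__getitem__):
                raise ValueError(f"cell key {key} not in canonical database order")
            if seen & members:
                raise ValueError("partition cells are not pairwise disjoint")
            seen |= members
            total += len(members)
        if total != self.union_size:
            raise ValueError(
                f"cell sizes sum to {total}, union_size says {self.union_size}"
            )


@dataclass(frozen=True)
class CoveragePercent:
    """Coverage of the union by one catalogue: exact value and integer print form."""

    value: float
    rounded: int


def project_to_rank(
    manifest: DatabaseManifest, tax: Taxonomy, rank: str
) -> RankProjection:
    """Harmonize a manifest to a set of canonical taxids at ``rank``.

    Each record's taxid is resolved (merged ids redirected); deleted and
    unknown ids become exclusions, as do records whose lineage has no node
    at the requested rank.  Duplicates collapse under set semantics, so a
    species and its strains contribute a single member.
    """
    taxon_set: set[int] = set()
    exclusions: list[Exclusion] = []
    for rec in manifest.records:
        res = tax.resolve(rec.taxid)
        if res.status == "deleted":
            exclusions.append(Exclusion(rec.accession, rec.taxid, "deleted_taxid"))
            continue
        if res.status == "unknown":
            exclusions.append(Exclusion(rec.accession, rec.taxid, "unknown_taxid"))
            continue
        anc = tax.ancestor_at_rank(res.canonical_taxid, rank)
        if anc is None:
            exclusions.append(
                Exclusion(rec.accession, rec.taxid, "no_ancestor_at_rank")
            )
        else:
            taxon_set.add(anc)
    return RankProjection(manifest.name, rank, taxon_set, exclusions)


def venn_partition(named_sets: Mapping[str, set[int]]) -> OverlapPartition:
    """Partition the union of named taxon sets into exact-subset cells.

    Each element of the union is assigned to the unique cell keyed by the
    exact subset of input sets containing it.  Input order of the mapping
    fixes the canonical database order, so output is deterministic.
    """
    if len(named_sets) < 2:
        raise ValueError(f"need at least 2 named sets, got {len(named_sets)}")
    databases = list(named_sets)
    if len(set(databases)) != len(databases):
        raise ValueError("database labels must be unique")

    membership: dict[int, list[str]] = {}
    for label in databases:  # canonical order ⇒ keys come out ordered
        for taxid in named_sets[label]:
            membership.setdefault(taxid, []).append(label)

    cells: dict[tuple[str, ...], set[int]] = {}
    for taxid, labels in membership.items():
        cells.setdefault(tuple(labels), set()).add(taxid)
    return OverlapPartition(databases, cells, union_size=len(membership))


def exactly_k_counts(p: OverlapPartition) -> dict[int, int]:
    """Number of taxa present in precisely k catalogues, for k = 1..N."""
    counts = {k: 0 for k in range(1, len(p.databases) + 1)}
    for key, members in p.cells.items():
        counts[len(key)] += len(members)
    return counts


def coverage_percent(p: OverlapPartition) -> dict[str, CoveragePercent]:
    """Per-catalogue coverage of the union, in percent.

    coverage(d) = 100 * |taxa in d| / union_size, computed from the cells
    whose key contains d.  Both the exact value and the nearest-integer
    percent (as the field prints it) are returned.
    """
    if p.union_size == 0:
        raise ValueError("coverage undefined for an empty union")
    out: dict[str, CoveragePercent] = {}
    for d in p.databases:
        in_d = sum(len(m) for key, m in p.cells.items() if d in key)
        value = 100.0 * in_d / p.union_size
        out[d] = CoveragePercent(value, round(value))
    return out


def consensus_set(p: OverlapPartition) -> set[int]:
    """Taxa present in all N catalogues (the all-databases cell)."""
    return set(p.cells.get(tuple(p.databases), set()))


# -- report writers ------------------------------------------------------


def write_partition_tsv(
    p: OverlapPartition, path: str | Path, include_members: bool = True
) -> None:
    """One row per cell: semicolon-joined subset, count, optional members."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["subset", "count"] + (["members"] if include_members else [])
        fh.write("\t".join(cols) + "\n")
        for key in sorted(p.cells, key=lambda k: (-len(k), [p.databases.index(d) for d in k])):
            members = p.cells[key]
            row = [";".join(key), str(len(members))]
            if include_members:
                row.append(",".join(str(t) for t in sorted(members)))
            fh.write("\t".join(row) + "\n")


def write_exactly_k_json(
    p: OverlapPartition, path: str | Path, metadata: Optional[dict] = None
) -> None:
    payload = {
        "databases": p.databases,
        "union_size": p.union_size,
        "exactly_k": {str(k): v for k, v in exactly_k_counts(p).items()},
    }
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_coverage_json(
    p: OverlapPartition, path: str | Path, metadata: Optional[dict] = None
) -> None:
    cov = coverage_percent(p)
    payload = {
        "union_size": p.union_size,
        "coverage_percent": {
            d: {"value": c.value, "rounded": c.rounded} for d, c in cov.items()
        },
    }
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_exclusions_tsv(
    projections: list[RankProjection], path: str | Path
) -> None:
    """All exclusions across projections: database, accession, taxid, reason."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("database\taccession\ttaxid\treason\n")
        for proj in projections:
            for exc in proj.exclusions:
                fh.write(f"{proj.database}\t{exc.accession}\t{exc.input_taxid}\t{exc.reason}\n")
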