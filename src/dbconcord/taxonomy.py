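"""NCBI-taxdump parsing and rank-projection queries.

NCBI distributes its taxonomy as a set of pipe-delimited dump files
(``nodes.dmp``, ``names.dmp``, ``merged.dmp``, ``delnodes.dmp``).  Every
taxon carries a universal integer identifier (taxID) and a rank label
("genus", "species", "strain", "no rank", ...).  Reference-genome
catalogues annotate their entries with taxIDs, which makes the taxonomy
the common coordinate system for comparing catalogues: an entry's taxID
is first resolved through the merged/deleted maps and then projected to
a chosen rank by climbing parent pointers.

The dialect is exact: fields are separated by ``"\\t|\\t"`` and each line
is terminated by ``"\\t|"``.  Only the scientific-name rows of
``names.dmp`` are read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

__all__ = [
    "TaxonomyNode",
    "Taxonomy",
    "ResolvedTaxid",
    "TaxdumpParseError",
    "TaxonomyStructureError",
    "TaxonomyLookupError",
    "load_taxdump",
    "resolve_taxid",
    "ancestor_at_rank",
]


class TaxdumpParseError(ValueError):
    """A dump line does not follow the taxdump field dialect."""


class TaxonomyStructureError(ValueError):
    """The node graph violates a structural invariant (cycle, dangling parent)."""


class TaxonomyLookupError(KeyError):
    """A query referenced a taxid that cannot be resolved to a node."""


@dataclass(frozen=True)
class TaxonomyNode:
    """One taxon: its id, parent id, rank label and scientific name."""

    taxid: int
    parent_taxid: int
    rank: str
    name: str = ""


@dataclass(frozen=True)
class ResolvedTaxid:
    """Outcome of resolving an input taxid through merged/deleted maps.

    ``status`` is one of ``found`` (canonical == input), ``merged``
    (redirected to a live node), ``deleted`` or ``unknown`` (no canonical id).
    """

    input_taxid: int
    canonical_taxid: Optional[int]
    status: str


def _normalize_rank(rank: str) -> str:
    return rank.strip().lower()


@dataclass
class Taxonomy:
    """A taxdump snapshot: live nodes plus the merged map and deleted set."""

    nodes: dict[int, TaxonomyNode]
    merged: dict[int, int] = field(default_factory=dict)
    deleted: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        for taxid, node in self.nodes.items():
            if node.parent_taxid != taxid and node.parent_taxid not in self.nodes:
                raise TaxonomyStructureError(
                    f"node {taxid} has dangling parent {node.parent_taxid}"
                )
        self._check_acyclic()
        live = set(self.nodes)
        if live & set(self.merged):
            bad = sorted(live & set(self.merged))[0]
            raise TaxonomyStructureError(f"taxid {bad} is both live and merged")
        if live & self.deleted:
            bad = sorted(live & self.deleted)[0]
            raise TaxonomyStructureError(f"taxid {bad} is both live and deleted")
        if set(self.merged) & self.deleted:
            bad = sorted(set(self.merged) & self.deleted)[0]
            raise TaxonomyStructureError(f"taxid {bad} is both merged and deleted")
        # merged chains must terminate on a live node without looping
        for old in self.merged:
            self._merged_terminus(old)

    def _check_acyclic(self) -> None:
        # Iterative parent walk with memoised "reaches root" marks; a walk
        # longer than the node count proves a cycle.
        ok: set[int] = set()
        limit = len(self.nodes) + 1
        for start in self.nodes:
            path = []
            cur = start
            steps = 0
            while cur not in ok:
                node = self.nodes[cur]
                path.append(cur)
                if node.parent_taxid == cur:  # root self-loop
                    break
                cur = node.parent_taxid
                steps += 1
                if steps > limit:
                    raise TaxonomyStructureError(
                        f"cyclic parent chain involving taxid {start}"
                    )
            ok.update(path)

    def _merged_terminus(self, old: int) -> int:
        seen = {old}
        cur = self.merged[old]
        while cur in self.merged:
            if cur in seen:
                raise TaxonomyStructureError(f"cycle in merged map at taxid {cur}")
            seen.add(cur)
            cur = self.merged[cur]
        if cur not in self.nodes:
            raise TaxonomyStructureError(
                f"merged target {cur} (from {old}) is not a live node"
            )
        return cur

    # -- queries ---------------------------------------------------------

    def resolve(self, taxid: int) -> ResolvedTaxid:
        """Resolve ``taxid`` through the merged map (transitively).

        Never raises: the outcome is encoded in ``status``.  Idempotent —
        resolving a canonical id returns it with status ``found``.
        """
        if taxid in self.nodes:
            return ResolvedTaxid(taxid, taxid, "found")
        if taxid in self.merged:
            return ResolvedTaxid(taxid, self._merged_terminus(taxid), "merged")
        if taxid in self.deleted:
            return ResolvedTaxid(taxid, None, "deleted")
        return ResolvedTaxid(taxid, None, "unknown")

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """First node of the requested rank on the lineage (inclusive).

        Walks parent pointers from the node toward the root and returns the
        taxid of the first node whose rank equals ``rank``
        (case-insensitively, trimmed), or ``None`` if the root is reached
        without a match.  Raises :class:`TaxonomyLookupError` for ids that
        do not resolve to a live node.
        """
        res = self.resolve(taxid)
        if res.canonical_taxid is None:
            raise TaxonomyLookupError(
                f"taxid {taxid} is not resolvable (status={res.status})"
            )
        want = _normalize_rank(rank)
        cur = res.canonical_taxid
        while True:
            node = self.nodes[cur]
            if _normalize_rank(node.rank) == want:
                return cur
            if node.parent_taxid == cur:
                return None
            cur = node.parent_taxid

    def ranks(self) -> set[str]:
        """Set of normalized rank labels present in the snapshot."""
        return {_normalize_rank(n.rank) for n in self.nodes.values()}


# -- dump-file parsing ---------------------------------------------------

_FIELD_SEP = "\t|\t"
_LINE_TERM = "\t|"


def _iter_dmp_fields(path: Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, field list) for a taxdump-dialect file."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if not line.endswith(_LINE_TERM):
                raise TaxdumpParseError(
                    f"{path}: line {lineno}: missing terminator {_LINE_TERM!r}"
                )
            yield lineno, line[: -len(_LINE_TERM)].split(_FIELD_SEP)


def _parse_int(token: str, path: Path, lineno: int) -> int:
    try:
        return int(token.strip())
    except ValueError as exc:
        raise TaxdumpParseError(
            f"{path}: line {lineno}: expected integer taxid, got {token!r}"
        ) from exc


def _require_file(path: str | Path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"taxdump file not found: {p}")
    return p


def load_taxdump(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
    delnodes_path: str | Path | None = None,
) -> Taxonomy:
    """Load a taxonomy from taxdump-dialect files.

    ``nodes.dmp`` supplies taxid, parent and rank (columns 1-3);
    ``names.dmp`` supplies scientific names (rows of other name classes are
    ignored, nodes without one get an empty name).  ``merged.dmp`` and
    ``delnodes.dmp`` are optional.  Structural invariants (no dangling
    parents, no cycles, disjoint id sets) are enforced at load.
    """
    nodes_p = _require_file(nodes_path)
    names_p = _require_file(names_path)

    raw_nodes: dict[int, tuple[int, str]] = {}
    for lineno, fields in _iter_dmp_fields(nodes_p):
        if len(fields) < 3:
            raise TaxdumpParseError(
                f"{nodes_p}: line {lineno}: expected >=3 fields, got {len(fields)}"
            )
        taxid = _parse_int(fields[0], nodes_p, lineno)
        parent = _parse_int(fields[1], nodes_p, lineno)
        rank = fields[2].strip()
        if not rank:
            raise TaxdumpParseError(f"{nodes_p}: line {lineno}: empty rank")
        if taxid in raw_nodes:
            raise TaxdumpParseError(
                f"{nodes_p}: line {lineno}: duplicate taxid {taxid}"
            )
        raw_nodes[taxid] = (parent, rank)

    names: dict[int, str] = {}
    for lineno, fields in _iter_dmp_fields(names_p):
        if len(fields) < 4:
            raise TaxdumpParseError(
                f"{names_p}: line {lineno}: expected >=4 fields, got {len(fields)}"
            )
        if fields[3].strip() == "scientific name":
            names[_parse_int(fields[0], names_p, lineno)] = fields[1].strip()

    merged: dict[int, int] = {}
    if merged_path is not None:
        merged_p = _require_file(merged_path)
        for lineno, fields in _iter_dmp_fields(merged_p):
            if len(fields) < 2:
                raise TaxdumpParseError(
                    f"{merged_p}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            merged[_parse_int(fields[0], merged_p, lineno)] = _parse_int(
                fields[1], merged_p, lineno
            )

    deleted: set[int] = set()
    if delnodes_path is not None:
        delnodes_p = _require_file(delnodes_path)
        for lineno, fields in _iter_dmp_fields(delnodes_p):
            deleted.add(_parse_int(fields[0], delnodes_p, lineno))

    nodes = {
        taxid: TaxonomyNode(taxid, parent, rank, names.get(taxid, ""))
        for taxid, (parent, rank) in raw_nodes.items()
    }
    return Taxonomy(nodes=nodes, merged=merged, deleted=deleted)


# Module-level wrappers mirroring the method API.

def resolve_taxid(tax: Taxonomy, taxid: int) -> ResolvedTaxid:
    return tax.resolve(taxid)


def ancestor_at_rank(tax: Taxonomy, taxid: int, rank: str) -> Optional[int]:
    return tax.ancestor_at_rank(taxid, rank)
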