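"""Reading and writing per-database reference-catalogue manifests.

A manifest is the machine-readable description of one reference database:
one :class:`ReferenceRecord` per reference (assembly), each carrying its
taxID and either an explicit list of sequences (id, length, role) or a
declared NCBI assembly level.  Three input routes are supported:

* the canonical manifest TSV (one row per sequence),
* NCBI ``assembly_summary.txt`` catalogues (one row per assembly,
  metadata only),
* FASTA files, scanned for sequence lengths with roles inferred from
  description-line keywords.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ROLES",
    "ASSEMBLY_LEVELS",
    "DEFAULT_HEADER_RULES",
    "SequenceRecord",
    "ReferenceRecord",
    "DatabaseManifest",
    "ManifestError",
    "ManifestParseError",
    "ManifestConsistencyError",
    "read_manifest_tsv",
    "write_manifest_tsv",
    "read_assembly_summary",
    "scan_fasta_composition",
]

ROLES = ("chromosome", "contig", "scaffold")
ASSEMBLY_LEVELS = ("Complete Genome", "Chromosome", "Scaffold", "Contig")

#: Ordered keyword -> role rules applied to FASTA description lines.  The
#: fall-through default is "contig": most microbial references are
#: fragmented, so an unrecognised header is conservatively a contig.
DEFAULT_HEADER_RULES: tuple[tuple[str, str], ...] = (
    ("complete genome", "chromosome"),
    ("chromosome", "chromosome"),
    ("scaffold", "scaffold"),
)

_MANIFEST_COLUMNS = ["accession", "taxid", "seq_id", "seq_length", "seq_role"]
_IUPAC_NT = set("ACGTURYSWKMBDHVN")


class ManifestError(ValueError):
    """Base class for manifest input problems."""


class ManifestParseError(ManifestError):
    """A row or entry could not be parsed (bad token, bad level, bad role)."""


class ManifestConsistencyError(ManifestError):
    """Rows contradict each other (taxid conflict, duplicate ids)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence of a reference: id, length in bp, and structural role."""

    seq_id: str
    length: int
    role: str

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ManifestError(f"sequence {self.seq_id}: negative length")
        if self.role not in ROLES:
            raise ManifestParseError(
                f"sequence {self.seq_id}: unknown role {self.role!r} "
                f"(expected one of {ROLES})"
            )


@dataclass(frozen=True)
class ReferenceRecord:
    """One catalogue entry: accession, taxID, sequences and/or declared level."""

    accession: str
    taxid: int
    sequences: tuple[SequenceRecord, ...] = ()
    declared_level: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ManifestError("reference record with empty accession")
        if not self.sequences and self.declared_level is None:
            raise ManifestError(
                f"record {self.accession}: needs sequences or a declared level"
            )
        if self.declared_level is not None and self.declared_level not in ASSEMBLY_LEVELS:
            raise ManifestParseError(
                f"record {self.accession}: unknown assembly level "
                f"{self.declared_level!r} (expected one of {ASSEMBLY_LEVELS})"
            )
        object.__setattr__(self, "sequences", tuple(self.sequences))


@dataclass
class DatabaseManifest:
    """A named database catalogue; accessions are unique within it."""

    name: str
    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ManifestError("manifest with empty database name")
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ManifestConsistencyError(
                    f"manifest {self.name}: duplicate accession {rec.accession}"
                )
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)


# -- canonical manifest TSV ----------------------------------------------


def read_manifest_tsv(path: str | Path, name: str) -> DatabaseManifest:
    """Read the canonical manifest TSV (one row per sequence).

    Rows sharing an accession are grouped into one record in row order; the
    taxid must be identical across an accession's rows, and
    (accession, seq_id) pairs must be unique.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"manifest file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestParseError(f"{path}: missing columns {missing}")

    records: dict[str, dict] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        lineno = idx + 2  # header is line 1
        acc = row.accession
        try:
            taxid = int(row.taxid)
            length = int(row.seq_length)
        except ValueError as exc:
            raise ManifestParseError(f"{path}: line {lineno}: {exc}") from exc
        role = row.seq_role.strip()
        if role not in ROLES:
            raise ManifestParseError(
                f"{path}: line {lineno}: unknown seq_role {role!r}"
            )
        entry = records.setdefault(acc, {"taxid": taxid, "seqs": [], "ids": set()})
        if entry["taxid"] != taxid:
            raise ManifestConsistencyError(
                f"{path}: accession {acc} carries conflicting taxids "
                f"{entry['taxid']} and {taxid}"
            )
        if row.seq_id in entry["ids"]:
            raise ManifestConsistencyError(
                f"{path}: duplicate (accession, seq_id) = ({acc}, {row.seq_id})"
            )
        entry["ids"].add(row.seq_id)
        entry["seqs"].append(SequenceRecord(row.seq_id, length, role))

    return DatabaseManifest(
        name=name,
        records=[
            ReferenceRecord(acc, e["taxid"], tuple(e["seqs"]))
            for acc, e in records.items()
        ],
    )


def write_manifest_tsv(manifest: DatabaseManifest, path: str | Path) -> None:
    """Write a manifest to the canonical TSV dialect (round-trips exactly).

    Records with no sequences (metadata-only) cannot be represented in the
    per-sequence dialect and raise :class:`ManifestError`.
    """
    rows = []
    for rec in manifest.records:
        if not rec.sequences:
            raise ManifestError(
                f"record {rec.accession} has no sequences; "
                "the manifest TSV dialect is per-sequence"
            )
        for seq in rec.sequences:
            rows.append((rec.accession, rec.taxid, seq.seq_id, seq.length, seq.role))
    df = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# -- NCBI assembly_summary -----------------------------------------------


def read_assembly_summary(
    path: str | Path, name: str, taxid_column: str = "taxid"
) -> DatabaseManifest:
    """Read an NCBI ``assembly_summary.txt``-dialect catalogue.

    Lines beginning ``#`` are headers; the last one carries the column
    names.  One metadata-only record per data row, with ``declared_level``
    from ``assembly_level`` and the taxid from ``taxid_column`` (either
    ``taxid`` or ``species_taxid``).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"assembly summary not found: {path}")
    if taxid_column not in ("taxid", "species_taxid"):
        raise ValueError(f"taxid_column must be taxid or species_taxid, got {taxid_column!r}")

    header: list[str] | None = None
    records: list[ReferenceRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("# ").split("\t")
                continue
            if header is None:
                raise ManifestParseError(f"{path}: line {lineno}: data before header")
            fields = line.split("\t")
            row = dict(zip(header, fields))
            try:
                acc = row["assembly_accession"]
                taxid = int(row[taxid_column])
                level = row["assembly_level"].strip()
            except (KeyError, ValueError) as exc:
                raise ManifestParseError(f"{path}: line {lineno}: {exc}") from exc
            if level not in ASSEMBLY_LEVELS:
                raise ManifestParseError(
                    f"{path}: line {lineno}: unknown assembly_level {level!r}"
                )
            records.append(ReferenceRecord(acc, taxid, (), level))
    return DatabaseManifest(name=name, records=records)


# -- FASTA composition scan ----------------------------------------------


def scan_fasta_composition(
    path: str | Path,
    accession: str,
    taxid: int,
    header_rules: Sequence[tuple[str, str]] = DEFAULT_HEADER_RULES,
    default_role: str = "contig",
) -> ReferenceRecord:
    """Build a :class:`ReferenceRecord` by scanning a FASTA file.

    Each entry becomes one sequence; the length is the residue count and
    the role is taken from the first rule whose keyword occurs
    (case-insensitively) in the description line, falling back to
    ``default_role``.  Residues outside the IUPAC nucleotide codes are
    logged as a warning but the record is kept.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    if not header_rules:
        raise ValueError("header_rules must be non-empty")

    seqs: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        desc = entry.description.lower()
        role = default_role
        for keyword, rule_role in header_rules:
            if keyword.lower() in desc:
                role = rule_role
                break
        residues = re.sub(r"\s+", "", str(entry.seq))
        bad = set(residues.upper()) - _IUPAC_NT
        if bad:
            logger.warning(
                "%s: sequence %s contains non-IUPAC characters %s; keeping record",
                path, entry.id, "".join(sorted(bad)),
            )
        seqs.append(SequenceRecord(entry.id, len(residues), role))
    if not seqs:
        raise ManifestError(f"{path}: empty FASTA")
    return ReferenceRecord(accession, taxid, tuple(seqs))
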