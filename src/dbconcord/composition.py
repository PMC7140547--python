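"""Assembly-completeness classification and contig length statistics.

Reference genomes sit at different stages of assembly: a *complete*
reference consists only of full chromosomes, a *fragmented* one only of
contigs/scaffolds, and a *mixed* one contains both.  Per-sequence roles
decide the class when present; otherwise the declared NCBI assembly
level is mapped ("Complete Genome" -> complete, "Chromosome" -> mixed,
"Scaffold"/"Contig" -> fragmented).  Scaffolds are grouped with contigs
throughout: fragmented assemblies are treated as sets of contigs without
separating the two, and raw residue counts are used (internal N-gaps are
not subtracted).

Length statistics cover the contig/scaffold sequences of fragmented and
mixed references; chromosome sequences are excluded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np

from .concordance import RankProjection, project_to_rank
from .manifest_io import DatabaseManifest, ReferenceRecord
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "CompletenessClass",
    "ClassificationError",
    "CompositionProfile",
    "LengthStats",
    "classify_reference",
    "composition_profile",
    "contig_length_stats",
    "complete_only_projection",
    "write_profile_json",
    "write_profile_tsv",
    "write_histogram_tsv",
]


class CompletenessClass(Enum):
    COMPLETE = "complete"
    FRAGMENTED = "fragmented"
    MIXED = "mixed"


class ClassificationError(ValueError):
    """A record carries neither sequences nor a declared assembly level."""


_LEVEL_TO_CLASS = {
    "Complete Genome": CompletenessClass.COMPLETE,
    "Chromosome": CompletenessClass.MIXED,
    "Scaffold": CompletenessClass.FRAGMENTED,
    "Contig": CompletenessClass.FRAGMENTED,
}


@dataclass
class CompositionProfile:
    """Per-database complete/fragmented/mixed counts and percentages."""

    database: str
    counts: dict[CompletenessClass, int]
    percentages: dict[CompletenessClass, float]
    n_unclassifiable: int = 0

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


@dataclass
class LengthStats:
    """Summary statistics over contig/scaffold lengths (bp)."""

    n: int
    mean_bp: float
    median_bp: float
    quartiles: tuple[float, float, float]  # (Q1, Q2, Q3)
    histogram: list[tuple[float, float, int]] = field(default_factory=list)


def classify_reference(r: ReferenceRecord) -> CompletenessClass:
    """Classify one reference as complete, fragmented, or mixed.

    Per-sequence roles take precedence over the declared assembly level:
    all-chromosome -> COMPLETE, no-chromosome -> FRAGMENTED, both -> MIXED.
    """
    if r.sequences:
        has_chrom = any(s.role == "chromosome" for s in r.sequences)
        has_frag = any(s.role in ("contig", "scaffold") for s in r.sequences)
        if has_chrom and has_frag:
            return CompletenessClass.MIXED
        if has_chrom:
            return CompletenessClass.COMPLETE
        return CompletenessClass.FRAGMENTED
    if r.declared_level is not None:
        return _LEVEL_TO_CLASS[r.declared_level]
    raise ClassificationError(
        f"record {r.accession}: neither sequences nor declared level"
    )


def composition_profile(
    m: DatabaseManifest,
    tax: Optional[Taxonomy] = None,
    rank: str = "species",
) -> CompositionProfile:
    """Composition of a database: fractions of complete/fragmented/mixed.

    By default percentages are per *reference*.  Passing a taxonomy
    aggregates per taxon at ``rank`` instead: a taxon counts as COMPLETE
    if any of its references is complete, else MIXED if any is mixed,
    else FRAGMENTED.  Unclassifiable records are counted separately and
    excluded from the percentages.
    """
    if not m.records:
        raise ValueError(f"manifest {m.name} is empty")

    classes: list[tuple[ReferenceRecord, CompletenessClass]] = []
    n_unclassifiable = 0
    for rec in m.records:
        try:
            classes.append((rec, classify_reference(rec)))
        except ClassificationError:
            n_unclassifiable += 1
            logger.warning("manifest %s: record %s unclassifiable", m.name, rec.accession)

    if tax is not None:
        per_taxon: dict[int, set[CompletenessClass]] = {}
        for rec, cls in classes:
            res = tax.resolve(rec.taxid)
            if res.canonical_taxid is None:
                continue
            anc = tax.ancestor_at_rank(res.canonical_taxid, rank)
            if anc is None:
                continue
            per_taxon.setdefault(anc, set()).add(cls)
        units = []
        for cls_set in per_taxon.values():
            if CompletenessClass.COMPLETE in cls_set:
                units.append(CompletenessClass.COMPLETE)
            elif CompletenessClass.MIXED in cls_set:
                units.append(CompletenessClass.MIXED)
            else:
                units.append(CompletenessClass.FRAGMENTED)
    else:
        units = [cls for _, cls in classes]

    if not units:
        raise ValueError(f"manifest {m.name}: no classifiable records")
    counts = {c: 0 for c in CompletenessClass}
    for cls in units:
        counts[cls] += 1
    total = len(units)
    percentages = {c: 100.0 * n / total for c, n in counts.items()}
    return CompositionProfile(m.name, counts, percentages, n_unclassifiable)


def contig_length_stats(m: DatabaseManifest, bins: int = 50) -> LengthStats:
    """Length statistics over contig/scaffold sequences.

    Sequences are drawn from references classified FRAGMENTED or MIXED;
    chromosome sequences never enter.  The histogram uses ``bins``
    equal-width bins from 0 to the observed maximum.
    """
    lengths: list[int] = []
    for rec in m.records:
        try:
            cls = classify_reference(rec)
        except ClassificationError:
            continue
        if cls is CompletenessClass.COMPLETE:
            continue
        lengths.extend(s.length for s in rec.sequences if s.role in ("contig", "scaffold"))
    if not lengths:
        raise ValueError(f"manifest {m.name}: no contig/scaffold sequences")

    arr = np.asarray(lengths, dtype=float)
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    counts, edges = np.histogram(arr, bins=bins, range=(0.0, float(arr.max())))
    hist = [
        (float(edges[i]), float(edges[i + 1]), int(counts[i]))
        for i in range(len(counts))
    ]
    return LengthStats(
        n=len(lengths),
        mean_bp=float(arr.mean()),
        median_bp=float(q2),
        quartiles=(float(q1), float(q2), float(q3)),
        histogram=hist,
    )


def complete_only_projection(
    m: DatabaseManifest, tax: Taxonomy, rank: str
) -> RankProjection:
    """Rank projection restricted to references classified COMPLETE.

    Supports consensus analyses over complete genomes only; a manifest
    with no complete references yields an empty taxon set.
    """
    complete = []
    for rec in m.records:
        try:
            if classify_reference(rec) is CompletenessClass.COMPLETE:
                complete.append(rec)
        except ClassificationError:
            continue
    sub = DatabaseManifest(m.name, complete)
    return project_to_rank(sub, tax, rank)


# -- report writers ------------------------------------------------------


def write_profile_json(
    profile: CompositionProfile, path: str | Path, metadata: Optional[dict] = None
) -> None:
    payload = {
        "database": profile.database,
        "counts": {c.value: n for c, n in profile.counts.items()},
        "percentages": {c.value: p for c, p in profile.percentages.items()},
        "n_unclassifiable": profile.n_unclassifiable,
    }
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_profile_tsv(profile: CompositionProfile, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("database\tclass\tcount\tpercent\n")
        for c in CompletenessClass:
            fh.write(
                f"{profile.database}\t{c.value}\t{profile.counts[c]}\t"
                f"{profile.percentages[c]:.4f}\n"
            )


def write_histogram_tsv(stats: LengthStats, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bin_lo\tbin_hi\tcount\n")
        for lo, hi, n in stats.histogram:
            fh.write(f"{lo:.1f}\t{hi:.1f}\t{n}\n")
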