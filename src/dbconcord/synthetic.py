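"""Synthetic catalogue generator with planted ground truth.

The real study conditions — several reference databases annotated with
NCBI taxIDs, a known overlap structure, known complete/fragmented/mixed
fractions, and heavy-tailed contig lengths — cannot be reconstructed
without downloading the live databases.  This module generates a
miniature version of those conditions from scratch: a rank-structured
taxonomy (genus -> species -> strain) written in the exact taxdump
dialect, plus N manifest TSVs whose species-level overlap partition,
composition fractions, and contig length model are *planted* and
returned as ground truth, so the full pipeline can be tested by exact
recovery.

Generated records may reference a species by its strain child (to
exercise rank projection) or through a merged-id alias (to exercise
taxid resolution); both are drawn from dedicated random streams so that
turning them on or off leaves the planted structure untouched.

Defaults emulate the fungal-catalogue setting: four databases, an
exactly-k overlap vector with the same shape as the published fungal
species partition at ~1/10 scale, composition fractions
(0.14 complete, 0.81 fragmented, 0.05 mixed), and lognormal contig
lengths with mean 500 kbp.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .concordance import OverlapPartition
from .manifest_io import DatabaseManifest, ReferenceRecord, SequenceRecord, write_manifest_tsv
from .taxonomy import Taxonomy, load_taxdump

__all__ = [
    "SimulationDesign",
    "SpeciesRegistry",
    "SyntheticTruth",
    "generate_taxonomy",
    "generate_databases",
    "write_reference_fasta",
]

FractionTriple = tuple[float, float, float]  # (complete, fragmented, mixed)


@dataclass
class SimulationDesign:
    """All knobs of the synthetic study, with study-like defaults.

    ``partition_cells`` (full cell-count vector keyed by database-label
    subsets) takes precedence over ``partition_exactly_k`` (counts per
    overlap degree, cells assigned at random).  ``composition_fractions``
    is one (complete, fragmented, mixed) triple applied to every database,
    or a per-label mapping.  Contig lengths are lognormal: the default
    (log-mean, log-sd) gives mean exp(mu + sigma^2/2) = 500 kbp.
    """

    n_databases: int = 4
    database_names: Optional[list[str]] = None
    n_genera: int = 48
    species_per_genus: float = 4.0  # mean; sampled as 1 + Poisson(mean - 1)
    strains_per_species: float = 1.0  # mean of Poisson
    partition_cells: Optional[dict[tuple[str, ...], int]] = None
    partition_exactly_k: dict[int, int] = field(
        default_factory=lambda: {4: 5, 3: 18, 2: 19, 1: 99}
    )
    composition_fractions: Union[FractionTriple, dict[str, FractionTriple]] = (
        0.14, 0.81, 0.05,
    )
    contigs_per_fragmented: float = 20.0  # mean; sampled as 1 + Poisson(mean - 1)
    length_log_mean: float = math.log(5e5) - 0.5
    length_log_sd: float = 1.0
    scaffold_fraction: float = 0.1  # fragment sequences labelled scaffold
    merged_fraction: float = 0.0  # emitted species ids redirected via merged.dmp
    strain_emission_fraction: float = 0.0  # records citing a strain child id
    strain_rank: str = "strain"  # "no rank" reproduces unranked-isolate ambiguity
    seed: int = 0

    def labels(self) -> list[str]:
        if self.database_names is not None:
            if len(self.database_names) != self.n_databases:
                raise ValueError("database_names length != n_databases")
            return list(self.database_names)
        return [f"db{i + 1}" for i in range(self.n_databases)]

    def fractions_for(self, label: str) -> FractionTriple:
        fr = self.composition_fractions
        if isinstance(fr, dict):
            fr = fr[label]
        if len(fr) != 3 or any(x < 0 for x in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"composition fractions {fr} must be >=0 and sum to 1")
        return tuple(fr)  # type: ignore[return-value]

    def validate(self) -> None:
        if self.n_databases < 2:
            raise ValueError("need at least 2 databases")
        if self.n_genera < 1:
            raise ValueError("need at least one genus")
        labels = self.labels()
        for lab in labels:
            self.fractions_for(lab)
        if self.partition_cells is not None:
            for key, count in self.partition_cells.items():
                if count < 0:
                    raise ValueError(f"negative cell count for {key}")
                if not key or not set(key) <= set(labels):
                    raise ValueError(f"cell key {key} not a non-empty subset of labels")
        else:
            for k, count in self.partition_exactly_k.items():
                if not 1 <= k <= self.n_databases:
                    raise ValueError(f"exactly-k degree {k} outside 1..N")
                if count < 0:
                    raise ValueError(f"negative exactly-{k} count")
        if not 0.0 <= self.merged_fraction <= 1.0:
            raise ValueError("merged_fraction outside [0, 1]")
        if not 0.0 <= self.strain_emission_fraction <= 1.0:
            raise ValueError("strain_emission_fraction outside [0, 1]")

    def partition_total(self) -> int:
        if self.partition_cells is not None:
            return sum(self.partition_cells.values())
        return sum(self.partition_exactly_k.values())

    @property
    def length_mean_bp(self) -> float:
        """Expected contig length of the lognormal model."""
        return math.exp(self.length_log_mean + self.length_log_sd**2 / 2)


@dataclass
class SpeciesRegistry:
    """Bookkeeping from taxonomy generation, consumed by database generation."""

    genus_taxids: list[int]
    species_taxids: list[int]
    genus_of_species: dict[int, int]
    strains_of_species: dict[int, list[int]]
    merged_alias: dict[int, int]  # species -> old-id alias in merged.dmp


@dataclass
class SyntheticTruth:
    """Planted ground truth returned by :func:`generate_databases`."""

    planted_partition: OverlapPartition
    planted_fractions: dict[str, FractionTriple]
    planted_length_mean_bp: dict[str, float]
    emitted_files: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "databases": self.planted_partition.databases,
            "union_size": self.planted_partition.union_size,
            "cells": {
                ";".join(key): sorted(members)
                for key, members in self.planted_partition.cells.items()
            },
            "fractions": {
                d: list(fr) for d, fr in self.planted_fractions.items()
            },
            "length_mean_bp": self.planted_length_mean_bp,
            "emitted_files": self.emitted_files,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                              encoding="utf-8")


# Independent random streams per concern: turning one feature on or off
# (merged aliases, strain emission) must not perturb the draws of another.
_STREAMS = ("taxonomy", "assignment", "composition", "emission", "merged", "lengths")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _dmp_line(*fields) -> str:
    return "\t|\t".join(str(f) for f in fields) + "\t|\n"


def generate_taxonomy(
    design: SimulationDesign, out_dir: str | Path
) -> tuple[Taxonomy, SpeciesRegistry]:
    """Emit taxdump files for a genus -> species -> strain hierarchy.

    Writes ``nodes.dmp``, ``names.dmp``, ``merged.dmp`` and
    ``delnodes.dmp`` in the exact dialect under ``out_dir`` and returns
    the loaded :class:`Taxonomy` plus the registry of generated ids.
    Deterministic given ``design.seed``; ``merged.dmp`` holds one alias
    per species when ``merged_fraction > 0`` and is empty otherwise.
    """
    design.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rngs(design.seed)["taxonomy"]

    nodes: list[tuple[int, int, str, str]] = [(1, 1, "no rank", "root")]
    genus_ids: list[int] = []
    species_ids: list[int] = []
    genus_of: dict[int, int] = {}
    strains_of: dict[int, list[int]] = {}

    next_id = 2
    for g in range(design.n_genera):
        gid = next_id
        next_id += 1
        genus_ids.append(gid)
        nodes.append((gid, 1, "genus", f"Genus{g + 1}"))
        n_sp = 1 + int(rng.poisson(max(design.species_per_genus - 1.0, 0.0)))
        for s in range(n_sp):
            sid = next_id
            next_id += 1
            species_ids.append(sid)
            genus_of[sid] = gid
            strains_of[sid] = []
            nodes.append((sid, gid, "species", f"Genus{g + 1} species{s + 1}"))
            n_str = int(rng.poisson(design.strains_per_species))
            # ranked strains hang under their species; unranked "isolates"
            # hang off the genus, so their lineage has no species node
            ranked = design.strain_rank.strip().lower() == "strain"
            for t in range(n_str):
                tid = next_id
                next_id += 1
                strains_of[sid].append(tid)
                nodes.append(
                    (tid, sid if ranked else gid, design.strain_rank,
                     f"Genus{g + 1} species{s + 1} strain{t + 1}")
                )

    alias: dict[int, int] = {}
    if design.merged_fraction > 0:
        for sid in species_ids:
            alias[sid] = next_id
            next_id += 1

    nodes_path = out / "nodes.dmp"
    names_path = out / "names.dmp"
    merged_path = out / "merged.dmp"
    delnodes_path = out / "delnodes.dmp"
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for taxid, parent, rank, _ in nodes:
            fh.write(_dmp_line(taxid, parent, rank))
    with open(names_path, "w", encoding="utf-8") as fh:
        for taxid, _, _, name in nodes:
            fh.write(_dmp_line(taxid, name, "", "scientific name"))
    with open(merged_path, "w", encoding="utf-8") as fh:
        for sid in species_ids:
            if sid in alias:
                fh.write(_dmp_line(alias[sid], sid))
    delnodes_path.write_text("", encoding="utf-8")

    tax = load_taxdump(nodes_path, names_path, merged_path, delnodes_path)
    registry = SpeciesRegistry(genus_ids, species_ids, genus_of, strains_of, alias)
    return tax, registry


def _plant_cells(
    design: SimulationDesign,
    registry: SpeciesRegistry,
    rng_assign: np.random.Generator,
) -> dict[tuple[str, ...], set[int]]:
    """Assign species to overlap cells according to the partition design."""
    labels = design.labels()
    total = design.partition_total()
    if total > len(registry.species_taxids):
        raise ValueError(
            f"partition total {total} exceeds the {len(registry.species_taxids)} "
            "generated species"
        )
    pool = list(registry.species_taxids)
    rng_assign.shuffle(pool)
    cells: dict[tuple[str, ...], set[int]] = {}
    pos = 0
    if design.partition_cells is not None:
        order = {d: i for i, d in enumerate(labels)}
        for key, count in design.partition_cells.items():
            canon = tuple(sorted(key, key=order.__getitem__))
            if count == 0:
                continue
            cells.setdefault(canon, set()).update(pool[pos:pos + count])
            pos += count
    else:
        for k in sorted(design.partition_exactly_k, reverse=True):
            for _ in range(design.partition_exactly_k[k]):
                idx = rng_assign.choice(len(labels), size=k, replace=False)
                canon = tuple(labels[i] for i in sorted(idx))
                cells.setdefault(canon, set()).add(pool[pos])
                pos += 1
    return cells


def generate_databases(
    design: SimulationDesign,
    registry: SpeciesRegistry,
    out_dir: str | Path,
) -> tuple[dict[str, DatabaseManifest], SyntheticTruth]:
    """Emit one manifest TSV per database with the planted structure.

    Species are assigned to overlap cells per the partition design; each
    database gets one record per species in its cells.  Record taxids may
    be strain children (``strain_emission_fraction``) or merged aliases
    (``merged_fraction``).  Completeness class, contig counts and lognormal
    lengths are drawn per record.  Returns the manifests and the
    :class:`SyntheticTruth` (also serialized as ``truth.json``).
    """
    design.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _rngs(design.seed)
    labels = design.labels()

    cells = _plant_cells(design, registry, rngs["assignment"])
    union = set().union(*cells.values()) if cells else set()
    planted = OverlapPartition(labels, cells, union_size=len(union))

    species_by_db: dict[str, list[int]] = {d: [] for d in labels}
    for key, members in cells.items():
        for d in key:
            species_by_db[d].extend(members)

    manifests: dict[str, DatabaseManifest] = {}
    files: dict[str, str] = {}
    for d in labels:
        fr = design.fractions_for(d)
        records: list[ReferenceRecord] = []
        for sid in sorted(species_by_db[d]):
            taxid = sid
            strains = registry.strains_of_species[sid]
            if strains and rngs["emission"].random() < design.strain_emission_fraction:
                taxid = strains[int(rngs["emission"].integers(len(strains)))]
            elif sid in registry.merged_alias and (
                rngs["merged"].random() < design.merged_fraction
            ):
                taxid = registry.merged_alias[sid]
            cls = int(rngs["composition"].choice(3, p=fr))
            records.append(
                _make_record(d, sid, taxid, cls, design, rngs)
            )
        manifest = DatabaseManifest(d, records)
        path = out / f"{d}.manifest.tsv"
        write_manifest_tsv(manifest, path)
        manifests[d] = manifest
        files[d] = str(path)

    truth = SyntheticTruth(
        planted_partition=planted,
        planted_fractions={d: design.fractions_for(d) for d in labels},
        planted_length_mean_bp={d: design.length_mean_bp for d in labels},
        emitted_files=files,
    )
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    truth.emitted_files["truth"] = str(truth_path)
    return manifests, truth


def _make_record(
    db: str,
    sid: int,
    taxid: int,
    cls: int,
    design: SimulationDesign,
    rngs: dict[str, np.random.Generator],
) -> ReferenceRecord:
    """Build one reference record of planted class 0=complete 1=fragmented 2=mixed."""
    rng_len = rngs["lengths"]
    rng_comp = rngs["composition"]
    acc = f"{db}:GCA_{sid:06d}"
    seqs: list[SequenceRecord] = []

    def chromosomes(n: int) -> None:
        for i in range(n):
            # chromosome sizes ~5 Mbp; never enter contig statistics
            length = int(rng_len.lognormal(math.log(5e6) - 0.125, 0.5))
            seqs.append(SequenceRecord(f"{acc}.chr{i + 1}", max(length, 1), "chromosome"))

    def fragments(n: int) -> None:
        for i in range(n):
            length = int(round(rng_len.lognormal(design.length_log_mean,
                                                 design.length_log_sd)))
            role = "scaffold" if rng_comp.random() < design.scaffold_fraction else "contig"
            seqs.append(SequenceRecord(f"{acc}.frag{i + 1}", max(length, 1), role))

    n_frag = 1 + int(rng_comp.poisson(max(design.contigs_per_fragmented - 1.0, 0.0)))
    if cls == 0:
        chromosomes(1 + int(rng_comp.poisson(2)))
    elif cls == 1:
        fragments(n_frag)
    else:
        chromosomes(1 + int(rng_comp.poisson(1)))
        fragments(n_frag)
    return ReferenceRecord(acc, taxid, tuple(seqs))


def write_reference_fasta(
    record: ReferenceRecord, path: str | Path, seed: int = 0, line_width: int = 70
) -> None:
    """Emit random-ACGT FASTA matching a record's sequence ids/lengths/roles.

    Intended for exercising the FASTA composition scanner; the role is
    embedded as a keyword in the description line.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with open(path, "w", encoding="utf-8") as fh:
        for seq in record.sequences:
            fh.write(f">{seq.seq_id} {seq.role} of {record.accession}\n")
            letters = "".join(rng.choice(bases, size=seq.length))
            for i in range(0, len(letters), line_width):
                fh.write(letters[i:i + line_width] + "\n")
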