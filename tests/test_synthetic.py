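"""Synthetic generator: determinism, planted structure, and exact recovery."""

import math

import numpy as np
import pytest
from scipy import stats

from dbconcord import (
    SimulationDesign,
    composition_profile,
    contig_length_stats,
    exactly_k_counts,
    generate_databases,
    generate_taxonomy,
    project_to_rank,
    scan_fasta_composition,
    venn_partition,
    write_reference_fasta,
)
from dbconcord.composition import CompletenessClass


def recover_partition(manifests, tax, rank="species"):
    return venn_partition(
        {lab: project_to_rank(m, tax, rank).taxon_set for lab, m in manifests.items()}
    )


class TestGenerateTaxonomy:
    def test_node_counts_match_design(self, tmp_path):
        design = SimulationDesign(
            n_genera=3, species_per_genus=2.0, strains_per_species=1.0, seed=7
        )
        tax, reg = generate_taxonomy(design, tmp_path)
        n_strains = sum(len(s) for s in reg.strains_of_species.values())
        assert len(reg.genus_taxids) == 3
        assert len(tax.nodes) == 1 + 3 + len(reg.species_taxids) + n_strains
        ranks = [tax.nodes[s].rank for s in reg.species_taxids]
        assert set(ranks) == {"species"}

    def test_zero_genera_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="genus"):
            generate_taxonomy(SimulationDesign(n_genera=0), tmp_path)

    def test_merged_dmp_empty_when_fraction_zero(self, tmp_path):
        generate_taxonomy(SimulationDesign(merged_fraction=0.0, seed=1), tmp_path)
        assert (tmp_path / "merged.dmp").read_text() == ""

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        design = SimulationDesign(seed=11, merged_fraction=0.1)
        a, b = tmp_path / "a", tmp_path / "b"
        generate_taxonomy(design, a)
        generate_taxonomy(design, b)
        for name in ("nodes.dmp", "names.dmp", "merged.dmp", "delnodes.dmp"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_emitted_dialect_reloads_through_the_parser(self, tmp_path):
        design = SimulationDesign(seed=2, merged_fraction=0.5)
        tax, reg = generate_taxonomy(design, tmp_path)
        assert set(reg.species_taxids) <= set(tax.nodes)
        assert all(tax.resolve(a).status == "merged"
                   for a in reg.merged_alias.values())


class TestPlantedRecovery:
    def test_full_cell_vector_recovered_exactly(self, tmp_path):
        labels = ["dbA", "dbB", "dbC"]
        cells = {
            ("dbA",): 10, ("dbB",): 8, ("dbC",): 12,
            ("dbA", "dbB"): 9, ("dbB", "dbC"): 6,
            ("dbA", "dbB", "dbC"): 15,
        }
        design = SimulationDesign(
            n_databases=3, database_names=labels, n_genera=20,
            partition_cells=cells, seed=5,
        )
        tax, reg = generate_taxonomy(design, tmp_path / "tax")
        manifests, truth = generate_databases(design, reg, tmp_path)
        p = recover_partition(manifests, tax)
        assert p.cells == truth.planted_partition.cells  # species identity, not counts
        assert {k: len(v) for k, v in p.cells.items()} == cells

    def test_exactly_k_vector_recovered(self, tmp_path):
        design = SimulationDesign(
            n_databases=3, n_genera=25, partition_exactly_k={3: 10, 2: 20, 1: 30},
            seed=9,
        )
        tax, reg = generate_taxonomy(design, tmp_path / "tax")
        manifests, _ = generate_databases(design, reg, tmp_path)
        counts = exactly_k_counts(recover_partition(manifests, tax))
        assert counts == {3: 10, 2: 20, 1: 30}

    def test_partition_total_exceeding_species_rejected(self, tmp_path):
        design = SimulationDesign(
            n_genera=1, species_per_genus=1.0, partition_exactly_k={1: 50}, seed=0
        )
        _, reg = generate_taxonomy(design, tmp_path / "tax")
        with pytest.raises(ValueError, match="exceeds"):
            generate_databases(design, reg, tmp_path)

    def test_composition_fractions_recovered_within_binomial_99ci(self, tmp_path):
        fractions = (0.14, 0.81, 0.05)
        design = SimulationDesign(
            n_databases=2, n_genera=280, species_per_genus=4.0,
            partition_exactly_k={2: 1000}, composition_fractions=fractions,
            contigs_per_fragmented=3.0, seed=13,
        )
        _, reg = generate_taxonomy(design, tmp_path / "tax")
        manifests, _ = generate_databases(design, reg, tmp_path)
        prof = composition_profile(manifests["db1"])
        n = prof.n_classified
        assert n == 1000
        for cls, frac in zip(
            (CompletenessClass.COMPLETE, CompletenessClass.FRAGMENTED,
             CompletenessClass.MIXED), fractions,
        ):
            lo, hi = stats.binom.interval(0.99, n, frac)
            assert lo <= prof.counts[cls] <= hi

    def test_length_mean_within_three_standard_errors(self, tmp_path):
        design = SimulationDesign(
            n_databases=2, n_genera=160, species_per_genus=4.0,
            partition_exactly_k={2: 500}, composition_fractions=(0.0, 1.0, 0.0),
            contigs_per_fragmented=21.0, seed=17,
        )
        _, reg = generate_taxonomy(design, tmp_path / "tax")
        manifests, truth = generate_databases(design, reg, tmp_path)
        s = contig_length_stats(manifests["db1"])
        assert s.n >= 10_000
        mu, sigma = design.length_log_mean, design.length_log_sd
        expected = math.exp(mu + sigma**2 / 2)
        assert expected == pytest.approx(truth.planted_length_mean_bp["db1"])
        sd = expected * math.sqrt(math.exp(sigma**2) - 1)
        assert abs(s.mean_bp - expected) <= 3 * sd / math.sqrt(s.n)


class TestEmissionInvariances:
    BASE = dict(n_databases=3, n_genera=30, strains_per_species=2.0,
                partition_exactly_k={3: 8, 2: 12, 1: 20}, seed=23)

    def test_strain_emission_leaves_species_partition_unchanged(self, tmp_path):
        d0 = SimulationDesign(strain_emission_fraction=0.0, **self.BASE)
        d1 = SimulationDesign(strain_emission_fraction=1.0, **self.BASE)
        tax0, reg0 = generate_taxonomy(d0, tmp_path / "t0")
        tax1, reg1 = generate_taxonomy(d1, tmp_path / "t1")
        m0, _ = generate_databases(d0, reg0, tmp_path / "m0")
        m1, _ = generate_databases(d1, reg1, tmp_path / "m1")
        assert recover_partition(m0, tax0).cells == recover_partition(m1, tax1).cells

    def test_merged_ids_are_transparent(self, tmp_path):
        d0 = SimulationDesign(merged_fraction=0.0, **self.BASE)
        d1 = SimulationDesign(merged_fraction=0.2, **self.BASE)
        tax0, reg0 = generate_taxonomy(d0, tmp_path / "t0")
        tax1, reg1 = generate_taxonomy(d1, tmp_path / "t1")
        m0, _ = generate_databases(d0, reg0, tmp_path / "m0")
        m1, _ = generate_databases(d1, reg1, tmp_path / "m1")
        p0, p1 = recover_partition(m0, tax0), recover_partition(m1, tax1)
        assert p0.cells == p1.cells
        # and some records really did go through merged ids
        emitted = {r.taxid for m in m1.values() for r in m.records}
        assert emitted & set(reg1.merged_alias.values())

    def test_unranked_strains_produce_projection_exclusions(self, tmp_path):
        design = SimulationDesign(strain_rank="no rank",
                                  strain_emission_fraction=1.0, **self.BASE)
        tax, reg = generate_taxonomy(design, tmp_path / "tax")
        manifests, _ = generate_databases(design, reg, tmp_path)
        projs = [project_to_rank(m, tax, "species") for m in manifests.values()]
        reasons = {e.reason for p in projs for e in p.exclusions}
        assert reasons <= {"no_ancestor_at_rank"}
        assert any(p.exclusions for p in projs)


def test_fasta_emission_round_trips_through_the_scanner(tmp_path):
    design = SimulationDesign(n_databases=2, n_genera=4, partition_exactly_k={2: 3},
                              contigs_per_fragmented=2.0, seed=3)
    _, reg = generate_taxonomy(design, tmp_path / "tax")
    manifests, _ = generate_databases(design, reg, tmp_path)
    rec = manifests["db1"].records[0]
    fasta = tmp_path / "ref.fa"
    write_reference_fasta(rec, fasta, seed=1)
    scanned = scan_fasta_composition(fasta, rec.accession, rec.taxid)
    assert [(s.length, s.role) for s in scanned.sequences] == [
        (s.length, s.role) for s in rec.sequences
    ]


def test_truth_json_is_deterministic(tmp_path):
    design = SimulationDesign(seed=42)
    for sub in ("a", "b"):
        _, reg = generate_taxonomy(design, tmp_path / sub / "tax")
        generate_databases(design, reg, tmp_path / sub)
    ja = (tmp_path / "a" / "truth.json").read_text()
    jb = (tmp_path / "b" / "truth.json").read_text()
    assert ja.replace(str(tmp_path / "a"), "") == jb.replace(str(tmp_path / "b"), "")
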