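from pathlib import Path

import pytest

from dbconcord import Taxonomy, TaxonomyNode, load_taxdump


def write_dmp(path: Path, rows: list[tuple]) -> Path:
    """Write rows in the taxdump dialect: \\t|\\t separators, \\t| terminator."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write("\t|\t".join(str(f) for f in row) + "\t|\n")
    return path


def make_taxdump(
    tmp_path: Path,
    nodes: list[tuple],
    names: list[tuple] | None = None,
    merged: list[tuple] | None = None,
    delnodes: list[tuple] | None = None,
) -> dict[str, Path]:
    """Emit a taxdump fileset under tmp_path and return the paths."""
    paths = {
        "nodes": write_dmp(tmp_path / "nodes.dmp", nodes),
        "names": write_dmp(
            tmp_path / "names.dmp",
            names or [(t[0], f"taxon {t[0]}", "", "scientific name") for t in nodes],
        ),
        "merged": write_dmp(tmp_path / "merged.dmp", merged or []),
        "delnodes": write_dmp(tmp_path / "delnodes.dmp", delnodes or []),
    }
    return paths


# Minimal lineage: root 1 -> genus 10 -> species 100 -> strain 1000.
FOUR_NODES = [
    (1, 1, "no rank"),
    (10, 1, "genus"),
    (100, 10, "species"),
    (1000, 100, "strain"),
]


@pytest.fixture
def tiny_taxdump(tmp_path) -> dict[str, Path]:
    return make_taxdump(tmp_path, FOUR_NODES, merged=[(999, 100)], delnodes=[(888,)])


@pytest.fixture
def tiny_taxonomy(tiny_taxdump) -> Taxonomy:
    return load_taxdump(
        tiny_taxdump["nodes"],
        tiny_taxdump["names"],
        tiny_taxdump["merged"],
        tiny_taxdump["delnodes"],
    )


@pytest.fixture
def two_genus_taxonomy() -> Taxonomy:
    """Root, two genera, three species, strains, plus an unranked isolate.

    Taxid 777 hangs directly off genus 20 with rank "no rank": its lineage
    has no species-rank node, mirroring isolates never assigned a species id.
    """
    nodes = {
        1: TaxonomyNode(1, 1, "no rank", "root"),
        10: TaxonomyNode(10, 1, "genus", "GenA"),
        20: TaxonomyNode(20, 1, "genus", "GenB"),
        100: TaxonomyNode(100, 10, "species", "GenA sp1"),
        101: TaxonomyNode(101, 10, "species", "GenA sp2"),
        200: TaxonomyNode(200, 20, "species", "GenB sp1"),
        1000: TaxonomyNode(1000, 100, "strain", "GenA sp1 strA"),
        777: TaxonomyNode(777, 20, "no rank", "GenB isolate"),
    }
    return Taxonomy(nodes=nodes, merged={999: 100}, deleted={888})
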