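"""Neighborhood extraction, P/S labeling, pathway tallies, and HTML rendering."""

import hashlib

import pytest

from ecrecruit import examples
from ecrecruit.ec import parse_ec
from ecrecruit.neighborhood import (
    GeneRecord,
    NeighborhoodConfig,
    ReportEntry,
    assign_labels,
    extract_neighborhood,
    load_genome_table,
    render_report,
    summarize_labels,
    summarize_pathways,
)


def gene(ordinal, gene_id, ec="", pathways=(), replicon="chr"):
    return GeneRecord(
        replicon_id=replicon,
        ordinal=ordinal,
        gene_id=gene_id,
        ec_list=tuple(parse_ec(e) for e in ([ec] if isinstance(ec, str) and ec else ec)),
        pathway_ids=frozenset(pathways),
    )


@pytest.fixture
def linear_genome():
    return [gene(i, f"g{i}") for i in range(30)]


def test_full_window(linear_genome):
    nh = extract_neighborhood(linear_genome, "g15", k=10)
    assert len(nh.genes) == 21
    assert nh.offsets == list(range(-10, 11))
    assert nh.genes[10].gene_id == "g15"


def test_left_truncation(linear_genome):
    nh = extract_neighborhood(linear_genome, "g0", k=10)
    assert len(nh.genes) == 11 and nh.offsets[0] == 0


def test_circular_wraparound(linear_genome):
    nh = extract_neighborhood(linear_genome, "g0", k=10, circular=True)
    assert len(nh.genes) == 21
    assert [g.gene_id for g in nh.genes[:3]] == ["g20", "g21", "g22"]
    assert nh.genes[10].gene_id == "g0"


def test_anchor_not_found(linear_genome):
    with pytest.raises(ValueError, match="ghost"):
        extract_neighborhood(linear_genome, "ghost", k=10)


def test_window_never_exceeds_2k_plus_1(linear_genome):
    for k in (1, 3, 10, 40):
        for anchor in ("g0", "g5", "g29"):
            nh = extract_neighborhood(linear_genome, anchor, k=k)
            assert len(nh.genes) <= 2 * k + 1


def test_label_rules():
    genes = [
        gene(0, "a", "2.6.1.85"),
        gene(1, "b", "2.4.2.8"),
        gene(2, "c"),
        gene(3, "d", "2.1.1.-"),
    ]
    nh = extract_neighborhood(genes, "a", k=10)
    nh = assign_labels(nh, pm_function_keys={"2.6.1.85", "2.4.2.8"},
                       sm_function_keys={"2.4.2.8", "2.1.1.-"})
    assert nh.labels["a"] == {"P"}
    assert nh.labels["b"] == {"P", "S"}
    assert nh.labels["c"] == frozenset()
    assert nh.labels["d"] == {"S"}  # wildcard EC matches the SM set by string, never P
    assert summarize_labels(nh) == (2, 2)


def test_pathway_summary_toy():
    genes = [
        gene(0, "a", pathways=("X",)),
        gene(1, "b", pathways=("X",)),
        gene(2, "anchor"),
        gene(3, "d", pathways=("X",)),
        gene(4, "e"),
        gene(9, "far", pathways=("Y",)),
    ]
    nh = extract_neighborhood(genes, "anchor", k=10)
    rows = summarize_pathways(nh, NeighborhoodConfig(k_outer=10, k_inner=2))
    assert rows == [(3, 3, "X"), (1, 0, "Y")]


def test_pabb_neighborhood_matches_published_tallies():
    nh = extract_neighborhood(examples.pabb_genome(), examples.pabb_anchor, k=10)
    nh = assign_labels(
        nh, examples.bacillibactin_pm_function_keys(), examples.bacillibactin_sm_function_keys()
    )
    assert summarize_labels(nh) == (13, 2)
    rows = summarize_pathways(nh)
    assert rows[0] == (6, 3, "bsu00790")  # folate biosynthesis dominates
    assert (2, 1, "bsu01110") in rows


def test_trpe_neighborhood_matches_published_tallies():
    nh = extract_neighborhood(examples.trpe_genome(), examples.trpe_anchor, k=10)
    nh = assign_labels(
        nh, examples.bacillibactin_pm_function_keys(), examples.bacillibactin_sm_function_keys()
    )
    assert summarize_labels(nh) == (17, 16)
    rows = summarize_pathways(nh)
    assert rows[0] == (16, 5, "bsu01110")
    assert (12, 5, "bsu00400") in rows


def test_label_permutation_invariance():
    genes = [gene(i, f"g{i}", ec) for i, ec in enumerate(["1.1.1.1", "2.3.1.9", "", "4.2.1.20"])]
    nh = extract_neighborhood(genes, "g1", k=10)
    labeled = assign_labels(nh, {"1.1.1.1", "4.2.1.20"}, {"2.3.1.9"})
    reversed_genome = [
        GeneRecord(replicon_id="chr", ordinal=i, gene_id=g.gene_id, ec_list=g.ec_list)
        for i, g in enumerate(reversed(genes))
    ]
    nh2 = assign_labels(extract_neighborhood(reversed_genome, "g1", k=10),
                        {"1.1.1.1", "4.2.1.20"}, {"2.3.1.9"})
    assert labeled.labels == nh2.labels


def test_genome_table_roundtrip(tmp_path):
    path = tmp_path / "genome.tsv"
    path.write_text(
        "replicon_id\tordinal\tgene_id\tstrand\tproduct\tec\tpathways\n"
        "chr\t0\tg0\t+\tenzyme A\t1.1.1.1\tp1;p2\n"
        "chr\t1\tg1\t-\tnot an enzyme\t\t\n"
    )
    genes = load_genome_table(path)
    assert len(genes) == 2
    assert genes[0].pathway_ids == {"p1", "p2"}
    assert str(genes[0].ec_list[0]) == "1.1.1.1"
    assert genes[1].ec_list == ()


def test_genome_table_rejects_nonincreasing_ordinals(tmp_path):
    path = tmp_path / "genome.tsv"
    path.write_text(
        "replicon_id\tordinal\tgene_id\tstrand\tproduct\tec\tpathways\n"
        "chr\t5\tg0\t+\tx\t\t\n"
        "chr\t5\tg1\t+\tx\t\t\n"
    )
    with pytest.raises(ValueError, match="ordinal"):
        load_genome_table(path)


@pytest.fixture
def report_entry():
    nh = extract_neighborhood(examples.pabb_genome(), examples.pabb_anchor, k=10)
    nh = assign_labels(
        nh, examples.bacillibactin_pm_function_keys(), examples.bacillibactin_sm_function_keys()
    )
    return ReportEntry(
        sm_annotation="bsu:BSU31990 Isochorismate synthase DhbC (EC 5.4.4.2)",
        homolog_annotation="PM bsu:BSU00740 PabB",
        evalue=5e-26,
        neighborhood=nh,
        pathway_rows=tuple(summarize_pathways(nh)),
    )


def test_render_deterministic(report_entry):
    pages = [
        render_report("BGC0000309", [report_entry], pathway_names=examples.PATHWAY_NAMES)
        for _ in range(2)
    ]
    assert hashlib.sha256(pages[0].encode()).digest() == hashlib.sha256(pages[1].encode()).digest()
    assert "5.0E-26" in pages[0] and "Folate biosynthesis" in pages[0]
    assert pages[0].count("<table") == 1


def test_render_empty_entries():
    page = render_report("BGC0000000", [])
    assert "No homologs" in page and page.startswith("<!DOCTYPE html>")


def test_render_bad_template(report_entry):
    with pytest.raises(ValueError, match="placeholder"):
        render_report("BGC0000309", [report_entry], link_template="https://example.org/static")
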