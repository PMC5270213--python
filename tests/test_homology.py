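"""Hit-table parsing, E-value/length filtering, and function hit maps."""

import random

import pytest

from ecrecruit.homology import (
    HitFilterConfig,
    HitTableError,
    HomologyHit,
    build_function_hit_map,
    filter_hits,
    parse_hit_table,
)
from conftest import make_catalog


def hit_line(q, s, evalue, lq=300, ls=300):
    return f"{q}\t{s}\t55.0\t{min(lq, ls)}\t10\t1\t1\t{lq}\t1\t{ls}\t{evalue}\t120.5"


def make_hit(q, s, evalue, bitscore=100.0):
    return HomologyHit(query_id=q, subject_id=s, evalue=evalue, bitscore=bitscore)


def test_parse_well_formed(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(hit_line("q1", "s1", "5e-26") + "\n" + hit_line("q2", "s2", "1e-30") + "\n")
    hits = parse_hit_table(path)
    assert len(hits) == 2
    assert hits[0].evalue == 5e-26 and hits[0].bitscore == 120.5


def test_parse_wrong_column_count(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(hit_line("q1", "s1", "1e-30") + "\n" + "q2\ts2\tonly three\n")
    with pytest.raises(HitTableError, match="line 2"):
        parse_hit_table(path)


def test_parse_non_numeric_evalue(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(hit_line("q1", "s1", "not_a_number") + "\n")
    with pytest.raises(HitTableError, match="line 1"):
        parse_hit_table(path)


def test_parse_extended_dialect(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(hit_line("q1", "s1", "1e-30") + "\t250\t310\n")
    (hit,) = parse_hit_table(path, dialect="std12+lens")
    assert (hit.qlen, hit.slen) == (250, 310)


@pytest.fixture
def catalogs():
    sm = make_catalog("SM", [("q1", "5.4.4.2", "bgc1", 100), ("q2", "5.4.4.2", "bgc2", 400)])
    pm = make_catalog(
        "PM",
        [
            ("s1", "2.6.1.85", "g1", 130),
            ("s2", "4.1.3.27", "g1", 131),
            ("s3", "2.6.1.85", "g2", 100),
            ("q1", "1.1.1.1", "g3", 100),  # same id as a query: self-hit target
        ],
    )
    return sm, pm


def test_length_rule_boundary_inclusive(catalogs):
    sm, pm = catalogs
    hits = [make_hit("q1", "s1", 1e-30), make_hit("q1", "s2", 1e-30)]
    kept, rejected = filter_hits(hits, HitFilterConfig(), sm, pm)
    # |130-100|/100 = 0.30 kept; |131-100|/100 = 0.31 rejected
    assert [h.subject_id for h in kept] == ["s1"]
    assert rejected[0][0].subject_id == "s2" and "length" in rejected[0][1]


def test_evalue_cutoff_inclusive(catalogs):
    sm, pm = catalogs
    hits = [make_hit("q1", "s3", 1e-20), make_hit("q1", "s1", 1.0001e-20)]
    kept, rejected = filter_hits(hits, HitFilterConfig(), sm, pm)
    assert [h.subject_id for h in kept] == ["s3"]
    assert "evalue" in rejected[0][1]


def test_self_hit_removal(catalogs):
    sm, pm = catalogs
    kept, rejected = filter_hits([make_hit("q1", "q1", 1e-50)], HitFilterConfig(), sm, pm)
    assert kept == [] and rejected[0][1] == "self_hit"
    kept, _ = filter_hits(
        [make_hit("q1", "q1", 1e-50)], HitFilterConfig(remove_self_hits=False), sm, pm
    )
    assert len(kept) == 1


def test_multi_hsp_collapse_to_best(catalogs):
    sm, pm = catalogs
    hits = [make_hit("q1", "s3", 1e-25), make_hit("q1", "s3", 1e-60)]
    kept, _ = filter_hits(hits, HitFilterConfig(), sm, pm)
    assert len(kept) == 1 and kept[0].evalue == 1e-60


def test_cutoff_monotonicity(catalogs):
    sm, pm = catalogs
    hits = [
        make_hit("q1", "s3", 1e-25),
        make_hit("q1", "s1", 1e-15),
        make_hit("q2", "s2", 1e-12),
    ]
    strict, _ = filter_hits(hits, HitFilterConfig(evalue_cutoff=1e-20), sm, pm)
    relaxed, _ = filter_hits(hits, HitFilterConfig(evalue_cutoff=1e-10), sm, pm)
    strict_pairs = {(h.query_id, h.subject_id) for h in strict}
    relaxed_pairs = {(h.query_id, h.subject_id) for h in relaxed}
    assert strict_pairs <= relaxed_pairs


def test_order_independence(catalogs):
    sm, pm = catalogs
    hits = [
        make_hit("q1", "s3", 1e-25),
        make_hit("q1", "s1", 1e-40),
        make_hit("q1", "s3", 1e-60),
        make_hit("q2", "s2", 1e-30),
    ]
    shuffled = hits[:]
    random.Random(7).shuffle(shuffled)
    kept_a, _ = filter_hits(hits, HitFilterConfig(), sm, pm)
    kept_b, _ = filter_hits(shuffled, HitFilterConfig(), sm, pm)
    assert kept_a == kept_b


def test_unresolvable_id(catalogs):
    sm, pm = catalogs
    with pytest.raises(HitTableError, match="ghost"):
        filter_hits([make_hit("ghost", "s1", 1e-30)], HitFilterConfig(), sm, pm)


def test_function_map_pools_queries_sharing_function():
    sm = make_catalog(
        "SM", [("q1", "5.4.4.2", "b1", 300), ("q2", "5.4.4.2", "b2", 300)]
    )
    pm = make_catalog("PM", [("s1", "2.6.1.85", "g1", 300), ("s2", "4.1.3.27", "g1", 300)])
    hits = [make_hit("q1", "s1", 1e-30), make_hit("q2", "s2", 1e-40)]
    fmap = build_function_hit_map(hits, sm, pm)
    assert fmap.by_function["full"]["5.4.4.2"] == [("2.6.1.85", 1e-30), ("4.1.3.27", 1e-40)]
    assert fmap.by_function["subdivision"]["5.4.4"] == [("2.6.1", 1e-30), ("4.1.3", 1e-40)]
    assert fmap.by_function["class"]["5"] == [("2", 1e-30), ("4", 1e-40)]


def test_function_map_omits_levels_with_wildcards():
    sm = make_catalog("SM", [("q1", "2.1.1.-", "b1", 300)])
    pm = make_catalog("PM", [("s1", "2.1.1.14", "g1", 300)])
    fmap = build_function_hit_map([make_hit("q1", "s1", 1e-30)], sm, pm)
    assert fmap.by_function["subdivision"]["2.1.1"] == [("2.1.1", 1e-30)]
    assert "full" not in {lvl for lvl in fmap.by_function if fmap.by_function[lvl]} or (
        fmap.by_function["full"] == {}
    )


def test_hit_conservation_across_levels():
    """Function-level multiset cardinality equals kept record-level hits complete there."""
    sm = make_catalog("SM", [("q1", "5.4.4.2", "b1", 300), ("q2", "1.-.-.-", "b1", 300)])
    pm = make_catalog("PM", [("s1", "5.4.4.2", "g1", 300), ("s2", "1.1.1.1", "g1", 300)])
    hits = [make_hit("q1", "s1", 1e-30), make_hit("q2", "s2", 1e-30)]
    fmap = build_function_hit_map(hits, sm, pm)
    assert fmap.n_hits("class") == 2
    assert fmap.n_hits("full") == 1  # q2 incomplete at full
    assert sum(len(v) for v in fmap.by_record.values()) == 2
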