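"""Functional-change graph construction, invariants, and exports."""

import math

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from ecrecruit.flexibility import functional_conservation
from ecrecruit.homology import FunctionHitMap, HitFilterConfig
from ecrecruit.network import DEFAULT_BINNING, EValueBinning, build_change_graph, export_graph


def fmap_from(view, level="subdivision"):
    by_function = {lvl: {} for lvl in ("class", "subclass", "subdivision", "full")}
    by_function[level] = view
    return FunctionHitMap(by_record={}, by_function=by_function, config=HitFilterConfig())


def test_toy_edge():
    fmap = fmap_from({"4.2.1": [("2.6.1", 1e-30), ("4.2.1", 1e-40)]})
    graph = build_change_graph(fmap, "subdivision")
    assert list(graph.edges) == [("2.6.1", "4.2.1")]
    edge = graph.edges["2.6.1", "4.2.1"]
    assert edge["weight"] == 1 and edge["mean_evalue"] == pytest.approx(1e-30)
    assert graph.nodes["4.2.1"]["n_hits"] == 2
    assert graph.nodes["4.2.1"]["fc"] == pytest.approx(0.5)


def test_all_same_graph_is_edgeless():
    fmap = fmap_from({"1.1.1": [("1.1.1", 1e-30)], "2.3.1": [("2.3.1", 1e-40)]})
    graph = build_change_graph(fmap, "subdivision")
    assert graph.number_of_edges() == 0 and graph.number_of_nodes() == 2


def test_no_self_loops_and_pm_flagging():
    fmap = fmap_from({"5.4.4": [("5.4.4", 1e-30), ("2.6.1", 1e-25)]})
    graph = build_change_graph(fmap, "subdivision", pm_keys={"2.6.1"})
    assert not list(nx.selfloop_edges(graph))
    assert graph.nodes["5.4.4"]["present_in_pm"] is False  # Fig-3-style "-" mark
    assert graph.nodes["2.6.1"]["present_in_pm"] is True


def test_geometric_vs_arithmetic_mean():
    fmap = fmap_from({"4.2.1": [("2.6.1", 1e-20), ("2.6.1", 1e-60)]})
    geo = build_change_graph(fmap, "subdivision", mean_mode="geometric")
    ari = build_change_graph(fmap, "subdivision", mean_mode="arithmetic")
    assert geo.edges["2.6.1", "4.2.1"]["mean_evalue"] == pytest.approx(1e-40)
    assert ari.edges["2.6.1", "4.2.1"]["mean_evalue"] == pytest.approx(5e-21)


@given(
    st.dictionaries(
        st.sampled_from(["1.1.1", "2.3.1", "4.2.1", "5.4.4", "6.3.2"]),
        st.lists(
            st.tuples(
                st.sampled_from(["1.1.1", "2.3.1", "4.2.1", "5.4.4", "6.3.2"]),
                st.floats(1e-120, 1e-21),
            ),
            min_size=1,
            max_size=10,
        ),
        min_size=1,
    )
)
def test_edge_weight_conservation_identity(view):
    """Sum of incoming edge weights equals n_hits x (1 - fc) for every node,
    and total hits split exactly into edge weights plus same-function hits."""
    fmap = fmap_from(view)
    fc = functional_conservation(fmap, "subdivision")
    graph = build_change_graph(fmap, "subdivision", fc_table=fc)
    total_same = 0
    for key, hits in view.items():
        n_same = sum(1 for pm, _ in hits if pm == key)
        total_same += n_same
        incoming = sum(d["weight"] for _, _, d in graph.in_edges(key, data=True))
        assert incoming == len(hits) - n_same
    total_hits = sum(len(h) for h in view.values())
    total_edges = sum(d["weight"] for _, _, d in graph.edges(data=True))
    assert total_edges + total_same == total_hits


@given(st.floats(min_value=1e-200, max_value=1.0))
def test_binning_exhaustive_and_exclusive(evalue):
    label = DEFAULT_BINNING.label(evalue)
    assert label in DEFAULT_BINNING.labels()
    # exactly one bin: labels partition by construction, check boundary orientation
    if evalue > 1e-20:
        assert label == ">1e-20"
    elif evalue <= 1e-100:
        assert label == "<=1e-100"


def test_binning_validation():
    with pytest.raises(ValueError):
        EValueBinning((1e-50, 1e-20))  # not decreasing
    with pytest.raises(ValueError):
        EValueBinning(())


@pytest.fixture
def toy_graph():
    fmap = fmap_from(
        {
            "5.4.4": [("2.6.1", 1e-26), ("4.1.3", 3e-21)],
            "2.3.1": [("2.3.1", 1e-50)],
        }
    )
    return build_change_graph(fmap, "subdivision", pm_keys={"2.6.1", "4.1.3", "2.3.1"})


def test_graphml_roundtrip(toy_graph, tmp_path):
    path = tmp_path / "g.graphml"
    export_graph(toy_graph, path, "graphml")
    back = nx.read_graphml(path)
    assert set(back.nodes) == set(toy_graph.nodes)
    assert set(back.edges) == set(toy_graph.edges)
    for u, v in toy_graph.edges:
        for attr in ("weight", "mean_evalue", "bin"):
            assert back.edges[u, v][attr] == pytest.approx(toy_graph.edges[u, v][attr]) \
                if attr != "bin" else back.edges[u, v][attr] == toy_graph.edges[u, v][attr]
    for n in toy_graph.nodes:
        assert back.nodes[n]["present_in_pm"] == toy_graph.nodes[n]["present_in_pm"]


def test_edge_tsv_row_count(toy_graph, tmp_path):
    path = tmp_path / "g.tsv"
    export_graph(toy_graph, path, "edge-tsv")
    lines = path.read_text().strip().splitlines()
    assert len(lines) - 1 == toy_graph.number_of_edges()


def test_sif_includes_isolated_nodes(tmp_path):
    fmap = fmap_from({"1.1.1": [("1.1.1", 1e-30)]})
    graph = build_change_graph(fmap, "subdivision")
    path = tmp_path / "g.sif"
    export_graph(graph, path, "sif")
    assert path.read_text().strip() == "1.1.1"


def test_unknown_format(toy_graph, tmp_path):
    with pytest.raises(ValueError, match="format"):
        export_graph(toy_graph, tmp_path / "x", "dot")
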