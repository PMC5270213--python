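"""Directed functional-change networks.

Every PM homolog hit whose function key differs from its SM query's key
witnesses a functional change acquired during (or since) recruitment from
primary metabolism. Pooling such hits per ordered key pair gives a directed
graph: an edge ``pm_key -> sm_key`` weighted by the number of supporting hits
and annotated with their mean E-value, binned on a logarithmic scale. Nodes
carry the total hit count and functional-conservation rate of their SM key;
same-function hits contribute to node fc, never to edges. Keys that never
occur on the PM side are flagged (``present_in_pm = False``).

Graphs are built with :mod:`networkx` and exported as GraphML (lossless),
SIF (topology only, interaction ``changes_to``), or an edge-attribute TSV,
with deterministic lexicographic node/edge ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from .flexibility import FcTable, functional_conservation
from .homology import FunctionHitMap

__all__ = [
    "EValueBinning",
    "DEFAULT_BINNING",
    "build_change_graph",
    "export_graph",
]


@dataclass(frozen=True)
class EValueBinning:
    """Logarithmic E-value bins defined by upper bounds.

    ``edges`` are strictly decreasing E-value upper bounds, e.g.
    ``(1e-20, 1e-50, 1e-100)`` yields the bins ``>1e-20``, ``(1e-50, 1e-20]``,
    ``(1e-100, 1e-50]`` and ``<=1e-100``; every positive E-value falls in
    exactly one bin.
    """

    edges: tuple[float, ...] = (1e-20, 1e-50, 1e-100)

    def __post_init__(self) -> None:
        if not self.edges or any(e <= 0 for e in self.edges):
            raise ValueError("bin edges must be positive")
        if any(b >= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly decreasing")

    def label(self, evalue: float) -> str:
        if evalue <= 0:
            raise ValueError("E-value must be positive for binning")
        if evalue > self.edges[0]:
            return f">{self.edges[0]:g}"
        for upper, lower in zip(self.edges, self.edges[1:]):
            if lower < evalue <= upper:
                return f"({lower:g},{upper:g}]"
        return f"<={self.edges[-1]:g}"

    def labels(self) -> tuple[str, ...]:
        out = [f">{self.edges[0]:g}"]
        out += [f"({lo:g},{up:g}]" for up, lo in zip(self.edges, self.edges[1:])]
        out.append(f"<={self.edges[-1]:g}")
        return tuple(out)


DEFAULT_BINNING = EValueBinning()

# E-values of 0 (underflow in aligner output) are clamped here before taking logs.
_EVALUE_FLOOR = 1e-300


def _mean_evalue(evalues: Sequence[float], mode: str) -> float:
    if mode == "arithmetic":
        return sum(evalues) / len(evalues)
    if mode == "geometric":
        logs = [math.log10(max(e, _EVALUE_FLOOR)) for e in evalues]
        return 10 ** (sum(logs) / len(logs))
    raise ValueError(f"unknown mean_mode {mode!r}")


def build_change_graph(
    fmap: FunctionHitMap,
    level: str,
    fc_table: Optional[FcTable] = None,
    pm_keys: Optional[Iterable[str]] = None,
    binning: EValueBinning = DEFAULT_BINNING,
    mean_mode: str = "geometric",
) -> nx.DiGraph:
    """Build the directed functional-change graph at *level*.

    Parameters
    ----------
    fmap:
        Function-level hit map (filtered hits only).
    level:
        EC grouping level; must match *fc_table* if one is supplied.
    fc_table:
        Functional-conservation rates; computed from *fmap* when omitted.
    pm_keys:
        Keys present in the PM catalog at this level; nodes outside this set
        are flagged ``present_in_pm = False``. When omitted, a key counts as
        present iff it occurs as a hit (edge source or same-function hit).
    binning, mean_mode:
        E-value bin boundaries and the per-edge mean (geometric by default:
        E-values span many orders of magnitude).
    """
    if fc_table is None:
        fc_table = functional_conservation(fmap, level)
    if fc_table.level != level:
        raise ValueError(f"level mismatch: map at {level!r}, fc at {fc_table.level!r}")
    view = fmap.by_function[level]
    graph = nx.DiGraph(
        level=level, mean_mode=mean_mode, bin_edges=",".join(f"{e:g}" for e in binning.edges)
    )
    hit_pm_keys: set[str] = set()
    edge_evalues: dict[tuple[str, str], list[float]] = {}
    for sm_key in view:
        for pm_key, evalue in view[sm_key]:
            hit_pm_keys.add(pm_key)
            if pm_key != sm_key:
                edge_evalues.setdefault((pm_key, sm_key), []).append(evalue)
    present = set(pm_keys) if pm_keys is not None else hit_pm_keys

    nodes = sorted(set(view) | {p for p, _ in edge_evalues})
    for key in nodes:
        attrs = {"present_in_pm": key in present}
        if key in fc_table.entries:
            fc, n_hits = fc_table.entries[key]
            attrs.update(fc=float(fc), n_hits=int(n_hits))
        else:
            attrs.update(n_hits=0)  # pure source: never an SM query key
        graph.add_node(key, **attrs)
    for (pm_key, sm_key) in sorted(edge_evalues):
        evs = edge_evalues[(pm_key, sm_key)]
        mean_ev = _mean_evalue(evs, mean_mode)
        graph.add_edge(
            pm_key,
            sm_key,
            weight=len(evs),
            mean_evalue=float(mean_ev),
            bin=binning.label(mean_ev),
        )
    return graph


def export_graph(graph: nx.DiGraph, path, format: str = "graphml") -> None:
    """Write the graph as ``graphml``, ``sif``, or ``edge-tsv``.

    GraphML round-trips all node and edge attributes; SIF carries topology
    only (interaction type ``changes_to``, isolated nodes as bare lines);
    edge-TSV carries all edge attributes, one row per edge.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "sif":
        lines = []
        connected = set()
        for u, v in sorted(graph.edges):
            lines.append(f"{u}\tchanges_to\t{v}")
            connected.update((u, v))
        for node in sorted(graph.nodes):
            if node not in connected:
                lines.append(str(node))
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "edge-tsv":
        lines = ["source\ttarget\tweight\tmean_evalue\tbin"]
        for u, v in sorted(graph.edges):
            data = graph.edges[u, v]
            lines.append(
                f"{u}\t{v}\t{data['weight']}\t{data['mean_evalue']:.6g}\t{data['bin']}"
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
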