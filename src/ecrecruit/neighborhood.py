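"""Genomic-neighborhood extraction, P/S labeling, and per-BGC HTML reports.

A putative primary-metabolism homolog (put_PM) of a BGC enzyme is judged by
its genomic context: in bacteria more than half of all genes sit in operons
whose products serve the same pathway, so the +/-10 gene window around a
put_PM (with the +/-2 window approximating a typical operon) is an informative
proxy for its metabolic role. Each neighbor gene is labeled

* ``P`` if at least one of its complete EC numbers occurs in the reference
  primary-metabolism function set, and
* ``S`` if its EC annotation is mapped to the species' secondary-metabolite
  biosynthesis pathway (the mapping may contain wildcarded EC entries and is
  matched on the rendered EC string).

Pathway memberships of the window are tallied as ``n_outer/n_inner pathway``
rows, and everything is assembled into one deterministic HTML page per BGC,
mirroring the layout "BGC; SM query <-> hit; E-value" followed by the labeled
neighborhood table and the pathway summary.

Windows are gene-order based (ordinals, not base pairs); replicons are linear
by default with truncation at the ends, with an optional circular mode.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ec import ECNumber, parse_ec

__all__ = [
    "GeneRecord",
    "NeighborhoodConfig",
    "GeneNeighborhood",
    "ReportEntry",
    "load_genome_table",
    "load_pathway_map",
    "extract_neighborhood",
    "assign_labels",
    "summarize_labels",
    "summarize_pathways",
    "render_report",
]

GENOME_COLUMNS = ("replicon_id", "ordinal", "gene_id", "strand", "product", "ec", "pathways")


@dataclass(frozen=True)
class GeneRecord:
    replicon_id: str
    ordinal: int
    gene_id: str
    strand: str = "+"
    product: str = ""
    ec_list: tuple[ECNumber, ...] = ()
    pathway_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class NeighborhoodConfig:
    k_outer: int = 10
    k_inner: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.k_inner <= self.k_outer):
            raise ValueError("need 0 < k_inner <= k_outer")


@dataclass
class GeneNeighborhood:
    """Ordered window of genes around an anchor, with per-gene offset and labels."""

    anchor: str
    genes: list[GeneRecord]
    offsets: list[int]
    labels: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anchor not in {g.gene_id for g in self.genes}:
            raise ValueError(f"anchor {self.anchor!r} missing from its own neighborhood")
        if len(self.genes) != len(self.offsets):
            raise ValueError("genes and offsets length mismatch")

    @property
    def anchor_record(self) -> GeneRecord:
        return next(g for g in self.genes if g.gene_id == self.anchor)


def load_genome_table(path, max_class: int = 6, strip_preliminary: bool = False) -> list[GeneRecord]:
    """Load a genome gene-order TSV.

    Columns: replicon_id, ordinal, gene_id, strand, product, ec (``;``-separated,
    may be empty or wildcarded), pathways (``;``-separated). Ordinals must be
    strictly increasing within each replicon.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in GENOME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    genes = []
    last_ordinal: dict[str, int] = {}
    for row in df.itertuples(index=False):
        ordinal = int(row.ordinal)
        prev = last_ordinal.get(row.replicon_id)
        if prev is not None and ordinal <= prev:
            raise ValueError(
                f"{path}: gene {row.gene_id!r}: ordinal {ordinal} not increasing on {row.replicon_id!r}"
            )
        last_ordinal[row.replicon_id] = ordinal
        ec_list = tuple(
            parse_ec(part.strip(), max_class=max_class, strip_preliminary=strip_preliminary)
            for part in str(row.ec).split(";")
            if part.strip()
        )
        pathways = frozenset(p.strip() for p in str(row.pathways).split(";") if p.strip())
        genes.append(
            GeneRecord(
                replicon_id=row.replicon_id,
                ordinal=ordinal,
                gene_id=row.gene_id,
                strand=row.strand,
                product=row.product,
                ec_list=ec_list,
                pathway_ids=pathways,
            )
        )
    return genes


def load_pathway_map(path) -> dict[str, str]:
    """Load a pathway map TSV (pathway_id, pathway_name) into a dict."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("pathway_id", "pathway_name"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return dict(zip(df["pathway_id"], df["pathway_name"]))


def extract_neighborhood(
    genome: Sequence[GeneRecord], anchor_id: str, k: int = 10, circular: bool = False
) -> GeneNeighborhood:
    """Genes within *k* gene-order positions of the anchor on its replicon.

    Linear replicons truncate at their ends; with ``circular=True`` the window
    wraps around (but never exceeds the replicon or 2k+1 genes). The anchor is
    always included.
    """
    anchor = next((g for g in genome if g.gene_id == anchor_id), None)
    if anchor is None:
        raise ValueError(f"anchor {anchor_id!r} not found in genome")
    replicon = sorted(
        (g for g in genome if g.replicon_id == anchor.replicon_id), key=lambda g: g.ordinal
    )
    idx = next(i for i, g in enumerate(replicon) if g.gene_id == anchor_id)
    n = len(replicon)
    if circular and n > 2 * k + 1:
        offsets = range(-k, k + 1)
        genes = [replicon[(idx + off) % n] for off in offsets]
        return GeneNeighborhood(anchor=anchor_id, genes=genes, offsets=list(offsets))
    lo = max(0, idx - k) if not circular else 0
    hi = min(n, idx + k + 1) if not circular else n
    genes = replicon[lo:hi]
    offsets = [i - idx for i in range(lo, hi)]
    return GeneNeighborhood(anchor=anchor_id, genes=genes, offsets=offsets)


def assign_labels(
    nh: GeneNeighborhood,
    pm_function_keys: Iterable[str],
    sm_function_keys: Iterable[str],
) -> GeneNeighborhood:
    """Label each gene with P and/or S against the reference function sets.

    ``P`` requires a *complete* EC whose full key is in *pm_function_keys*;
    ``S`` matches any of the gene's EC renderings (wildcards included) against
    *sm_function_keys*, which therefore may carry wildcarded entries. Genes
    without a qualifying EC get no label. Pure per-gene function; gene order
    is irrelevant.
    """
    pm_keys = set(pm_function_keys)
    sm_keys = set(sm_function_keys)
    labels: dict[str, frozenset[str]] = {}
    for gene in nh.genes:
        flags = set()
        for ec in gene.ec_list:
            if ec.is_complete_at("full") and ec.key("full") in pm_keys:
                flags.add("P")
            if str(ec) in sm_keys:
                flags.add("S")
        labels[gene.gene_id] = frozenset(flags)
    return GeneNeighborhood(
        anchor=nh.anchor, genes=list(nh.genes), offsets=list(nh.offsets), labels=labels
    )


def summarize_labels(nh: GeneNeighborhood) -> tuple[int, int]:
    """Counts of genes carrying P and carrying S (anchor included)."""
    n_p = sum(1 for g in nh.genes if "P" in nh.labels.get(g.gene_id, frozenset()))
    n_s = sum(1 for g in nh.genes if "S" in nh.labels.get(g.gene_id, frozenset()))
    return n_p, n_s


def summarize_pathways(
    nh: GeneNeighborhood, config: NeighborhoodConfig = NeighborhoodConfig()
) -> list[tuple[int, int, str]]:
    """Pathway tallies ``(n_outer, n_inner, pathway_id)`` over the window.

    ``n_outer`` counts window genes annotated with the pathway; ``n_inner``
    those within ``k_inner`` of the anchor. Rows sorted by (n_outer desc,
    pathway_id). The neighborhood must have been extracted with
    ``k = k_outer``.
    """
    counts: dict[str, list[int]] = {}
    for gene, offset in zip(nh.genes, nh.offsets):
        for pw in gene.pathway_ids:
            outer_inner = counts.setdefault(pw, [0, 0])
            outer_inner[0] += 1
            if abs(offset) <= config.k_inner:
                outer_inner[1] += 1
    rows = [(v[0], v[1], pw) for pw, v in counts.items()]
    rows.sort(key=lambda r: (-r[0], r[2]))
    return rows


@dataclass(frozen=True)
class ReportEntry:
    """One SM-enzyme/homolog pair with its labeled neighborhood and pathway rows."""

    sm_annotation: str
    homolog_annotation: str
    evalue: float
    neighborhood: GeneNeighborhood
    pathway_rows: tuple[tuple[int, int, str], ...] = ()


def _format_gene_annotation(gene: GeneRecord) -> str:
    parts = [gene.gene_id]
    if gene.product:
        parts.append(gene.product)
    if gene.ec_list:
        parts.append("(EC " + "; ".join(str(ec) for ec in gene.ec_list) + ")")
    return " ".join(parts)


def render_report(
    bgc_id: str,
    entries: Sequence[ReportEntry],
    link_template: str = "https://www.genome.jp/dbget-bin/www_bget?{gene_id}",
    pathway_names: Optional[dict[str, str]] = None,
) -> str:
    """Render one BGC page as deterministic HTML (no timestamps, stable order).

    Each gene row links out through *link_template*, which must contain the
    ``{gene_id}`` placeholder. An empty entry list produces a valid page
    stating that no homologs were found.
    """
    if "{gene_id}" not in link_template:
        raise ValueError("link_template must contain the '{gene_id}' placeholder")
    pathway_names = pathway_names or {}
    esc = html.escape
    out = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>{esc(bgc_id)}</title></head><body>",
        f"<h1>{esc(bgc_id)}</h1>",
    ]
    if not entries:
        out.append("<p>No homologs found for this cluster.</p>")
    for entry in entries:
        header = (
            f"{esc(bgc_id)}; SM* {esc(entry.sm_annotation)} &harr; "
            f"{esc(entry.homolog_annotation)}; E-value {entry.evalue:.1E}"
        )
        out.append(f"<h2>{header}</h2>")
        out.append("<table border='1'>")
        out.append("<tr><th>E_PM</th><th>K_SM</th><th>Annotation</th></tr>")
        nh = entry.neighborhood
        for gene in nh.genes:
            flags = nh.labels.get(gene.gene_id, frozenset())
            link = link_template.format(gene_id=gene.gene_id)
            anchor_mark = " <b>(anchor)</b>" if gene.gene_id == nh.anchor else ""
            out.append(
                "<tr>"
                f"<td>{'P' if 'P' in flags else ''}</td>"
                f"<td>{'S' if 'S' in flags else ''}</td>"
                f"<td><a href='{esc(link, quote=True)}'>{esc(_format_gene_annotation(gene))}</a>"
                f"{anchor_mark}</td>"
                "</tr>"
            )
        out.append("</table>")
        if entry.pathway_rows:
            out.append("<h3>Pathways in &plusmn;10/&plusmn;2 neighborhood</h3><ul>")
            for n_outer, n_inner, pw in entry.pathway_rows:
                name = pathway_names.get(pw, "")
                label = f"{pw} {name}".strip()
                out.append(f"<li>{n_outer}/{n_inner} {esc(label)}</li>")
            out.append("</ul>")
    out.append("</body></html>")
    return "\n".join(out) + "\n"
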