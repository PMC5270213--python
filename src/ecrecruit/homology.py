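"""Homology hit-table parsing and filtering.

Homology between an SM query and a PM subject is accepted from a precomputed
BLAST-style hit (the package never runs an aligner) when the E-value passes a
stringent cutoff (default 1e-20; 1e-10 serves as a relaxed control) and the
subject length deviates from the query length by at most 30% — the length rule
suppresses false positives arising from a single shared domain in multi-domain
enzymes. Filtered record-level hits are pooled per enzyme function into a
:class:`FunctionHitMap`: at each EC grouping level, every SM function key maps
to the multiset of (PM function key, E-value) pairs supplied by its records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .catalog import EnzymeCatalog
from .ec import LEVELS

__all__ = [
    "HitFilterConfig",
    "HomologyHit",
    "FunctionHitMap",
    "HitTableError",
    "STD12_COLUMNS",
    "parse_hit_table",
    "filter_hits",
    "build_function_hit_map",
    "write_rejection_log",
]

STD12_COLUMNS = (
    "query_id",
    "subject_id",
    "pident",
    "aln_len",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


class HitTableError(ValueError):
    """Raised for malformed hit tables, with offending line numbers."""


@dataclass(frozen=True)
class HitFilterConfig:
    """E-value and length filters applied to raw hits.

    ``evalue_cutoff`` is inclusive (a hit at exactly the cutoff is kept);
    ``length_tolerance`` is the maximum allowed |L_subject - L_query| / L_query,
    also inclusive at the boundary.
    """

    evalue_cutoff: float = 1e-20
    length_tolerance: float = 0.30
    remove_self_hits: bool = True

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if not (0 <= self.length_tolerance < 1):
            raise ValueError("length_tolerance must be in [0, 1)")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    pident: Optional[float] = None
    aln_len: Optional[int] = None
    qstart: Optional[int] = None
    qend: Optional[int] = None
    sstart: Optional[int] = None
    send: Optional[int] = None
    qlen: Optional[int] = None
    slen: Optional[int] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise HitTableError(f"negative evalue {self.evalue} for {self.query_id}->{self.subject_id}")


def parse_hit_table(path, dialect: str = "std12") -> list[HomologyHit]:
    """Parse a BLAST tabular (outfmt-6-style) TSV.

    ``dialect="std12"`` expects the standard 12 columns; ``"std12+lens"``
    expects two extra trailing columns ``qlen`` and ``slen``. Malformed rows
    are rejected with their line numbers.
    """
    if dialect == "std12":
        columns = STD12_COLUMNS
    elif dialect == "std12+lens":
        columns = STD12_COLUMNS + ("qlen", "slen")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw_lines = Path(path).read_text().splitlines()
    hits = []
    for lineno, line in enumerate(raw_lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise HitTableError(
                f"{path}: line {lineno}: expected {len(columns)} columns, got {len(fields)}"
            )
        row = dict(zip(columns, fields))
        try:
            hit = HomologyHit(
                query_id=row["query_id"],
                subject_id=row["subject_id"],
                pident=float(row["pident"]),
                aln_len=int(row["aln_len"]),
                qstart=int(row["qstart"]),
                qend=int(row["qend"]),
                sstart=int(row["sstart"]),
                send=int(row["send"]),
                evalue=float(row["evalue"]),
                bitscore=float(row["bitscore"]),
                qlen=int(row["qlen"]) if "qlen" in row else None,
                slen=int(row["slen"]) if "slen" in row else None,
            )
        except (ValueError, HitTableError) as exc:
            raise HitTableError(f"{path}: line {lineno}: {exc}") from None
        hits.append(hit)
    return hits


def _collapse_best(hits: Sequence[HomologyHit]) -> list[HomologyHit]:
    """Collapse multi-HSP rows: keep the minimum-E-value hit per (query, subject).

    Ties broken by higher bitscore so the result is order-independent.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for hit in hits:
        key = (hit.query_id, hit.subject_id)
        cur = best.get(key)
        if cur is None or (hit.evalue, -hit.bitscore) < (cur.evalue, -cur.bitscore):
            best[key] = hit
    return [best[k] for k in sorted(best)]


def filter_hits(
    hits: Sequence[HomologyHit],
    config: HitFilterConfig = HitFilterConfig(),
    query_catalog: Optional[EnzymeCatalog] = None,
    subject_catalog: Optional[EnzymeCatalog] = None,
) -> tuple[list[HomologyHit], list[tuple[HomologyHit, str]]]:
    """Apply self-hit, E-value, and length filters.

    Lengths come from the hit rows themselves (``std12+lens`` dialect) or are
    resolved through the catalogs. Returns (kept hits, rejection log of
    (hit, reason)); kept hits are sorted by (query_id, subject_id).
    """
    q_lengths = query_catalog.lengths() if query_catalog is not None else {}
    s_lengths = subject_catalog.lengths() if subject_catalog is not None else {}
    kept: list[HomologyHit] = []
    rejected: list[tuple[HomologyHit, str]] = []
    for hit in _collapse_best(hits):
        if config.remove_self_hits and hit.query_id == hit.subject_id:
            rejected.append((hit, "self_hit"))
            continue
        if hit.evalue > config.evalue_cutoff:
            rejected.append((hit, f"evalue {hit.evalue:g} > {config.evalue_cutoff:g}"))
            continue
        lq = hit.qlen if hit.qlen is not None else q_lengths.get(hit.query_id)
        ls = hit.slen if hit.slen is not None else s_lengths.get(hit.subject_id)
        if lq is None:
            raise HitTableError(f"cannot resolve query length for {hit.query_id!r}")
        if ls is None:
            raise HitTableError(f"cannot resolve subject length for {hit.subject_id!r}")
        deviation = abs(ls - lq) / lq
        if deviation > config.length_tolerance:
            rejected.append((hit, f"length deviation {deviation:.4f} > {config.length_tolerance}"))
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.query_id, h.subject_id))
    return kept, rejected


@dataclass
class FunctionHitMap:
    """Filtered homology evidence pooled per enzyme function.

    ``by_record`` maps each query gene to its kept (subject gene, E-value)
    pairs. ``by_function[level]`` maps each SM function key to the multiset of
    (PM function key, E-value) pairs pooled over all query records bearing
    that function; queries or subjects incomplete at a level are omitted from
    that level's view.
    """

    by_record: dict[str, list[tuple[str, float]]]
    by_function: dict[str, dict[str, list[tuple[str, float]]]]
    config: HitFilterConfig = field(default_factory=HitFilterConfig)

    def levels(self) -> tuple[str, ...]:
        return tuple(self.by_function)

    def n_hits(self, level: str) -> int:
        return sum(len(v) for v in self.by_function[level].values())


def build_function_hit_map(
    hits: Sequence[HomologyHit],
    query_catalog: EnzymeCatalog,
    subject_catalog: EnzymeCatalog,
    config: HitFilterConfig = HitFilterConfig(),
) -> FunctionHitMap:
    """Pool filtered hits into per-function views at every grouping level.

    Both catalogs must already be inclusion-filtered (one EC per record).
    *hits* are taken as already filtered; apply :func:`filter_hits` first.
    """
    q_by_gene = query_catalog.by_gene()
    s_by_gene = subject_catalog.by_gene()
    by_record: dict[str, list[tuple[str, float]]] = {}
    by_function: dict[str, dict[str, list[tuple[str, float]]]] = {lvl: {} for lvl in LEVELS}
    for hit in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
        q = q_by_gene.get(hit.query_id)
        s = s_by_gene.get(hit.subject_id)
        if q is None:
            raise HitTableError(f"query {hit.query_id!r} not in query catalog")
        if s is None:
            raise HitTableError(f"subject {hit.subject_id!r} not in subject catalog")
        by_record.setdefault(hit.query_id, []).append((hit.subject_id, hit.evalue))
        for level in LEVELS:
            if q.ec.is_complete_at(level) and s.ec.is_complete_at(level):
                sm_key = q.ec.key(level)
                pm_key = s.ec.key(level)
                by_function[level].setdefault(sm_key, []).append((pm_key, hit.evalue))
    return FunctionHitMap(by_record=by_record, by_function=by_function, config=config)


def write_rejection_log(rejected: Sequence[tuple[HomologyHit, str]], path) -> None:
    """Export the per-hit rejection reasons as TSV (query, subject, reason)."""
    lines = ["query_id\tsubject_id\treason"]
    for hit, reason in rejected:
        lines.append(f"{hit.query_id}\t{hit.subject_id}\t{reason}")
    Path(path).write_text("\n".join(lines) + "\n")
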