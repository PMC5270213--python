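"""Functional-flexibility classification of recruited enzymes.

Each SM function with at least one accepted PM homolog is classified by the
functional makeup of its hits at a chosen EC grouping level:

* ``ALL_SAME`` — every PM hit shares the SM function's key (a monofunctional
  family: the recruited enzyme kept its chemistry);
* ``MIXED`` — some hits share the key and some do not (a multifunctional
  family);
* ``ALL_DIFF`` — no hit shares the key (the function most likely changed after
  recruitment).

The three categories partition the classified keys. The hit-weighted rate of
functional conservation ``fc(g) = (# hits whose PM key equals g) / (# hits to
SM queries in g)`` summarizes each group; fc < 1 marks groups whose homologs
catalyze different reactions in primary metabolism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

from .homology import FunctionHitMap

__all__ = [
    "Category",
    "FunctionClassification",
    "ClassificationSummary",
    "FcTable",
    "classify_functions",
    "summarize_classification",
    "functional_conservation",
    "recruitment_fraction",
    "hits_counts_table",
    "write_classifications",
    "write_fc_table",
    "write_summary_json",
]


class Category(str, Enum):
    ALL_SAME = "ALL_SAME"
    MIXED = "MIXED"
    ALL_DIFF = "ALL_DIFF"


@dataclass(frozen=True)
class FunctionClassification:
    key: str
    level: str
    category: Category
    n_hits: int
    n_same: int

    def __post_init__(self) -> None:
        if self.n_hits < 1 or not (0 <= self.n_same <= self.n_hits):
            raise ValueError(f"invalid counts n_same={self.n_same}, n_hits={self.n_hits}")
        expected = (
            Category.ALL_SAME
            if self.n_same == self.n_hits
            else Category.ALL_DIFF
            if self.n_same == 0
            else Category.MIXED
        )
        if self.category != expected:
            raise ValueError(f"category {self.category} inconsistent with counts")


@dataclass(frozen=True)
class ClassificationSummary:
    """Counts and percent fractions per category.

    ``n_keys`` is the denominator of the fractions: by default the number of
    classified keys (fractions then sum to 100), but it may be the size of a
    larger reference set — e.g. all SM subdivisions, including those without
    any PM homolog — in which case the fractions sum to less than 100 and the
    remainder is the unclassified share.
    """

    level: str
    counts: dict
    fractions: dict
    n_classified: int
    n_keys: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_classified:
            raise ValueError("counts do not sum to n_classified")
        if self.n_classified > self.n_keys:
            raise ValueError("more classified keys than the fraction denominator")


@dataclass
class FcTable:
    """Per-group functional-conservation rates: key -> (fc in [0, 1], n_hits)."""

    level: str
    entries: dict[str, tuple[float, int]]


def classify_functions(fmap: FunctionHitMap, level: str) -> list[FunctionClassification]:
    """One classification per SM key with >= 1 hit at *level*."""
    view = fmap.by_function[level]
    out = []
    for sm_key in sorted(view):
        hits = view[sm_key]
        n_same = sum(1 for pm_key, _ in hits if pm_key == sm_key)
        n_hits = len(hits)
        category = (
            Category.ALL_SAME
            if n_same == n_hits
            else Category.ALL_DIFF
            if n_same == 0
            else Category.MIXED
        )
        out.append(
            FunctionClassification(
                key=sm_key, level=level, category=category, n_hits=n_hits, n_same=n_same
            )
        )
    return out


def summarize_classification(classifications, n_total: Optional[int] = None) -> ClassificationSummary:
    """Counts and percent fractions per category.

    *n_total* overrides the fraction denominator; use it to express the
    fractions relative to a larger key universe (e.g. every SM subdivision,
    classified or not). Defaults to the number of classifications.
    """
    classifications = list(classifications)
    if not classifications:
        raise ValueError("no classifications to summarize")
    level = classifications[0].level
    counts = {cat: 0 for cat in Category}
    for c in classifications:
        counts[c.category] += 1
    n_classified = len(classifications)
    n = n_total if n_total is not None else n_classified
    fractions = {cat: 100.0 * counts[cat] / n for cat in Category}
    return ClassificationSummary(
        level=level, counts=counts, fractions=fractions, n_classified=n_classified, n_keys=n
    )


def functional_conservation(fmap: FunctionHitMap, level: str, weighting: str = "hits") -> FcTable:
    """Rate of functional conservation per group key at *level*.

    With the canonical ``weighting="hits"``, fc(g) is the fraction of all PM
    hits pooled under SM key g whose PM key equals g. ``weighting="keys"``
    instead averages each SM key's own same-fraction (here the grouping and
    classification levels coincide, so the two agree per key; the option
    matters when fc values are aggregated downstream).
    """
    if weighting not in ("hits", "keys"):
        raise ValueError(f"unknown weighting {weighting!r}")
    view = fmap.by_function[level]
    entries: dict[str, tuple[float, int]] = {}
    for key in sorted(view):
        hits = view[key]
        if not hits:
            continue
        n_same = sum(1 for pm_key, _ in hits if pm_key == key)
        entries[key] = (n_same / len(hits), len(hits))
    return FcTable(level=level, entries=entries)


def recruitment_fraction(n_shared: int, n_total_sm: int) -> float:
    """Percent of SM functions that possess at least one PM homolog."""
    if n_total_sm <= 0:
        raise ValueError("n_total_sm must be > 0")
    if not (0 <= n_shared <= n_total_sm):
        raise ValueError("need 0 <= n_shared <= n_total_sm")
    return 100.0 * n_shared / n_total_sm


def hits_counts_table(fmap: FunctionHitMap, level: str):
    """Per-key hit counts (TOT, SAME, DIFF) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for c in classify_functions(fmap, level):
        rows.append(
            {"key": c.key, "TOT": c.n_hits, "SAME": c.n_same, "DIFF": c.n_hits - c.n_same}
        )
    return pd.DataFrame(rows, columns=["key", "TOT", "SAME", "DIFF"])


def write_classifications(classifications, path) -> None:
    lines = ["key\tlevel\tcategory\tn_hits\tn_same"]
    for c in classifications:
        lines.append(f"{c.key}\t{c.level}\t{c.category.value}\t{c.n_hits}\t{c.n_same}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fc_table(table: FcTable, path) -> None:
    lines = ["key\tfc\tn_hits"]
    for key in sorted(table.entries):
        fc, n = table.entries[key]
        lines.append(f"{key}\t{fc:.6g}\t{n}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_summary_json(summary: ClassificationSummary, path, config_echo: dict | None = None) -> None:
    payload = {
        "level": summary.level,
        "n_classified": summary.n_classified,
        "n_keys": summary.n_keys,
        "counts": {cat.value: summary.counts[cat] for cat in Category},
        "fractions_percent": {cat.value: summary.fractions[cat] for cat in Category},
    }
    if config_echo is not None:
        payload["config"] = config_echo
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
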