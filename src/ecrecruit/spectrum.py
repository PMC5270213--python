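"""EC-frequency spectra and overrepresentation statistics.

The enzymatic spectrum of a catalog is the normalized frequency (in percent)
with which each EC grouping key occurs among its records. Comparing the SM
spectrum against the PM spectrum per key gives the overrepresentation ratio
``overrep(k) = f_SM(k) / f_PM(k)``; keys strongly overrepresented in SM flag
reaction chemistries specific to secondary metabolism.

Records whose EC is wildcarded above the requested level are dropped from that
level's denominator rather than imputed; frequencies are carried at full
precision and rounded only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .catalog import EnzymeCatalog
from .ec import IncompleteAtLevel, LEVELS

__all__ = [
    "FrequencyTable",
    "OverrepTable",
    "ec_frequencies",
    "overrep_ratios",
    "shared_exclusive_functions",
    "frequency_correlation",
    "write_frequency_table",
    "write_overrep_table",
]


@dataclass
class FrequencyTable:
    """Normalized key frequencies in percent; non-empty tables sum to 100."""

    level: str
    entries: dict[str, float]
    n_records_used: int

    def __post_init__(self) -> None:
        if self.entries:
            total = sum(self.entries.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError(f"frequencies sum to {total}, expected 100")
            if any(v < 0 for v in self.entries.values()):
                raise ValueError("negative frequency")


@dataclass
class OverrepTable:
    """Per-key SM/PM frequency ratios.

    Keys with zero PM frequency but positive SM frequency cannot form a ratio
    and are listed in ``absent_in_pm``; keys absent from SM get ratio 0.
    """

    level: str
    entries: dict[str, float]
    absent_in_pm: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.entries) & self.absent_in_pm
        if overlap:
            raise ValueError(f"keys both rated and absent_in_pm: {sorted(overlap)}")


def ec_frequencies(
    catalog: EnzymeCatalog, level: str, weight: str = "records"
) -> FrequencyTable:
    """Normalized frequency spectrum of *catalog* at *level*.

    With the default ``weight="records"`` every record complete at the level
    contributes one count to its key (the abundance reading); with
    ``weight="distinct"`` each distinct full EC number contributes once,
    for sensitivity analysis.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if weight not in ("records", "distinct"):
        raise ValueError(f"unknown weighting {weight!r}")
    counts: dict[str, int] = {}
    if weight == "records":
        units = [rec.ec for rec in catalog.records]
    else:
        units = sorted({rec.ec for rec in catalog.records}, key=str)
    n_used = 0
    for ec in units:
        if not ec.is_complete_at(level):
            continue
        key = ec.key(level)
        counts[key] = counts.get(key, 0) + 1
        n_used += 1
    entries = {k: 100.0 * c / n_used for k, c in sorted(counts.items())} if n_used else {}
    return FrequencyTable(level=level, entries=entries, n_records_used=n_used)


def overrep_ratios(sm_freq: FrequencyTable, pm_freq: FrequencyTable) -> OverrepTable:
    """Per-key ratio f_SM / f_PM over the union of keys."""
    if sm_freq.level != pm_freq.level:
        raise ValueError(f"level mismatch: {sm_freq.level!r} vs {pm_freq.level!r}")
    entries: dict[str, float] = {}
    absent: set[str] = set()
    for key in sorted(set(sm_freq.entries) | set(pm_freq.entries)):
        f_sm = sm_freq.entries.get(key, 0.0)
        f_pm = pm_freq.entries.get(key, 0.0)
        if f_pm > 0:
            entries[key] = f_sm / f_pm
        elif f_sm > 0:
            absent.add(key)
    return OverrepTable(level=sm_freq.level, entries=entries, absent_in_pm=absent)


def shared_exclusive_functions(
    sm_catalog: EnzymeCatalog, pm_catalog: EnzymeCatalog, level: str
) -> tuple[set[str], set[str], set[str]]:
    """Partition the union of keys into (shared, sm_only, pm_only)."""
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    sm_keys = {r.ec.key(level) for r in sm_catalog.records if r.ec.is_complete_at(level)}
    pm_keys = {r.ec.key(level) for r in pm_catalog.records if r.ec.is_complete_at(level)}
    return sm_keys & pm_keys, sm_keys - pm_keys, pm_keys - sm_keys


def frequency_correlation(
    a: FrequencyTable, b: FrequencyTable, pairing: str = "union_zero_fill"
) -> float:
    """Squared Pearson correlation of two frequency tables.

    ``pairing="union_zero_fill"`` pairs over the union of keys, filling absent
    keys with 0 (keys private to one side count as disagreement);
    ``"intersection"`` pairs only keys present in both tables.
    """
    if a.level != b.level:
        raise ValueError(f"level mismatch: {a.level!r} vs {b.level!r}")
    if pairing == "union_zero_fill":
        keys = sorted(set(a.entries) | set(b.entries))
    elif pairing == "intersection":
        keys = sorted(set(a.entries) & set(b.entries))
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    if len(keys) < 3:
        raise ValueError(f"need >= 3 paired keys, got {len(keys)}")
    x = np.array([a.entries.get(k, 0.0) for k in keys])
    y = np.array([b.entries.get(k, 0.0) for k in keys])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in paired frequencies")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def write_frequency_table(table: FrequencyTable, path) -> None:
    """Export as TSV (key, frequency_percent, n_records_used), sorted by key."""
    lines = ["key\tfrequency_percent\tn_records_used"]
    for key in sorted(table.entries):
        lines.append(f"{key}\t{table.entries[key]:.6g}\t{table.n_records_used}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_overrep_table(table: OverrepTable, path, flag_threshold: float = 20.0) -> None:
    """Export as TSV with a flag column marking ratios above *flag_threshold*.

    Keys absent from the PM side appear with ratio ``inf`` and the flag set.
    """
    lines = ["key\tratio\tflagged"]
    for key in sorted(set(table.entries) | table.absent_in_pm):
        if key in table.absent_in_pm:
            lines.append(f"{key}\tinf\t1")
        else:
            ratio = table.entries[key]
            lines.append(f"{key}\t{ratio:.6g}\t{int(ratio > flag_threshold)}")
    Path(path).write_text("\n".join(lines) + "\n")
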