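"""Enzyme catalog ingestion and inclusion filtering.

A catalog is a role-tagged table of enzyme records — the primary-metabolism
(PM) side groups records by genome, the secondary-metabolism (SM) side by
biosynthetic gene cluster (BGC). Inclusion follows two rules: a record must
carry an EC number, and records annotated with more than one EC number are
eliminated (their function is ambiguous). A :class:`FilterLog` accounts for
every input record so the audit numbers are reportable.

Catalog files are UTF-8 TSV with header
``gene_id  collection_id  species_tax  ec  length  product``; the ``ec`` field
may hold several ``;``-separated EC numbers or be empty. ``#``-prefixed lines
are comments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ec import ECNumber, ECParseError, parse_ec

__all__ = [
    "EnzymeRecord",
    "EnzymeCatalog",
    "FilterLog",
    "CatalogError",
    "CATALOG_COLUMNS",
    "load_catalog",
    "apply_inclusion_filters",
    "leave_one_out",
    "check_fasta_lengths",
]

CATALOG_COLUMNS = ("gene_id", "collection_id", "species_tax", "ec", "length", "product")


class CatalogError(ValueError):
    """Raised for structurally invalid catalog files or queries."""


@dataclass(frozen=True)
class EnzymeRecord:
    gene_id: str
    collection_id: str
    species_tax: str
    ec_list: tuple[ECNumber, ...]
    length: int
    product: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise CatalogError(f"record {self.gene_id!r}: length must be > 0, got {self.length}")

    @property
    def ec(self) -> ECNumber:
        """The record's single EC number; only valid after inclusion filtering."""
        if len(self.ec_list) != 1:
            raise CatalogError(
                f"record {self.gene_id!r} has {len(self.ec_list)} EC numbers; apply inclusion filters first"
            )
        return self.ec_list[0]


@dataclass
class EnzymeCatalog:
    """A role-tagged set of enzyme records grouped into collections."""

    role: str  # "PM" or "SM"
    records: tuple[EnzymeRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("PM", "SM"):
            raise CatalogError(f"role must be 'PM' or 'SM', got {self.role!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise CatalogError(f"duplicate gene_id {rec.gene_id!r} in catalog")
            seen.add(rec.gene_id)

    @property
    def collections(self) -> set[str]:
        return {rec.collection_id for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_gene(self) -> dict[str, EnzymeRecord]:
        return {rec.gene_id: rec for rec in self.records}

    def lengths(self) -> dict[str, int]:
        return {rec.gene_id: rec.length for rec in self.records}


@dataclass(frozen=True)
class FilterLog:
    n_input: int
    n_removed_no_ec: int
    n_removed_multi_ec: int
    n_kept: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_no_ec + self.n_removed_multi_ec + self.n_kept:
            raise ValueError("FilterLog does not account for every input record")


def _parse_ec_field(text, gene_id: str, **parse_kwargs) -> tuple[ECNumber, ...]:
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return ()
    text = str(text).strip()
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            out.append(parse_ec(part, **parse_kwargs))
        except ECParseError as exc:
            raise CatalogError(f"record {gene_id!r}: {exc}") from exc
    return tuple(out)


def load_catalog(
    path,
    role: str,
    max_class: int = 6,
    strip_preliminary: bool = False,
) -> EnzymeCatalog:
    """Load a catalog TSV; see module docstring for the format."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing column(s) {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise CatalogError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    records = []
    for row in df.itertuples(index=False):
        try:
            length = int(row.length)
        except (TypeError, ValueError):
            raise CatalogError(
                f"{path}: record {row.gene_id!r}: unparseable length {row.length!r}"
            ) from None
        records.append(
            EnzymeRecord(
                gene_id=row.gene_id,
                collection_id=row.collection_id,
                species_tax=row.species_tax,
                ec_list=_parse_ec_field(
                    row.ec, row.gene_id, max_class=max_class, strip_preliminary=strip_preliminary
                ),
                length=length,
                product=row.product,
            )
        )
    return EnzymeCatalog(role=role, records=tuple(records))


def apply_inclusion_filters(catalog: EnzymeCatalog) -> tuple[EnzymeCatalog, FilterLog]:
    """Keep records with exactly one EC number.

    Records without an EC are removed (their function is unknown) and records
    with more than one EC are removed as well (their function is ambiguous).
    Idempotent; the log accounts for every input record.
    """
    kept, no_ec, multi_ec = [], 0, 0
    for rec in catalog.records:
        n = len(rec.ec_list)
        if n == 0:
            no_ec += 1
        elif n > 1:
            multi_ec += 1
        else:
            kept.append(rec)
    log = FilterLog(
        n_input=len(catalog.records),
        n_removed_no_ec=no_ec,
        n_removed_multi_ec=multi_ec,
        n_kept=len(kept),
    )
    return EnzymeCatalog(role=catalog.role, records=tuple(kept)), log


def leave_one_out(
    catalog: EnzymeCatalog, held_out: str
) -> tuple[tuple[EnzymeRecord, ...], tuple[EnzymeRecord, ...]]:
    """Split the catalog into (queries from *held_out*, references from the rest).

    Used for the within-side controls: the enzymes of one genome (or one BGC)
    are compared against the pooled enzymes of all other collections, which
    baselines the functional diversity attainable without crossing the PM/SM
    boundary.
    """
    if held_out not in catalog.collections:
        raise CatalogError(f"unknown collection_id {held_out!r}")
    queries = tuple(r for r in catalog.records if r.collection_id == held_out)
    references = tuple(r for r in catalog.records if r.collection_id != held_out)
    if not references:
        warnings.warn(
            f"collection {held_out!r} is the only collection; reference set is empty",
            stacklevel=2,
        )
    return queries, references


def check_fasta_lengths(catalog: EnzymeCatalog, fasta_path) -> None:
    """Validate an optional companion protein FASTA against catalog lengths.

    Every FASTA record id must name a catalog gene and its sequence length
    must equal the catalog length. Sequences are not otherwise used.
    """
    from Bio import SeqIO

    lengths = catalog.lengths()
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        if seq_rec.id not in lengths:
            raise CatalogError(f"FASTA record {seq_rec.id!r} not present in catalog")
        if len(seq_rec.seq) != lengths[seq_rec.id]:
            raise CatalogError(
                f"FASTA record {seq_rec.id!r}: sequence length {len(seq_rec.seq)} "
                f"!= catalog length {lengths[seq_rec.id]}"
            )
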