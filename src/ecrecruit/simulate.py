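"""Synthetic input bundles with planted ground truth.

The generator emulates the study design end to end without any database
access: a primary-metabolism (PM) side of BGC-free genomes and a
secondary-metabolism (SM) side of biosynthetic gene clusters, both annotated
with EC numbers drawn from configurable per-class profiles (defaulting to the
observed PM/SM class spectra); homolog families whose PM and SM members carry
identical, mixed, or disjoint EC numbers; a BLAST-style hit table whose
in-family E-values sit below the stringent cutoff and whose decoys straddle
the filters (above-cutoff E-values, or passing E-values with out-of-tolerance
lengths); records without an EC or with multiple ECs injected at configured
fractions; and per-genome gene-order tables with operon-like runs of
co-pathway genes, one planted putative-PM anchor per genome, and an embedded
BGC span.

:func:`oracle_expected_outputs` recomputes every downstream quantity from the
planted structure by exhaustive enumeration over plain strings — it shares no
code with the pipeline modules, so pipeline-vs-oracle equality is a real
cross-check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FamilyDesign",
    "SimulationConfig",
    "SyntheticTruth",
    "Bundle",
    "OracleResults",
    "default_family_design",
    "simulate",
    "oracle_expected_outputs",
]

_LEVEL_DEPTH = {"class": 1, "subclass": 2, "subdivision": 3, "full": 4}


@dataclass(frozen=True)
class FamilyDesign:
    """One planted homolog family.

    Every SM member is homologous to every PM member; the intended category
    records what the classification should recover at the full-EC level when
    all planted hits pass the filters.
    """

    family_id: str
    pm_functions: tuple[str, ...]
    sm_functions: tuple[str, ...]
    n_pm_per_function: int = 2
    n_sm_per_function: int = 1
    intended_category: Optional[str] = None


def default_family_design() -> tuple[FamilyDesign, ...]:
    """Twelve families: six monofunctional, four mixed, two fully changed.

    ``fam_ics`` mirrors the isochorismate-synthase story: an SM enzyme
    (EC 5.4.4.2) whose PM homologs are an aminodeoxychorismate synthase
    (EC 2.6.1.85) and an anthranilate synthase (EC 4.1.3.27) — three EC
    classes on one fold. ``fam_mix_adenyl`` mirrors the acid-adenylate pair
    (EC 2.7.7.58 / EC 6.2.1.26).
    """
    return (
        FamilyDesign("fam_ics", ("2.6.1.85", "4.1.3.27"), ("5.4.4.2",), intended_category="ALL_DIFF"),
        FamilyDesign("fam_same_acyl", ("2.3.1.9",), ("2.3.1.9",), intended_category="ALL_SAME"),
        FamilyDesign("fam_same_adh", ("1.1.1.1",), ("1.1.1.1",), intended_category="ALL_SAME"),
        FamilyDesign("fam_same_trps", ("4.2.1.20",), ("4.2.1.20",), intended_category="ALL_SAME"),
        FamilyDesign("fam_same_lig", ("6.3.2.4",), ("6.3.2.4",), intended_category="ALL_SAME"),
        FamilyDesign("fam_same_blac", ("3.5.2.6",), ("3.5.2.6",), intended_category="ALL_SAME"),
        FamilyDesign("fam_same_met", ("2.1.1.14",), ("2.1.1.14",), intended_category="ALL_SAME"),
        FamilyDesign("fam_mix_adcs", ("2.6.1.85", "4.1.3.27"), ("2.6.1.85",), intended_category="MIXED"),
        FamilyDesign("fam_mix_decarb", ("4.1.1.11", "4.1.1.15"), ("4.1.1.11",), intended_category="MIXED"),
        FamilyDesign("fam_mix_oxy", ("1.14.13.7", "1.1.1.2"), ("1.14.13.7",), intended_category="MIXED"),
        FamilyDesign("fam_mix_adenyl", ("2.7.7.58", "6.2.1.26"), ("2.7.7.58",), intended_category="MIXED"),
        FamilyDesign("fam_diff_isom", ("2.7.1.36",), ("5.3.3.2",), intended_category="ALL_DIFF"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_pm_collections: int = 15
    genes_per_collection: int = 60
    n_bgcs: int = 20
    enzymes_per_bgc: int = 6
    #: per-class sampling weights for background functions (classes 1..6)
    ec_class_weights_pm: tuple[float, ...] = (18.71, 35.25, 17.25, 10.70, 6.67, 11.42)
    ec_class_weights_sm: tuple[float, ...] = (22.10, 36.33, 11.64, 17.28, 6.81, 5.84)
    family_design: tuple[FamilyDesign, ...] = field(default_factory=default_family_design)
    #: in-family E-values sit below the stringent cutoff ...
    evalue_range_in_family: tuple[float, float] = (1e-80, 1e-25)
    #: ... decoy E-values straddle the relaxed control cutoff but not 1e-20
    evalue_range_decoy: tuple[float, float] = (1e-15, 1e-5)
    n_decoy_hits: int = 30
    n_length_violation_hits: int = 5
    length_min: int = 200
    length_max: int = 500
    length_jitter: float = 0.10
    operon_lengths: tuple[int, ...] = (3, 4)
    fraction_no_ec: float = 0.05
    fraction_multi_ec: float = 0.05

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.ec_class_weights_pm + self.ec_class_weights_sm):
            raise ValueError("class weights must be >= 0")
        if not (0 <= self.length_jitter < 1):
            raise ValueError("length_jitter must be in [0, 1)")
        lo, hi = self.evalue_range_in_family
        if not (lo < hi <= 1e-20):
            raise ValueError("in-family E-value range must lie at or below the 1e-20 cutoff")
        lo, hi = self.evalue_range_decoy
        if not (1e-20 < lo < hi):
            raise ValueError("decoy E-value range must lie above the 1e-20 cutoff")
        for fam in self.family_design:
            if not fam.pm_functions or not fam.sm_functions:
                raise ValueError(f"family {fam.family_id!r} has an empty function set")


@dataclass
class SyntheticTruth:
    """Planted facts, sufficient for independent recomputation of all outputs."""

    pm_rows: list  # dicts: gene_id, collection_id, ec (";"-joined), length
    sm_rows: list
    hit_rows: list  # dicts: query_id, subject_id, evalue
    genome_rows: list  # dicts: replicon_id, ordinal, gene_id, ec, pathways
    sm_pathway_functions: list  # EC strings mapped to the SM biosynthesis pathway
    gene_family: dict  # gene_id -> family_id for planted genes
    anchors: list  # dicts: genome_id, anchor_gene_id, bgc_id, sm_gene_id, evalue, operon_pathway
    injected: dict  # side -> {"no_ec": n, "multi_ec": n}
    intended_categories: dict  # sm full-EC key -> intended category

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class Bundle:
    paths: dict
    truth: SyntheticTruth
    config: SimulationConfig


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def _random_function(rng: np.random.Generator, weights: Sequence[float]) -> str:
    """A background full EC number; serials >= 100 never collide with designs."""
    w = np.asarray(weights, dtype=float)
    cls = int(rng.choice(np.arange(1, len(w) + 1), p=w / w.sum()))
    return f"{cls}.{rng.integers(1, 9) + 0}.{rng.integers(1, 30) + 0}.{rng.integers(100, 400)}"


def simulate(config: SimulationConfig, outdir) -> Bundle:
    """Generate a bundle of input files plus its ground truth.

    Deterministic given ``config.seed``: the same configuration produces
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    collections = [f"genome{i:02d}" for i in range(config.n_pm_collections)]
    bgcs = [f"BGC{i:04d}" for i in range(config.n_bgcs)]

    pm_rows: list[dict] = []
    sm_rows: list[dict] = []
    gene_family: dict[str, str] = {}
    gene_length: dict[str, int] = {}
    hit_rows: list[dict] = []
    intended: dict[str, str] = {}

    def add_pm(ec: str, collection: str, length: int, product: str, family: Optional[str]) -> str:
        gid = f"pm_g{len(pm_rows):05d}"
        pm_rows.append(
            {"gene_id": gid, "collection_id": collection, "ec": ec, "length": length, "product": product}
        )
        gene_length[gid] = length
        if family:
            gene_family[gid] = family
        return gid

    def add_sm(ec: str, bgc: str, length: int, product: str, family: Optional[str]) -> str:
        gid = f"sm_g{len(sm_rows):05d}"
        sm_rows.append(
            {"gene_id": gid, "collection_id": bgc, "ec": ec, "length": length, "product": product}
        )
        gene_length[gid] = length
        if family:
            gene_family[gid] = family
        return gid

    def jittered(base: int) -> int:
        lo = int(round(base * (1 - config.length_jitter)))
        hi = int(round(base * (1 + config.length_jitter)))
        return int(rng.integers(lo, hi + 1))

    # --- planted homolog families ----------------------------------------
    for fam in config.family_design:
        base_len = int(rng.integers(config.length_min, config.length_max + 1))
        pm_members: list[str] = []
        for ec in fam.pm_functions:
            for _ in range(fam.n_pm_per_function):
                coll = collections[int(rng.integers(0, len(collections)))]
                pm_members.append(
                    add_pm(ec, coll, jittered(base_len), f"{fam.family_id} PM enzyme", fam.family_id)
                )
        sm_members: list[str] = []
        for ec in fam.sm_functions:
            intended[ec] = fam.intended_category or ""
            for _ in range(fam.n_sm_per_function):
                bgc = bgcs[int(rng.integers(0, len(bgcs)))]
                sm_members.append(
                    add_sm(ec, bgc, jittered(base_len), f"{fam.family_id} SM enzyme", fam.family_id)
                )
        for q in sm_members:
            for s in pm_members:
                hit_rows.append(
                    {"query_id": q, "subject_id": s, "evalue": _log_uniform(rng, *config.evalue_range_in_family)}
                )

    # --- background enzymes ----------------------------------------------
    n_pm_target = config.n_pm_collections * config.genes_per_collection
    while len(pm_rows) < n_pm_target:
        coll = collections[len(pm_rows) % len(collections)]
        add_pm(
            _random_function(rng, config.ec_class_weights_pm),
            coll,
            int(rng.integers(config.length_min, config.length_max + 1)),
            "background PM enzyme",
            None,
        )
    n_sm_target = config.n_bgcs * config.enzymes_per_bgc
    while len(sm_rows) < n_sm_target:
        bgc = bgcs[len(sm_rows) % len(bgcs)]
        add_sm(
            _random_function(rng, config.ec_class_weights_sm),
            bgc,
            int(rng.integers(config.length_min, config.length_max + 1)),
            "background SM enzyme",
            None,
        )

    planted_sm = [r for r in sm_rows if r["gene_id"] in gene_family]
    background_pm = [r for r in pm_rows if r["gene_id"] not in gene_family]

    # --- decoy hits straddling the filters --------------------------------
    for _ in range(config.n_decoy_hits):
        q = planted_sm[int(rng.integers(0, len(planted_sm)))]
        s = background_pm[int(rng.integers(0, len(background_pm)))]
        hit_rows.append(
            {"query_id": q["gene_id"], "subject_id": s["gene_id"],
             "evalue": _log_uniform(rng, *config.evalue_range_decoy)}
        )
    # passing E-value but out-of-tolerance subject length
    added = 0
    for s in background_pm:
        if added >= config.n_length_violation_hits:
            break
        q = planted_sm[added % len(planted_sm)]
        if abs(s["length"] - q["length"]) / q["length"] > 0.35:
            hit_rows.append(
                {"query_id": q["gene_id"], "subject_id": s["gene_id"],
                 "evalue": _log_uniform(rng, *config.evalue_range_in_family)}
            )
            added += 1

    # --- records removed by the inclusion filters -------------------------
    injected = {"PM": {"no_ec": 0, "multi_ec": 0}, "SM": {"no_ec": 0, "multi_ec": 0}}
    for side, rows, adder, coll_pool in (
        ("PM", pm_rows, add_pm, collections),
        ("SM", sm_rows, add_sm, bgcs),
    ):
        n_no = int(round(config.fraction_no_ec * len(rows)))
        n_multi = int(round(config.fraction_multi_ec * len(rows)))
        for _ in range(n_no):
            adder("", coll_pool[int(rng.integers(0, len(coll_pool)))],
                  int(rng.integers(config.length_min, config.length_max + 1)), "no-EC record", None)
        for _ in range(n_multi):
            weights = config.ec_class_weights_pm if side == "PM" else config.ec_class_weights_sm
            ec = ";".join((_random_function(rng, weights), _random_function(rng, weights)))
            adder(ec, coll_pool[int(rng.integers(0, len(coll_pool)))],
                  int(rng.integers(config.length_min, config.length_max + 1)), "multi-EC record", None)
        injected[side] = {"no_ec": n_no, "multi_ec": n_multi}

    # --- genomes: operon runs, planted anchor, embedded BGC span -----------
    genome_rows: list[dict] = []
    anchors: list[dict] = []
    sm_by_bgc: dict[str, list[dict]] = {}
    for r in sm_rows:
        sm_by_bgc.setdefault(r["collection_id"], []).append(r)
    pm_by_coll: dict[str, list[dict]] = {}
    for r in pm_rows:
        pm_by_coll.setdefault(r["collection_id"], []).append(r)

    hit_by_pair = {(h["query_id"], h["subject_id"]): h["evalue"] for h in hit_rows}
    fam_sm_members: dict[str, list[str]] = {}
    for r in planted_sm:
        fam_sm_members.setdefault(gene_family[r["gene_id"]], []).append(r["gene_id"])

    for i, coll in enumerate(collections):
        members = list(pm_by_coll.get(coll, []))
        anchor_row = next((r for r in members if r["gene_id"] in gene_family), None)
        operon_pathway = f"path{i:03d}"
        ordered: list[tuple[dict, str]] = []  # (row, pathways)
        rest = [r for r in members if anchor_row is None or r["gene_id"] != anchor_row["gene_id"]]
        if anchor_row is not None:
            op_len = int(config.operon_lengths[int(rng.integers(0, len(config.operon_lengths)))])
            co_members, rest = rest[: op_len - 1], rest[op_len - 1 :]
            block = co_members[: (op_len - 1) // 2] + [anchor_row] + co_members[(op_len - 1) // 2 :]
            for r in block:
                ordered.append((r, operon_pathway))
            fam = gene_family[anchor_row["gene_id"]]
            sm_gene = sorted(fam_sm_members[fam])[0]
            anchors.append(
                {
                    "genome_id": coll,
                    "anchor_gene_id": anchor_row["gene_id"],
                    "bgc_id": next(r["collection_id"] for r in sm_rows if r["gene_id"] == sm_gene),
                    "sm_gene_id": sm_gene,
                    "evalue": hit_by_pair[(sm_gene, anchor_row["gene_id"])],
                    "operon_pathway": operon_pathway,
                }
            )
        # embedded BGC span: the SM enzymes of one cluster, contiguous
        span = sm_by_bgc.get(bgcs[i % len(bgcs)], [])
        half = len(rest) // 2
        for r in rest[:half]:
            ordered.append((r, ""))
        for r in span:
            ordered.append((r, "path_sm"))
        for r in rest[half:]:
            ordered.append((r, ""))
        for ordinal, (r, pathway) in enumerate(ordered):
            genome_rows.append(
                {
                    "replicon_id": coll,
                    "ordinal": ordinal,
                    "gene_id": r["gene_id"],
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "product": r["product"],
                    "ec": r["ec"],
                    "pathways": pathway,
                }
            )

    sm_pathway_functions = sorted(
        {r["ec"] for r in sm_rows if r["ec"] and ";" not in r["ec"]}
    )

    truth = SyntheticTruth(
        pm_rows=pm_rows,
        sm_rows=sm_rows,
        hit_rows=hit_rows,
        genome_rows=genome_rows,
        sm_pathway_functions=sm_pathway_functions,
        gene_family=gene_family,
        anchors=anchors,
        injected=injected,
        intended_categories=intended,
    )
    paths = _write_bundle(outdir, truth, config)
    return Bundle(paths=paths, truth=truth, config=config)


def _write_bundle(outdir: Path, truth: SyntheticTruth, config: SimulationConfig) -> dict:
    paths = {}

    def catalog_lines(rows, species):
        lines = ["gene_id\tcollection_id\tspecies_tax\tec\tlength\tproduct"]
        for r in rows:
            lines.append(
                f"{r['gene_id']}\t{r['collection_id']}\t{species}\t{r['ec']}\t{r['length']}\t{r['product']}"
            )
        return "\n".join(lines) + "\n"

    paths["pm_catalog"] = outdir / "pm_catalog.tsv"
    paths["pm_catalog"].write_text(catalog_lines(truth.pm_rows, "synthetic_pm_taxon"))
    paths["sm_catalog"] = outdir / "sm_catalog.tsv"
    paths["sm_catalog"].write_text(catalog_lines(truth.sm_rows, "synthetic_sm_taxon"))

    length = {r["gene_id"]: r["length"] for r in truth.pm_rows + truth.sm_rows}
    lines = []
    for h in truth.hit_rows:
        lq, ls = length[h["query_id"]], length[h["subject_id"]]
        aln = min(lq, ls)
        bits = max(30.0, -2.0 * math.log10(h["evalue"]))
        lines.append(
            f"{h['query_id']}\t{h['subject_id']}\t55.00\t{aln}\t{max(0, aln // 10)}\t1"
            f"\t1\t{lq}\t1\t{ls}\t{h['evalue']:.3e}\t{bits:.1f}"
        )
    paths["hits"] = outdir / "hits.tsv"
    paths["hits"].write_text("\n".join(lines) + "\n")

    lines = ["replicon_id\tordinal\tgene_id\tstrand\tproduct\tec\tpathways"]
    for r in truth.genome_rows:
        lines.append(
            f"{r['replicon_id']}\t{r['ordinal']}\t{r['gene_id']}\t{r['strand']}"
            f"\t{r['product']}\t{r['ec']}\t{r['pathways']}"
        )
    paths["genomes"] = outdir / "genomes.tsv"
    paths["genomes"].write_text("\n".join(lines) + "\n")

    pathway_ids = sorted({r["pathways"] for r in truth.genome_rows if r["pathways"]})
    lines = ["pathway_id\tpathway_name"]
    for pid in pathway_ids:
        name = "Biosynthesis of secondary metabolites" if pid == "path_sm" else f"synthetic pathway {pid}"
        lines.append(f"{pid}\t{name}")
    paths["pathway_map"] = outdir / "pathway_map.tsv"
    paths["pathway_map"].write_text("\n".join(lines) + "\n")

    lines = ["ec"] + truth.sm_pathway_functions
    paths["sm_pathway_functions"] = outdir / "sm_pathway_functions.tsv"
    paths["sm_pathway_functions"].write_text("\n".join(lines) + "\n")

    lines = ["bgc_id\tsm_gene_id\tgenome_id\tanchor_gene_id\tevalue"]
    for a in truth.anchors:
        lines.append(
            f"{a['bgc_id']}\t{a['sm_gene_id']}\t{a['genome_id']}\t{a['anchor_gene_id']}\t{a['evalue']:.3e}"
        )
    paths["pairs"] = outdir / "pairs.tsv"
    paths["pairs"].write_text("\n".join(lines) + "\n")

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


@dataclass
class OracleResults:
    filter_logs: dict  # side -> counts
    frequencies: dict  # side -> level -> {key: percent}
    shared: dict  # level -> sorted key lists {"shared","sm_only","pm_only"}
    kept_hits: list  # (query_id, subject_id, evalue), sorted
    classifications: dict  # level -> {sm_key: (category, n_hits, n_same)}
    category_counts: dict  # level -> {category: count}
    fc: dict  # level -> {key: (fc, n_hits)}
    edges: dict  # level -> {(pm_key, sm_key): weight}
    neighborhoods: dict  # anchor gene -> {"n_P", "n_S", "pathway_rows"}


def _key_at(ec: str, level: str) -> Optional[str]:
    parts = ec.split(".")
    depth = _LEVEL_DEPTH[level]
    head = parts[:depth]
    if "-" in head:
        return None
    return ".".join(head)


def oracle_expected_outputs(
    truth: SyntheticTruth,
    evalue_cutoff: float = 1e-20,
    length_tolerance: float = 0.30,
    k_outer: int = 10,
    k_inner: int = 2,
) -> OracleResults:
    """Expected pipeline outputs by exhaustive enumeration over the truth.

    Pure string/dict arithmetic: inclusion filtering keeps rows whose ``ec``
    field holds exactly one EC; hits are kept iff the E-value is at or below
    the cutoff and the length deviation at or below the tolerance; everything
    downstream is direct counting.
    """
    levels = tuple(_LEVEL_DEPTH)

    filter_logs = {}
    kept_rows = {}
    for side, rows in (("PM", truth.pm_rows), ("SM", truth.sm_rows)):
        no_ec = [r for r in rows if not r["ec"]]
        multi = [r for r in rows if ";" in r["ec"]]
        kept = [r for r in rows if r["ec"] and ";" not in r["ec"]]
        filter_logs[side] = {
            "n_input": len(rows),
            "n_removed_no_ec": len(no_ec),
            "n_removed_multi_ec": len(multi),
            "n_kept": len(kept),
        }
        kept_rows[side] = kept

    frequencies = {"PM": {}, "SM": {}}
    for side in ("PM", "SM"):
        for level in levels:
            counts: dict[str, int] = {}
            for r in kept_rows[side]:
                key = _key_at(r["ec"], level)
                if key is not None:
                    counts[key] = counts.get(key, 0) + 1
            total = sum(counts.values())
            frequencies[side][level] = {k: 100.0 * v / total for k, v in counts.items()} if total else {}

    shared = {}
    for level in levels:
        sm_keys = {_key_at(r["ec"], level) for r in kept_rows["SM"]} - {None}
        pm_keys = {_key_at(r["ec"], level) for r in kept_rows["PM"]} - {None}
        shared[level] = {
            "shared": sorted(sm_keys & pm_keys),
            "sm_only": sorted(sm_keys - pm_keys),
            "pm_only": sorted(pm_keys - sm_keys),
        }

    length = {r["gene_id"]: r["length"] for r in truth.pm_rows + truth.sm_rows}
    ec_of = {r["gene_id"]: r["ec"] for r in kept_rows["PM"] + kept_rows["SM"]}
    best: dict[tuple[str, str], float] = {}
    for h in truth.hit_rows:
        pair = (h["query_id"], h["subject_id"])
        if pair not in best or h["evalue"] < best[pair]:
            best[pair] = h["evalue"]
    kept_hits = []
    for (q, s), e in sorted(best.items()):
        if q == s or e > evalue_cutoff:
            continue
        if abs(length[s] - length[q]) / length[q] > length_tolerance:
            continue
        kept_hits.append((q, s, e))

    classifications = {}
    category_counts = {}
    fc = {}
    edges = {}
    for level in levels:
        pooled: dict[str, list[str]] = {}
        edge_w: dict[tuple[str, str], int] = {}
        for q, s, e in kept_hits:
            if q not in ec_of or s not in ec_of:
                continue
            sm_key = _key_at(ec_of[q], level)
            pm_key = _key_at(ec_of[s], level)
            if sm_key is None or pm_key is None:
                continue
            pooled.setdefault(sm_key, []).append(pm_key)
            if pm_key != sm_key:
                edge_w[(pm_key, sm_key)] = edge_w.get((pm_key, sm_key), 0) + 1
        cls = {}
        counts = {"ALL_SAME": 0, "MIXED": 0, "ALL_DIFF": 0}
        fc_level = {}
        for sm_key, pm_keys in pooled.items():
            n_same = sum(1 for p in pm_keys if p == sm_key)
            n = len(pm_keys)
            cat = "ALL_SAME" if n_same == n else "ALL_DIFF" if n_same == 0 else "MIXED"
            cls[sm_key] = (cat, n, n_same)
            counts[cat] += 1
            fc_level[sm_key] = (n_same / n, n)
        classifications[level] = cls
        category_counts[level] = counts
        fc[level] = fc_level
        edges[level] = edge_w

    pm_full_keys = {_key_at(r["ec"], "full") for r in kept_rows["PM"]} - {None}
    sm_funcs = set(truth.sm_pathway_functions)
    by_replicon: dict[str, list[dict]] = {}
    for r in truth.genome_rows:
        by_replicon.setdefault(r["replicon_id"], []).append(r)
    neighborhoods = {}
    for a in truth.anchors:
        genes = sorted(by_replicon[a["genome_id"]], key=lambda r: r["ordinal"])
        idx = next(i for i, g in enumerate(genes) if g["gene_id"] == a["anchor_gene_id"])
        window = [(i - idx, genes[i]) for i in range(max(0, idx - k_outer), min(len(genes), idx + k_outer + 1))]
        n_p = n_s = 0
        pw_counts: dict[str, list[int]] = {}
        for off, g in window:
            ecs = [p for p in g["ec"].split(";") if p]
            if any("-" not in e and e in pm_full_keys for e in ecs):
                n_p += 1
            if any(e in sm_funcs for e in ecs):
                n_s += 1
            for pw in (p for p in g["pathways"].split(";") if p):
                c = pw_counts.setdefault(pw, [0, 0])
                c[0] += 1
                if abs(off) <= k_inner:
                    c[1] += 1
        rows = sorted(((v[0], v[1], pw) for pw, v in pw_counts.items()), key=lambda r: (-r[0], r[2]))
        neighborhoods[a["anchor_gene_id"]] = {"n_P": n_p, "n_S": n_s, "pathway_rows": rows}

    return OracleResults(
        filter_logs=filter_logs,
        frequencies=frequencies,
        shared=shared,
        kept_hits=kept_hits,
        classifications=classifications,
        category_counts=category_counts,
        fc=fc,
        edges=edges,
        neighborhoods=neighborhoods,
    )
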