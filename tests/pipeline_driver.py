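"""End-to-end pipeline driver over a simulated bundle, for oracle comparisons."""

import pandas as pd

from ecrecruit.catalog import apply_inclusion_filters, load_catalog
from ecrecruit.ec import LEVELS
from ecrecruit.flexibility import classify_functions, functional_conservation
from ecrecruit.homology import (
    HitFilterConfig,
    build_function_hit_map,
    filter_hits,
    parse_hit_table,
)
from ecrecruit.neighborhood import (
    assign_labels,
    extract_neighborhood,
    load_genome_table,
    summarize_labels,
    summarize_pathways,
)
from ecrecruit.network import build_change_graph
from ecrecruit.spectrum import ec_frequencies, shared_exclusive_functions


def run_pipeline(bundle, evalue_cutoff=1e-20):
    """Run every stage on a simulated bundle through the public API.

    Returns a dict shaped like the oracle's fields (counts and key sets, not
    E-value floats, which lose precision through file round-trips).
    """
    pm, pm_log = apply_inclusion_filters(load_catalog(bundle.paths["pm_catalog"], "PM"))
    sm, sm_log = apply_inclusion_filters(load_catalog(bundle.paths["sm_catalog"], "SM"))
    config = HitFilterConfig(evalue_cutoff=evalue_cutoff)
    hits = parse_hit_table(bundle.paths["hits"])
    kept, _ = filter_hits(hits, config, query_catalog=sm, subject_catalog=pm)
    fmap = build_function_hit_map(kept, sm, pm, config)

    out = {
        "filter_logs": {"PM": vars(pm_log), "SM": vars(sm_log)},
        "kept_pairs": sorted((h.query_id, h.subject_id) for h in kept),
        "frequencies": {"PM": {}, "SM": {}},
        "shared": {},
        "classifications": {},
        "category_counts": {},
        "fc": {},
        "edges": {},
        "neighborhoods": {},
    }
    for level in LEVELS:
        out["frequencies"]["PM"][level] = ec_frequencies(pm, level).entries
        out["frequencies"]["SM"][level] = ec_frequencies(sm, level).entries
        shared, sm_only, pm_only = shared_exclusive_functions(sm, pm, level)
        out["shared"][level] = {
            "shared": sorted(shared),
            "sm_only": sorted(sm_only),
            "pm_only": sorted(pm_only),
        }
        classifications = classify_functions(fmap, level)
        out["classifications"][level] = {
            c.key: (c.category.value, c.n_hits, c.n_same) for c in classifications
        }
        counts = {"ALL_SAME": 0, "MIXED": 0, "ALL_DIFF": 0}
        for c in classifications:
            counts[c.category.value] += 1
        out["category_counts"][level] = counts
        fc = functional_conservation(fmap, level)
        out["fc"][level] = dict(fc.entries)
        graph = build_change_graph(fmap, level, fc_table=fc)
        out["edges"][level] = {(u, v): d["weight"] for u, v, d in graph.edges(data=True)}

    genome = load_genome_table(bundle.paths["genomes"])
    pm_keys = {r.ec.key("full") for r in pm.records}
    sm_keys = set(pd.read_csv(bundle.paths["sm_pathway_functions"], sep="\t", dtype=str)["ec"])
    pairs = pd.read_csv(bundle.paths["pairs"], sep="\t", dtype=str)
    for row in pairs.itertuples(index=False):
        nh = assign_labels(extract_neighborhood(genome, row.anchor_gene_id, k=10), pm_keys, sm_keys)
        n_p, n_s = summarize_labels(nh)
        out["neighborhoods"][row.anchor_gene_id] = {
            "n_P": n_p,
            "n_S": n_s,
            "pathway_rows": summarize_pathways(nh),
        }
    return out
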