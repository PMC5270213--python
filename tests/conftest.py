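import pytest
from hypothesis import settings

from ecrecruit.catalog import EnzymeCatalog, EnzymeRecord
from ecrecruit.ec import parse_ec
from ecrecruit.simulate import SimulationConfig, oracle_expected_outputs, simulate
from pipeline_driver import run_pipeline

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

__all__ = ["make_record", "make_catalog", "run_pipeline"]


def make_record(gene_id, ec, collection="c1", length=300, role_tax="tax"):
    ec_list = tuple(parse_ec(e) for e in ec.split(";")) if ec else ()
    return EnzymeRecord(
        gene_id=gene_id,
        collection_id=collection,
        species_tax=role_tax,
        ec_list=ec_list,
        length=length,
    )


def make_catalog(role, specs):
    """specs: iterable of (gene_id, ec string or '', [collection], [length])."""
    records = []
    for spec in specs:
        gene_id, ec = spec[0], spec[1]
        collection = spec[2] if len(spec) > 2 else "c1"
        length = spec[3] if len(spec) > 3 else 300
        records.append(make_record(gene_id, ec, collection, length))
    return EnzymeCatalog(role=role, records=tuple(records))


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default-configuration synthetic bundle, seed 1."""
    outdir = tmp_path_factory.mktemp("bundle_seed1")
    return simulate(SimulationConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def oracle(bundle):
    return oracle_expected_outputs(bundle.truth)


@pytest.fixture(scope="session")
def pipeline_results(bundle):
    return run_pipeline(bundle)
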