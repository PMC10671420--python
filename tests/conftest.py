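import logging

import pytest

from pmscoex import (
    default_benchmark,
    plant_gene_sets,
    run_pipeline,
    simulate_expression,
    simulate_pli,
)
from pmscoex.config import config_from_dict

logging.getLogger("pmscoex").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def benchmark_spec():
    return default_benchmark()


@pytest.fixture(scope="session")
def benchmark_data(benchmark_spec):
    """(ExpressionMatrix in RPKM, PlantedTruth) for the default benchmark."""
    return simulate_expression(benchmark_spec)


@pytest.fixture(scope="session")
def benchmark_annotation(benchmark_spec, benchmark_data):
    _, truth = benchmark_data
    return plant_gene_sets(truth, benchmark_spec)


@pytest.fixture(scope="session")
def benchmark_run(tmp_path_factory, benchmark_spec, benchmark_data, benchmark_annotation):
    """One full pipeline run on the default synthetic benchmark."""
    M, truth = benchmark_data
    out = tmp_path_factory.mktemp("benchmark_run")
    pli_path = out / "pli.tsv"
    simulate_pli(truth, benchmark_spec).to_csv(pli_path, sep="\t", index=False)
    cfg = config_from_dict(
        {
            "preprocess": {"restrict_to_annotated": False},
            "paths": {"out_dir": str(out / "pipeline"), "pli": str(pli_path)},
        }
    )
    return run_pipeline(cfg, expression=M, annotation=benchmark_annotation)
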