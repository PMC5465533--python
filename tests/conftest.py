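import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lnctissue import (
    ExpressionMatrix,
    SimulationConfig,
    simulate_expression,
    simulate_sites,
)
from lnctissue.expression_io import filter_expressed, log_transform
from lnctissue.specificity import profile_genes, specific_genes_by_tissue

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(rows, gene_ids=None, tissues=None, transformed=False):
    """Small helper to build an ExpressionMatrix from a list of rows."""
    rows = np.asarray(rows, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(rows.shape[0])]
    tissues = tissues or [f"t{j + 1}" for j in range(rows.shape[1])]
    df = pd.DataFrame(rows, index=gene_ids, columns=tissues)
    df.index.name = "gene_id"
    return ExpressionMatrix(df, transformed=transformed)


@pytest.fixture(scope="session")
def default_benchmark():
    """The default synthetic study at seed 1: matrix, catalog, truth, sites."""
    cfg = SimulationConfig(seed=1)
    matrix, catalog, truth = simulate_expression(cfg)
    sites = simulate_sites(cfg, truth)
    return cfg, matrix, catalog, truth, sites


@pytest.fixture(scope="session")
def profiled_benchmark(default_benchmark):
    """Benchmark after filtering, log transform and specificity profiling."""
    cfg, matrix, catalog, truth, sites = default_benchmark
    logged = log_transform(filter_expressed(matrix))
    profiles = profile_genes(logged)
    tissue_sets = specific_genes_by_tissue(profiles, logged.tissue_names)
    return cfg, logged, catalog, truth, sites, profiles, tissue_sets
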