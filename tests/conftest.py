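import numpy as np
import pandas as pd
import pytest

import phylotrx as px


@pytest.fixture(scope="session")
def small_config():
    return px.SimulationConfig(n_genes=300, n_ps=8, effect_size=2.0, seed=11)


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return px.simulate_gene_catalog(small_config)


@pytest.fixture(scope="session")
def small_counts(small_catalog, small_config):
    cm, means = px.simulate_counts(small_catalog, small_config)
    return cm


@pytest.fixture(scope="session")
def small_expr(small_counts):
    fractions = px.normalize_fraction_of_transcripts(small_counts)
    return px.collapse_replicates(fractions, small_counts)


def toy_stage_expression(values, stages=None):
    """Build a StageExpression from a plain nested list (genes x stages)."""
    arr = np.asarray(values, dtype=float)
    stages = stages or [f"s{j}" for j in range(arr.shape[1])]
    genes = [f"g{i}" for i in range(arr.shape[0])]
    return px.StageExpression(
        values=pd.DataFrame(arr, index=genes, columns=stages),
        stage_order=list(stages),
    )
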