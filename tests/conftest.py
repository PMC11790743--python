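import numpy as np
import pandas as pd
import pytest

import flydelay as fd


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration simulated dataset, shared across tests."""
    return fd.simulate_dataset(fd.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_sim_fitted(default_sim):
    """Size factors, dispersions and normalized counts for the default sim."""
    matrix, design, annotation, truth = default_sim
    factors = fd.size_factors_median_of_ratios(matrix)
    dispersions = fd.estimate_dispersion(matrix, design, factors)
    normalized = fd.normalize(matrix, factors)
    return factors, dispersions, normalized


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 samples with easy hand-checkable numbers."""
    return fd.ExpressionMatrix(
        pd.DataFrame(
            [[2, 4], [8, 16], [5, 10]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def small_design():
    """Standard 18-sample design: 2 sexes x 3 ages x 3 replicates."""
    rows = []
    for sex in ("F", "M"):
        for age in (3, 7, 14):
            for rep in (1, 2, 3):
                rows.append({"sample": f"{sex}{age}_r{rep}", "sex": sex,
                             "age_days": age, "replicate": rep})
    return fd.SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def chain_dag():
    """2-term ontology: b is_a a with the default 0.8 weight."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_edge("b", "a", relation="is_a")
    return fd.OntologyDAG(g)
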