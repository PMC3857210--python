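import numpy as np
import pandas as pd
import pytest

from netcondense import ExpressionMatrix, GroupLabels, network_from_edges


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_matrix():
    """4 genes x 4 samples, strictly positive linear intensities."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 4.0, 8.0],
            "s2": [2.0, 2.0, 5.0, 7.0],
            "s3": [1.5, 3.0, 4.5, 9.0],
            "s4": [2.5, 1.0, 6.0, 6.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    return ExpressionMatrix(values)


@pytest.fixture
def small_labels():
    return GroupLabels({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


@pytest.fixture
def toy_network():
    return network_from_edges([("a", "b"), ("b", "c"), ("c", "d")])


def random_linear_matrix(rng, n_genes, n_samples, prefix_g="g", prefix_s="s"):
    values = pd.DataFrame(
        np.exp2(rng.normal(8, 1.5, (n_genes, n_samples))),
        index=[f"{prefix_g}{i}" for i in range(n_genes)],
        columns=[f"{prefix_s}{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(values)
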