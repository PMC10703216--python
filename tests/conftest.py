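import numpy as np
import pandas as pd
import pytest

from protsig import ProteinMatrix, SyntheticConfig, generate_expression


@pytest.fixture
def toy_matrix() -> ProteinMatrix:
    """Six samples, three proteins, two balanced classes, no missing."""
    values = pd.DataFrame(
        {
            "P1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "P2": [0.5, 0.1, 0.3, 0.4, 0.2, 0.6],
            "P3": [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
        },
        index=[f"S{i}" for i in range(6)],
    )
    labels = pd.Series(["LUAD"] * 3 + ["LUSC"] * 3, index=values.index)
    return ProteinMatrix(values, labels, classes=("LUAD", "LUSC"))


@pytest.fixture
def planted_matrix() -> tuple[ProteinMatrix, dict]:
    """200/class, 8 proteins, 2 planted with effect size 1.5."""
    cfg = SyntheticConfig(
        n_per_class=200, m_proteins=8, informative=[(0, 1.5), (3, 1.5)], seed=42
    )
    return generate_expression(cfg)


def linear_gaussian_cov(edges: list[tuple[str, str, float]], noise_sd: float = 1.0) -> pd.DataFrame:
    """Population covariance of a linear-Gaussian DAG: (I-B)^-1 D (I-B)^-T."""
    import networkx as nx

    g = nx.DiGraph((a, b) for a, b, _ in edges)
    order = list(nx.topological_sort(g))
    idx = {v: i for i, v in enumerate(order)}
    B = np.zeros((len(order), len(order)))
    for a, b, c in edges:
        B[idx[b], idx[a]] = c
    A = np.linalg.inv(np.eye(len(order)) - B)
    cov = A @ (noise_sd**2 * np.eye(len(order))) @ A.T
    nodes = sorted(order)
    return pd.DataFrame(cov, index=order, columns=order).loc[nodes, nodes]
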