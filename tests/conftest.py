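import numpy as np
import pytest

from neuromantel import (
    ExpressionMatrix,
    RegionOntology,
    SimilarityMatrix,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Small signal-mode synthetic study shared across read-only tests."""
    return generate_dataset(
        SyntheticConfig(
            n_leaf_regions=16, branching=4, n_genes=40, frac_pair=0.1, seed=11
        )
    )


@pytest.fixture
def toy_ontology():
    """Three-level toy: root -> {A, B}; A -> {A1, A2}; A2 -> {A2a, A2b}."""
    return RegionOntology(
        [
            ("root", "root", None),
            ("A", "region A", "root"),
            ("B", "region B", "root"),
            ("A1", "region A1", "A"),
            ("A2", "region A2", "A"),
            ("A2a", "region A2a", "A2"),
            ("A2b", "region A2b", "A2"),
        ]
    )


def random_similarity(n: int, rng: np.random.Generator, kind: str = "correlation"):
    """Symmetric random matrix with the right diagonal for its kind."""
    m = rng.standard_normal((n, n))
    m = (m + m.T) / 2
    if kind == "distance":
        m = np.abs(m)
        np.fill_diagonal(m, 0.0)
    else:
        m = np.clip(m / (np.abs(m).max() + 1e-9), -1, 1)
        np.fill_diagonal(m, 1.0)
    return SimilarityMatrix([f"r{i}" for i in range(n)], m, kind)


def expression_from_values(values: np.ndarray) -> ExpressionMatrix:
    y, x = values.shape
    series = [f"S{i:03d}" for i in range(y)]
    return ExpressionMatrix(
        series,
        {s: f"G{i:03d}" for i, s in enumerate(series)},
        [f"r{j}" for j in range(x)],
        values,
    )
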