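import numpy as np
import pandas as pd
import pytest

from reosig import CohortSpec, ExpressionMatrix, PhenotypeLabels, generate_cohort


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 3 samples with one masked cell and one exact tie."""
    values = pd.DataFrame(
        {
            "s1": [5.0, 3.0, 2.0, 1.0],
            "s2": [2.0, 2.0, np.nan, 4.0],
            "s3": [1.0, 6.0, 3.0, 3.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def tiny_labels() -> PhenotypeLabels:
    return PhenotypeLabels(
        classes=pd.Series(
            {"s1": "normal", "s2": "normal", "s3": "cancer"}, name="class"
        )
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted-signal cohort shared across discovery/classifier tests."""
    spec = CohortSpec(
        n_genes=60,
        n_reference=40,
        n_alternative=40,
        n_planted=8,
        p_orientation=0.97,
        seed=11,
    )
    return generate_cohort(spec)


def naive_pair_counts(values: np.ndarray):
    """Brute-force orientation counting: plain loops over pairs and samples.

    Independent oracle for the vectorized implementation; returns dicts
    keyed by (i, j) row-index pairs with i < j.
    """
    n_genes, n_samples = values.shape
    gt, lt, tie, und = {}, {}, {}, {}
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            g = l = t = u = 0
            for s in range(n_samples):
                vi, vj = values[i, s], values[j, s]
                if np.isnan(vi) or np.isnan(vj):
                    u += 1
                elif vi > vj:
                    g += 1
                elif vi < vj:
                    l += 1
                else:
                    t += 1
            gt[(i, j)] = g
            lt[(i, j)] = l
            tie[(i, j)] = t
            und[(i, j)] = u
    return gt, lt, tie, und
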