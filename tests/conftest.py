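import numpy as np
import pandas as pd
import pytest

import kernelgp as kg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def standardized_markers(rng):
    """Random 10-line x 50-marker standardized matrix."""
    raw = rng.integers(0, 3, size=(10, 50)).astype(float)
    return kg.standardize_markers(
        kg.MarkerMatrix(raw, [f"L{i}" for i in range(10)], [f"M{j}" for j in range(50)])
    )


@pytest.fixture
def small_trial():
    """Small synthetic hybrid trial (hybrids, records, kernels), shared.

    80 hybrids from 20 founders, 300 markers, 3 environments, 25% of cells
    unobserved.
    """
    cfg = kg.SimConfig(
        n_parents=20, n_hybrids=80, p=300, s=3, sparsity=0.25, seed=7
    )
    founders, crosses = kg.simulate_founders_and_hybrids(cfg)
    hybrids = kg.make_hybrid_genotypes(founders, crosses)
    records = kg.simulate_multienv_phenotypes(hybrids, cfg)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # monomorphic columns dropped
        X = kg.standardize_markers(hybrids)
    return {
        "cfg": cfg,
        "founders": founders,
        "crosses": crosses,
        "hybrids": hybrids,
        "records": records,
        "X": X,
        "GB": kg.linear_kernel(X),
        "GK": kg.gaussian_kernel(X),
    }


@pytest.fixture
def toy_records():
    """Three records over two environments: (A,e1), (B,e1), (A,e2)."""
    df = pd.DataFrame(
        {
            "line": ["A", "B", "A"],
            "env": ["e1", "e1", "e2"],
            "trait": ["t", "t", "t"],
            "value": [1.0, 2.0, 3.0],
        }
    )
    return kg.PhenotypeRecords(df)
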