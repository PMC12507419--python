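import numpy as np
import pandas as pd
import pytest

from statesig import (
    default_scenario,
    preprocess_counts,
    select_genes,
    simulate_counts,
)


@pytest.fixture(scope="session")
def default_fixture():
    """The frozen reference study: simulated counts, metadata, planted
    truth, preprocessed expression and the elbow selection."""
    spec = default_scenario()
    counts, meta, truth = simulate_counts(spec)
    expr = preprocess_counts(counts, meta)
    selection = select_genes(expr, meta, method="f_elbow", level="dataset")
    return {
        "spec": spec,
        "counts": counts,
        "meta": meta,
        "truth": truth,
        "expr": expr,
        "selection": selection,
    }


@pytest.fixture()
def toy_counts():
    """4 genes x 4 samples, two categories, hand-checkable."""
    counts = pd.DataFrame(
        [[10, 20, 30, 40],
         [5, 5, 5, 5],
         [100, 110, 10, 12],
         [0, 1, 2, 3]],
        index=["gA", "gB", "gC", "gD"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {
            "category": ["early", "early", "late", "late"],
            "dataset": ["d1", "d1", "d2", "d2"],
            "batch": ["b1", "b1", "b1", "b1"],
            "is_control": [True, True, False, False],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return counts, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(20240930)
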