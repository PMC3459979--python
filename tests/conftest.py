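import numpy as np
import pandas as pd
import pytest

import domexpr as dx


@pytest.fixture(scope="session")
def small_multi_pair():
    """3 pairs x 3v3, 200 genes, 5% shared DE."""
    cfg = dx.ExprSimConfig(
        n_pairs=3, samples_per_group=3, n_genes=200,
        frac_shared_de=0.05, seed=42,
    )
    return dx.simulate_counts(cfg)


@pytest.fixture(scope="session")
def single_pair_null():
    """One pair, 5v5, 400 genes, no domestication effect."""
    cfg = dx.ExprSimConfig(
        n_pairs=1, samples_per_group=5, n_genes=400,
        dispersion_a0=0.1, dispersion_a1=0.0, seed=7,
    )
    return dx.simulate_counts(cfg)


def make_samples(pairs, statuses, sexes=None, prefix="s"):
    """Hand-build a sample metadata frame."""
    n = len(pairs)
    if sexes is None:
        sexes = ["F"] * n
    idx = [f"{prefix}{i + 1}" for i in range(n)]
    return pd.DataFrame(
        {"pair": pairs, "status": statuses, "sex": sexes},
        index=pd.Index(idx, name="sample"),
    )


@pytest.fixture
def toy_counts_2x3():
    """The 3-gene, 2-sample matrix with hand-computed size factors."""
    return pd.DataFrame(
        {"s1": [2, 4, 8], "s2": [4, 8, 16]},
        index=["g1", "g2", "g3"],
    )
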