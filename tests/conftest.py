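import numpy as np
import pandas as pd
import pytest

from growthmicro import TaxTree
from growthmicro.diversity import AbundanceTable


@pytest.fixture(scope="session")
def toy_tree() -> TaxTree:
    """Four genera in one phylum: ((A,B),(C,D))."""
    return TaxTree.from_newick(
        "(((A:1,B:1)n1:1,(C:1,D:1)n2:1)p__Firmicutes:1)root;"
    )


@pytest.fixture()
def toy_table(toy_tree) -> AbundanceTable:
    """10-sample table where leaf D is rare in all samples."""
    counts = pd.DataFrame(
        {
            "A": [10, 12, 9, 14, 11, 10, 13, 9, 12, 10],
            "B": [50, 48, 55, 60, 52, 49, 51, 58, 54, 50],
            "C": [30, 28, 33, 31, 29, 35, 30, 32, 28, 31],
            "D": [0, 1, 0, 2, 0, 1, 0, 0, 0, 0],
        },
        index=[f"S{i}" for i in range(10)],
    )
    return AbundanceTable(counts=counts, taxonomy=toy_tree.taxonomy(), tree=toy_tree)


@pytest.fixture(scope="session")
def two_phylum_table() -> AbundanceTable:
    """Small table with Firmicutes and Bacteroidetes for F:B checks."""
    tree = TaxTree.from_newick(
        "((F1:1,F2:1)p__Firmicutes:1,(B1:1,B2:1)p__Bacteroidetes:1)root;"
    )
    counts = pd.DataFrame(
        {
            "F1": [120, 80, 10],
            "F2": [80, 120, 0],
            "B1": [60, 100, 0],
            "B2": [40, 100, 0],
        },
        index=["s1", "s2", "s3"],
    )
    return AbundanceTable(counts=counts, taxonomy=tree.taxonomy(), tree=tree)


@pytest.fixture(scope="session")
def dense_two_component():
    """Known 2-component functional model sampled densely with light noise."""
    from growthmicro.synthetic import _orthonormal_components, true_mean_curve

    rng = np.random.default_rng(90210)
    grid = np.arange(0, 731, dtype=float)
    mu = true_mean_curve(grid)
    phis = _orthonormal_components(grid, ("sin1", "cos1"))
    lams = (np.array([0.008, 0.004]) * np.sqrt(730.0)) ** 2
    n = 120
    scores = rng.normal(0.0, np.sqrt(lams), size=(n, 2))
    curves = mu + scores @ phis
    obs = []
    for i in range(n):
        t = np.sort(rng.choice(731, size=15, replace=False)).astype(float)
        y = curves[i, t.astype(int)] + rng.normal(0, 0.002, size=15)
        obs.append((t, y))
    return {"grid": grid, "mu": mu, "phis": phis, "lams": lams,
            "scores": scores, "curves": curves, "obs": obs}


@pytest.fixture(scope="session")
def fpca_model(dense_two_component):
    import growthmicro as gm

    return gm.fit_fpca(dense_two_component["obs"])
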