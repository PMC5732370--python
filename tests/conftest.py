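"""Shared fixtures.

The heavy Monte-Carlo computations (type-I-error and power cells of the
benchmark design) are session-scoped so the calibration, power and trend
tests all read from one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import spca_eigentest as se


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_centred(rng, n=20, p=10):
    """A random centred frequency-like matrix."""
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    return se.CentredFreqMatrix(
        X=X,
        unit_ids=[f"u{i}" for i in range(n)],
        column_ids=[f"c{j}" for j in range(p)],
    )


def random_weights(rng, n=20, k=4):
    coords = se.CoordinateSet(
        unit_ids=[f"u{i}" for i in range(n)], xy=rng.uniform(size=(n, 2))
    )
    return se.knn_graph(coords, k)


@pytest.fixture
def small_problem(rng):
    """A 20-unit, 10-column instance with a KNN network."""
    return random_centred(rng), random_weights(rng)


# ---------------------------------------------------------------------------
# benchmark-scale Monte-Carlo fixtures (shared across tests)

TYPE1_REPS = 200
POWER_REPS = 100
BENCH_B = 199


@pytest.fixture(scope="session")
def type1_cells():
    """Rejection rates with no spatial structure (random coordinates).

    Two design cells: stepping-stone m=0.005 with 200 SNPs and island
    m=0.005 with 40 SNPs, 200 replicates x 199 permutations each.
    """
    df, _ = se.power_study(
        models=["SS"],
        rates=[0.005],
        patterns=["random"],
        n_loci_list=[200],
        n_reps=TYPE1_REPS,
        B=BENCH_B,
        alphas=[0.05],
        seed=11,
    )
    df2, _ = se.power_study(
        models=["IS"],
        rates=[0.005],
        patterns=["random"],
        n_loci_list=[40],
        n_reps=TYPE1_REPS,
        B=BENCH_B,
        alphas=[0.05],
        seed=11,
    )
    import pandas as pd

    return pd.concat([df, df2], ignore_index=True)


@pytest.fixture(scope="session")
def power_cells():
    """Power of the global-side test on spatially segregated (patch) data.

    Stepping-stone model, migration rates 0.005 and 0.1, 200 and 40 SNPs,
    100 replicates x 199 permutations per cell.
    """
    df, hist = se.power_study(
        models=["SS"],
        rates=[0.005, 0.1],
        patterns=["global"],
        n_loci_list=[200, 40],
        n_reps=POWER_REPS,
        B=BENCH_B,
        alphas=[0.05],
        seed=17,
    )
    return df, hist


def cell_value(df, side="pos", alpha=0.05, **keys):
    sel = (df["side"] == side) & (df["alpha"] == alpha)
    for col, val in keys.items():
        sel &= df[col] == val
    out = df.loc[sel, "proportion_significant"]
    assert len(out) == 1, f"ambiguous cell selection: {keys}"
    return float(out.iloc[0])
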