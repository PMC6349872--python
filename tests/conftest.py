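"""Shared fixtures: random sequences, toy classification sets, tiny benchmarks."""

from __future__ import annotations

import numpy as np
import pytest

from herbres.seqio import SequenceRecord


def random_acgt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_sequences(rng) -> list[str]:
    """100 pure-ACGT sequences, lengths 10-500, for oracle-equivalence tests."""
    return [
        random_acgt(rng, int(length))
        for length in rng.integers(10, 501, size=100)
    ]


@pytest.fixture(scope="session")
def separable_2d():
    """Linearly separable toy set: class +1 at x1 > 1, class -1 at x1 < -1."""
    rng = np.random.default_rng(7)
    n = 40
    pos = np.column_stack([rng.uniform(1.5, 3.0, n), rng.normal(0, 1, n)])
    neg = np.column_stack([rng.uniform(-3.0, -1.5, n), rng.normal(0, 1, n)])
    X = np.vstack([pos, neg])
    y = np.array(["pos"] * n + ["neg"] * n, dtype=object)
    return X, y


@pytest.fixture(scope="session")
def three_clusters():
    """Three well-separated 2-D Gaussian clusters."""
    rng = np.random.default_rng(11)
    centers = {"a": (0, 0), "b": (10, 0), "c": (0, 10)}
    X, y = [], []
    for name, (cx, cy) in centers.items():
        X.append(rng.normal((cx, cy), 0.5, size=(15, 2)))
        y.extend([name] * 15)
    return np.vstack(X), np.array(y, dtype=object)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Small, strongly separated benchmark reused across model tests."""
    from herbres.synthetic_data import make_benchmark

    return make_benchmark(
        0.9,
        0.9,
        binary_per_class=28,
        multi_sizes={"ACCase": 6, "ALS": 6, "EPSPS": 5, "GS": 5, "HPPD": 4,
                     "PDS": 4, "PPO": 4},
        independent_resistant={"ACCase": 2, "ALS": 2, "EPSPS": 2, "GS": 2,
                               "HPPD": 2, "PDS": 2, "PPO": 2},
        independent_non_resistant=30,
        length_range=(200, 400),
        seed=5,
    )
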