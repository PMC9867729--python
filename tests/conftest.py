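import numpy as np
import pytest

from cellca import CountMatrix


@pytest.fixture
def diag2():
    """2x2 diagonal table [[2,0],[0,2]] — maximal association."""
    return CountMatrix([[2.0, 0.0], [0.0, 2.0]], ["g1", "g2"], ["c1", "c2"])


@pytest.fixture
def uniform2():
    """2x2 all-ones table — exact row/column independence."""
    return CountMatrix(np.ones((2, 2)), ["g1", "g2"], ["c1", "c2"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_table(rng, m, n, low=0, high=10):
    """Random integer table with no zero margins (resampled until valid)."""
    while True:
        X = rng.integers(low, high, size=(m, n)).astype(float)
        if X.sum(axis=1).min() > 0 and X.sum(axis=0).min() > 0:
            return CountMatrix(
                X,
                [f"g{i}" for i in range(m)],
                [f"c{j}" for j in range(n)],
            )


def chi2_oracle(X):
    """Brute-force Pearson chi-squared: sum (O-E)^2 / E, E from margins."""
    X = np.asarray(X, dtype=float)
    N = X.sum()
    E = np.outer(X.sum(axis=1), X.sum(axis=0)) / N
    return float(((X - E) ** 2 / E).sum())


def ari_oracle(a, b):
    """Pair-counting ARI over all n-choose-2 pairs (Hubert-Arabie)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    same_a = same_b = same_both = 0
    pairs = n * (n - 1) / 2
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            same_a += sa
            same_b += sb
            same_both += sa and sb
    expected = same_a * same_b / pairs
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0 if np.array_equal(
            np.unique(a, return_inverse=True)[1],
            np.unique(b, return_inverse=True)[1],
        ) else 0.0
    return (same_both - expected) / (max_index - expected)
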