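"""CFS: discretization, symmetrical uncertainty, merit formula, and the
best-first search against exhaustive and greedy oracles."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from riboclass import (
    CFSSelector,
    EqualFrequencyDiscretizer,
    best_first_select,
    cfs_merit,
    symmetrical_uncertainty,
)
from riboclass.cfs import discretize


# -- independent oracle helpers (Counter/math based, no package internals) --

def oracle_entropy(v):
    c = Counter(v)
    n = len(v)
    return -sum((k / n) * math.log2(k / n) for k in c.values())


def oracle_su(a, b):
    ha, hb = oracle_entropy(a), oracle_entropy(b)
    if ha + hb == 0:
        return 0.0
    hab = oracle_entropy(list(zip(a, b)))
    return max(0.0, min(1.0, 2 * (ha + hb - hab) / (ha + hb)))


def oracle_best_subset(D, y, n_features):
    """Exhaustive CFS maximum over all non-empty subsets."""
    cols = [list(D[:, j]) for j in range(n_features)]
    yl = list(y)
    best = 0.0
    for r in range(1, n_features + 1):
        for S in itertools.combinations(range(n_features), r):
            rcf = sum(oracle_su(cols[j], yl) for j in S)
            rff = sum(oracle_su(cols[a], cols[b]) for a, b in itertools.combinations(S, 2))
            best = max(best, rcf / math.sqrt(r + 2 * rff))
    return best


# -- discretization --

def test_discretizer_equal_frequency_bins():
    X = np.arange(1, 11, dtype=float).reshape(-1, 1)
    d = EqualFrequencyDiscretizer(n_bins=5).fit(X)
    bins = d.transform(X).ravel()
    assert Counter(bins) == {0: 2, 1: 2, 2: 2, 3: 2, 4: 2}


def test_discretizer_constant_feature_single_bin():
    X = np.full((20, 1), 7.0)
    bins = EqualFrequencyDiscretizer(n_bins=10).fit(X).transform(X)
    assert set(bins.ravel()) == {0}


def test_discretizer_reuses_training_cuts_on_new_data():
    X = np.arange(100, dtype=float).reshape(-1, 1)
    d = EqualFrequencyDiscretizer(n_bins=4).fit(X)
    held_out = np.array([[-5.0], [50.0], [500.0]])
    assert d.transform(held_out).ravel().tolist() == [0, 2, 3]


def test_discretizer_ties_share_a_bin():
    X = np.array([[1.0]] * 6 + [[2.0]] * 6)
    bins = EqualFrequencyDiscretizer(n_bins=4).fit(X).transform(X).ravel()
    assert len(set(bins[:6])) == 1 and len(set(bins[6:])) == 1


def test_discretizer_rejects_bad_bins():
    with pytest.raises(ValueError):
        EqualFrequencyDiscretizer(n_bins=1).fit(np.zeros((3, 1)))


# -- symmetrical uncertainty --

def test_su_identity_and_symmetry(rng):
    x = rng.integers(0, 4, 200)
    y = rng.integers(0, 4, 200)
    assert symmetrical_uncertainty(x, x) == pytest.approx(1.0)
    assert symmetrical_uncertainty(x, y) == pytest.approx(symmetrical_uncertainty(y, x))


def test_su_independent_uniform_near_zero():
    rng = np.random.default_rng(7)
    x = rng.integers(0, 2, 10_000)
    y = rng.integers(0, 2, 10_000)
    assert symmetrical_uncertainty(x, y) < 0.01


def test_su_matches_oracle_on_random_vectors(rng):
    for _ in range(10):
        x = rng.integers(0, 5, 60)
        y = rng.integers(0, 3, 60)
        assert symmetrical_uncertainty(x, y) == pytest.approx(
            oracle_su(list(x), list(y)), abs=1e-12
        )


def test_su_length_mismatch():
    with pytest.raises(ValueError):
        symmetrical_uncertainty([0, 1], [0, 1, 2])


# -- merit formula --

def test_merit_formula_reductions():
    rcf = {0: 0.6, 1: 0.6}
    # single feature: merit == class correlation
    assert cfs_merit([0], rcf, {}) == pytest.approx(0.6)
    # perfectly redundant pair: merit stays r
    pair_red = {0: {1: 1.0}, 1: {0: 1.0}}
    assert cfs_merit([0, 1], rcf, pair_red) == pytest.approx(0.6)
    # independent pair: merit grows by sqrt(2)
    pair_ind = {0: {1: 0.0}, 1: {0: 0.0}}
    assert cfs_merit([0, 1], rcf, pair_ind) == pytest.approx(0.6 * math.sqrt(2))
    with pytest.raises(ValueError):
        cfs_merit([], rcf, {})


def test_duplicate_feature_never_raises_merit(rng):
    # adding an exact duplicate (SU=1 with the original) cannot help
    r = 0.7
    rcf = {0: r, 1: r}
    pair = {0: {1: 1.0}, 1: {0: 1.0}}
    assert cfs_merit([0, 1], rcf, pair) <= cfs_merit([0], rcf, {}) + 1e-12


# -- best-first search --

def test_perfect_feature_is_selected(rng):
    n = 60
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 5))
    X[:, 2] = y  # feature 2 equals the class
    res = best_first_select(X, labels=y, max_stale=5, n_bins=4)
    assert 2 in res.indices
    assert res.merit == pytest.approx(1.0, abs=1e-9)


def test_all_constant_features_return_empty_subset():
    X = np.ones((20, 4))
    y = np.array([0, 1] * 10)
    with pytest.warns(UserWarning, match="uninformative"):
        res = best_first_select(X, labels=y)
    assert res.indices == [] and res.merit == 0.0


@pytest.mark.parametrize("trial", range(10))
def test_best_first_matches_exhaustive_on_six_features(trial):
    rng = np.random.default_rng(1000 + trial)
    n = 40
    X = rng.integers(0, 5, size=(n, 6)).astype(float)
    y = (X[:, 0] + X[:, 1] + rng.integers(0, 3, n) > 5).astype(int)
    res = best_first_select(X, labels=y, max_stale=6, n_bins=4)
    D, _ = discretize(X, n_bins=4)
    assert res.merit == pytest.approx(oracle_best_subset(D, y, 6), abs=1e-9)
    # self-consistency: stored merit equals merit recomputed from stored names
    cols = {j: list(D[:, j]) for j in res.indices}
    rcf = {j: oracle_su(cols[j], list(y)) for j in res.indices}
    pair = {
        frozenset((a, b)): oracle_su(cols[a], cols[b])
        for a, b in itertools.combinations(res.indices, 2)
    }
    assert cfs_merit(res.indices, rcf, pair) == pytest.approx(res.merit, abs=1e-9)


def test_best_first_beats_greedy_forward(rng):
    # greedy forward-only search is a lower bound on best-first with backtracking
    for trial in range(5):
        r = np.random.default_rng(50 + trial)
        X = r.integers(0, 4, size=(50, 8)).astype(float)
        y = (X[:, 0] + X[:, 3] > 3).astype(int)
        res = best_first_select(X, labels=y, max_stale=8, n_bins=4)
        D, _ = discretize(X, n_bins=4)
        cols = [list(D[:, j]) for j in range(8)]
        yl = list(y)

        def merit_of(S):
            rcf = sum(oracle_su(cols[j], yl) for j in S)
            rff = sum(oracle_su(cols[a], cols[b]) for a, b in itertools.combinations(S, 2))
            return rcf / math.sqrt(len(S) + 2 * rff)

        # greedy forward
        S, best = [], 0.0
        while True:
            cands = [(merit_of(S + [j]), j) for j in range(8) if j not in S]
            m, j = max(cands)
            if m <= best:
                break
            best, S = m, S + [j]
        assert res.merit >= best - 1e-9


def test_selector_estimator_transform_is_column_subset(rng):
    import pandas as pd

    n = 80
    y = rng.integers(0, 2, n)
    X = pd.DataFrame(
        rng.integers(0, 6, size=(n, 6)).astype(float), columns=list("abcdef")
    )
    X["b"] = y * 3.0
    sel = CFSSelector(n_bins=4).fit(X, y)
    assert "b" in sel.selected_names_
    out = sel.transform(X)
    assert list(out.columns) == sel.selected_names_
    # array input goes through the same index-based path
    out2 = sel.transform(X.to_numpy())
    assert np.array_equal(out2, out.to_numpy())
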