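"""Correlation-based feature subset selection (CFS) with best-first search.

CFS scores a candidate subset S of features by the merit

    merit(S) = s * r_cf / sqrt(s + s*(s-1) * r_ff)

where s = |S|, r_cf is the mean feature-class correlation and r_ff the mean
pairwise feature-feature correlation within S. High merit requires features
that each predict the class yet are mutually non-redundant. The correlation
measure is symmetrical uncertainty SU(x, y) = 2*[H(x)+H(y)-H(x,y)] / [H(x)+H(y)]
over equal-frequency discretized counts (entropy H in bits; SU in [0, 1]).

The subset space is searched forward best-first with backtracking: an open
list of subsets keyed by merit, the best open subset expanded by adding each
unused feature, stopping after `max_stale` consecutive expansions that fail
to improve the global best. Ties are broken by column order, so the search
is deterministic for a given matrix.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .kmers import KmerFeatureMatrix

__all__ = [
    "EqualFrequencyDiscretizer",
    "discretize",
    "symmetrical_uncertainty",
    "cfs_merit",
    "best_first_select",
    "FeatureSubset",
    "CFSSelector",
]


class EqualFrequencyDiscretizer(TransformerMixin, BaseEstimator):
    """Per-feature equal-frequency binning with stored cut points.

    Each distinct training value is assigned a bin from the midrank of its
    occurrences (``ceil(midrank * n_bins / n) - 1``, then compressed to
    consecutive indices), so equal values always share a bin, a constant
    feature occupies the single bin 0, and a heavily skewed two-valued
    feature still splits into two bins. Cut points are the midpoints between
    adjacent distinct values whose bins differ; ``transform`` reuses them,
    so held-out data is binned with the training discretization.
    """

    def __init__(self, n_bins: int = 10):
        self.n_bins = n_bins

    def fit(self, X, y=None) -> "EqualFrequencyDiscretizer":
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        cuts = []
        for j in range(X.shape[1]):
            u, counts = np.unique(X[:, j], return_counts=True)
            if len(u) < 2:
                cuts.append(np.empty(0))
                continue
            midrank = np.cumsum(counts) - (counts - 1) / 2.0
            bins = np.ceil(midrank * self.n_bins / n).astype(int)
            boundary = np.flatnonzero(np.diff(bins) > 0)
            cuts.append((u[boundary] + u[boundary + 1]) / 2.0)
        self.cut_points_ = cuts
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        out = np.empty(X.shape, dtype=np.int64)
        for j, cuts in enumerate(self.cut_points_):
            out[:, j] = np.searchsorted(cuts, X[:, j], side="right")
        return out


def discretize(matrix: KmerFeatureMatrix | np.ndarray, n_bins: int = 10):
    """Equal-frequency discretization; returns (binned array, fitted discretizer)."""
    X = matrix.X.to_numpy() if isinstance(matrix, KmerFeatureMatrix) else np.asarray(matrix)
    disc = EqualFrequencyDiscretizer(n_bins=n_bins).fit(X)
    return disc.transform(X), disc


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x: Sequence[int], y: Sequence[int]) -> float:
    """SU(x, y) in [0, 1]; 0 when both vectors carry no information."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    _, xc = np.unique(x, return_inverse=True)
    _, yc = np.unique(y, return_inverse=True)
    nx, ny = xc.max() + 1, yc.max() + 1
    joint = np.bincount(xc * ny + yc, minlength=nx * ny)
    hx = _entropy_from_counts(np.bincount(xc, minlength=nx))
    hy = _entropy_from_counts(np.bincount(yc, minlength=ny))
    hxy = _entropy_from_counts(joint)
    denom = hx + hy
    if denom == 0.0:
        return 0.0
    return float(np.clip(2.0 * (hx + hy - hxy) / denom, 0.0, 1.0))


def _su_profile(D: np.ndarray, v: np.ndarray) -> np.ndarray:
    """SU of every column of the discretized matrix D against vector v."""
    v = np.asarray(v)
    _, vc = np.unique(v, return_inverse=True)
    nv = vc.max() + 1
    hv = _entropy_from_counts(np.bincount(vc, minlength=nv))
    out = np.empty(D.shape[1])
    for j in range(D.shape[1]):
        col = D[:, j]
        nc = col.max() + 1
        hx = _entropy_from_counts(np.bincount(col, minlength=nc))
        hxy = _entropy_from_counts(np.bincount(col * nv + vc, minlength=nc * nv))
        denom = hx + hv
        out[j] = 0.0 if denom == 0.0 else 2.0 * (hx + hv - hxy) / denom
    return np.clip(out, 0.0, 1.0)


def cfs_merit(
    subset: Sequence[int] | Sequence[str],
    class_corr,
    pairwise_corr,
) -> float:
    """CFS merit of a subset given feature-class and feature-feature SU.

    `class_corr` maps feature -> SU with the class; `pairwise_corr` maps an
    unordered feature pair (given as a frozenset or looked up symmetrically
    via ``pairwise_corr[i][j]``) -> SU. A single feature's merit reduces to
    its class correlation.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    s = len(subset)
    sum_rcf = float(sum(class_corr[f] for f in subset))
    sum_rff = 0.0
    for a in range(s):
        for b in range(a + 1, s):
            i, j = subset[a], subset[b]
            try:
                sum_rff += float(pairwise_corr[i][j])
            except (TypeError, IndexError, KeyError):
                sum_rff += float(pairwise_corr[frozenset((i, j))])
    return sum_rcf / np.sqrt(s + 2.0 * sum_rff)


@dataclass
class FeatureSubset:
    """Result of a CFS search: feature names in selection order plus merit."""

    names: list[str]
    indices: list[int]
    merit: float
    trace: list[tuple[int, float]] = field(default_factory=list)


def best_first_select(
    matrix: KmerFeatureMatrix | np.ndarray,
    labels: Sequence | None = None,
    max_stale: int = 5,
    n_bins: int = 10,
    feature_names: Sequence[str] | None = None,
) -> FeatureSubset:
    """Forward best-first CFS search with backtracking.

    Returns the best subset found, its merit, and the trace of (size, merit)
    improvements. If every feature is constant (all class correlations zero)
    an empty subset with merit 0 is returned with a warning.
    """
    if isinstance(matrix, KmerFeatureMatrix):
        X = matrix.X.to_numpy()
        names = list(matrix.X.columns)
        y = matrix.families.to_numpy() if labels is None else np.asarray(labels)
    else:
        X = np.asarray(matrix)
        if labels is None:
            raise ValueError("labels are required for an array input")
        y = np.asarray(labels)
        names = list(feature_names) if feature_names is not None else [str(j) for j in range(X.shape[1])]
    if X.shape[0] < 2 or len(np.unique(y)) < 2:
        raise ValueError("need at least 2 rows and 2 classes")

    D, _ = discretize(X, n_bins=n_bins)
    _, yc = np.unique(y, return_inverse=True)
    rcf = _su_profile(D, yc)
    n_feat = X.shape[1]

    if np.all(rcf == 0.0):
        warnings.warn("all features are uninformative; returning an empty subset")
        return FeatureSubset(names=[], indices=[], merit=0.0, trace=[])

    pair_cache: dict[int, np.ndarray] = {}

    def pair_vec(i: int) -> np.ndarray:
        if i not in pair_cache:
            pair_cache[i] = _su_profile(D, D[:, i])
        return pair_cache[i]

    # heap entries: (-merit, tiebreak, node in insertion order, sum_rcf, sum_rff)
    counter = 0
    open_list: list[tuple[float, int, tuple[int, ...], float, float]] = []
    heapq.heappush(open_list, (0.0, counter, (), 0.0, 0.0))
    visited: set[frozenset[int]] = set()
    best_merit, best_node = 0.0, ()
    trace: list[tuple[int, float]] = []
    stale = 0

    while open_list and stale <= max_stale:
        _, _, node, sum_rcf, sum_rff = heapq.heappop(open_list)
        key = frozenset(node)
        if key in visited:
            continue
        visited.add(key)

        s1 = len(node) + 1
        su_to_node = np.zeros(n_feat)
        for i in node:
            su_to_node += pair_vec(i)
        child_rcf = sum_rcf + rcf
        child_rff = sum_rff + su_to_node
        merit = child_rcf / np.sqrt(s1 + 2.0 * child_rff)
        if node:
            merit[list(node)] = -np.inf

        improved = False
        order = np.argsort(-merit, kind="stable")  # push best children first
        for j in order:
            m = merit[j]
            if not np.isfinite(m):
                continue
            counter += 1
            heapq.heappush(
                open_list, (-m, counter, node + (int(j),), float(child_rcf[j]), float(child_rff[j]))
            )
            if m > best_merit + 1e-12:
                best_merit, best_node = float(m), node + (int(j),)
                trace.append((len(best_node), best_merit))
                improved = True
        stale = 0 if improved else stale + 1

    indices = list(best_node)
    return FeatureSubset(
        names=[names[i] for i in indices], indices=indices, merit=best_merit, trace=trace
    )


class CFSSelector(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: fit runs the CFS best-first search on the
    training data, transform subsets columns (no refitting on held-out data).
    """

    def __init__(self, n_bins: int = 10, max_stale: int = 5):
        self.n_bins = n_bins
        self.max_stale = max_stale

    def fit(self, X, y) -> "CFSSelector":
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            arr = X.to_numpy()
        else:
            arr = np.asarray(X)
            names = [str(j) for j in range(arr.shape[1])]
        subset = best_first_select(
            arr, labels=y, max_stale=self.max_stale, n_bins=self.n_bins, feature_names=names
        )
        self.subset_ = subset
        self.selected_indices_ = subset.indices
        self.selected_names_ = subset.names
        self.merit_ = subset.merit
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_names_]
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        return X[:, self.selected_indices_]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.selected_names_, dtype=object)


def save_subset(subset: FeatureSubset, txt_path, json_path=None) -> None:
    """Serialize a subset: one k-mer per line, plus an optional JSON sidecar."""
    import json
    from pathlib import Path

    Path(txt_path).write_text("".join(f"{n}\n" for n in subset.names))
    if json_path is not None:
        payload = {
            "merit": round(subset.merit, 6),
            "n_selected": len(subset.names),
            "trace": [[s, round(m, 6)] for s, m in subset.trace],
        }
        Path(json_path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
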