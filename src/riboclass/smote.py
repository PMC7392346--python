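"""Synthetic Minority Over-sampling (SMOTE), implemented from scratch.

For each class below the target count, synthetic samples are generated by
repeatedly (round-robin over the class's rows in original order) taking a
sample x, drawing one of its k nearest same-class neighbors x_hat (Euclidean
distance, ties broken toward the lower row index), drawing u ~ Uniform[0, 1)
and emitting

    x_new = x + u * (x_hat - x)

until the class reaches the target. The default target "auto" equalizes all
classes to the majority count. Original rows are passed through unchanged and
precede all synthetic rows; every draw flows from a single seed, so a run is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = ["nearest_neighbors", "synthesize_sample", "smote_balance", "ResampleResult", "SMOTEResampler"]


def nearest_neighbors(X: np.ndarray, index: int, k: int) -> np.ndarray:
    """Indices of the k rows nearest to row `index` (self excluded).

    Distance ties resolve to the lower row index; k is clamped to n-1.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to have a neighbor")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    d = np.sqrt(((X - X[index]) ** 2).sum(axis=1))
    d[index] = np.inf
    order = np.argsort(d, kind="stable")  # stable sort => lower index wins ties
    return order[: min(k, X.shape[0] - 1)]


def synthesize_sample(x: np.ndarray, x_hat: np.ndarray, u: float) -> np.ndarray:
    """Linear interpolation x + u*(x_hat - x) with u in [0, 1)."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {x_hat.shape}")
    return x + u * (x_hat - x)


@dataclass
class ResampleResult:
    """Balanced data: originals first (original order), then synthetic rows."""

    X: np.ndarray
    y: np.ndarray
    counts_before: dict
    counts_after: dict
    provenance: np.ndarray  # "original" | "synthetic" per row
    parents: np.ndarray  # (n_synthetic, 2) original-row indices (sample, neighbor)
    seed: int

    @property
    def n_synthetic(self) -> int:
        return int((self.provenance == "synthetic").sum())


def smote_balance(
    X: np.ndarray,
    y: Sequence,
    k_neighbors: int = 5,
    target: str | Mapping = "auto",
    random_state: int = 0,
    round_counts: bool = False,
) -> ResampleResult:
    """Oversample every under-target class to the target count.

    ``target="auto"`` balances all classes to the size of the largest one; a
    mapping gives explicit per-class targets. ``round_counts`` rounds the
    synthetic feature values to integers for strict count semantics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite feature values")
    if k_neighbors < 1:
        raise ValueError(f"k_neighbors must be >= 1, got {k_neighbors}")

    classes, first_pos = np.unique(y, return_index=True)
    classes = classes[np.argsort(first_pos)]  # deterministic: first-appearance order
    counts_before = {c: int((y == c).sum()) for c in classes}
    if target == "auto":
        top = max(counts_before.values())
        targets = {c: top for c in classes}
    else:
        targets = {c: int(target.get(c, counts_before[c])) for c in classes}

    rng = np.random.default_rng(random_state)
    synth_rows: list[np.ndarray] = []
    synth_labels: list = []
    parents: list[tuple[int, int]] = []
    for c in classes:
        members = np.flatnonzero(y == c)
        n_new = targets[c] - len(members)
        if n_new <= 0:
            continue
        if len(members) < 2:
            raise ValueError(
                f"class {c!r} has a single sample and cannot be oversampled "
                "(SMOTE needs at least one same-class neighbor)"
            )
        Xc = X[members]
        d = cdist(Xc, Xc)
        np.fill_diagonal(d, np.inf)
        kk = min(k_neighbors, len(members) - 1)
        nbr = np.argsort(d, axis=1, kind="stable")[:, :kk]  # within-class indices
        for i in range(n_new):
            p = i % len(members)
            q = nbr[p, rng.integers(kk)]
            u = rng.random()
            row = synthesize_sample(Xc[p], Xc[q], u)
            if round_counts:
                row = np.rint(row)
            synth_rows.append(row)
            synth_labels.append(c)
            parents.append((int(members[p]), int(members[q])))

    if synth_rows:
        X_res = np.vstack([X, np.vstack(synth_rows)])
        y_res = np.concatenate([y, np.asarray(synth_labels, dtype=y.dtype)])
    else:
        X_res, y_res = X.copy(), y.copy()
    provenance = np.array(
        ["original"] * X.shape[0] + ["synthetic"] * len(synth_rows), dtype=object
    )
    counts_after = {c: int((y_res == c).sum()) for c in classes}
    return ResampleResult(
        X=X_res,
        y=y_res,
        counts_before=counts_before,
        counts_after=counts_after,
        provenance=provenance,
        parents=np.asarray(parents, dtype=np.int64).reshape(-1, 2),
        seed=random_state,
    )


class SMOTEResampler(BaseEstimator):
    """Estimator wrapper with an imblearn-style ``fit_resample`` interface."""

    def __init__(
        self,
        k_neighbors: int = 5,
        target: str | Mapping = "auto",
        random_state: int = 0,
        round_counts: bool = False,
    ):
        self.k_neighbors = k_neighbors
        self.target = target
        self.random_state = random_state
        self.round_counts = round_counts

    def fit_resample(self, X, y):
        self.result_ = smote_balance(
            X,
            y,
            k_neighbors=self.k_neighbors,
            target=self.target,
            random_state=self.random_state,
            round_counts=self.round_counts,
        )
        return self.result_.X, self.result_.y
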