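"""Model selection pipeline: 70/30 split, 10-fold cross-validated grid search
over six classifier families, SMOTE applied strictly inside training folds,
and winner selection by the composite valid score

    valid = 0.6 * F_macro + 0.2 * recall_macro + 0.2 * precision_macro.

The fold partition is computed once per run and reused for every
hyperparameter combination and for both the balanced and imbalanced arms, so
the two arms are scored on bit-identical validation folds. When balancing is
on, SMOTE sees only the training portion of each fold (and, for the final
model, only the full training split); validation folds and the test set are
never resampled.

Classifier internals are delegated to scikit-learn; everything around them —
the split, the fold protocol, the in-fold balancing, the scoring and the
selection rule — lives here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from ._random import substream, substream_int
from .smote import smote_balance

__all__ = [
    "DEFAULT_GRIDS",
    "FAST_GRIDS",
    "ModelSpec",
    "GridResult",
    "SplitSpec",
    "split_dataset",
    "valid_score",
    "grid_search_cv",
    "fit_predict",
    "ValidScoreGridSearchCV",
]

# The published hyperparameter grids, verbatim. Declaration order fixes
# tie-breaking in winner selection.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "KNN": {"n_neighbors": [2, 4, 6, 8, 10, 12, 14, 16]},
    "SVM": {"kernel": ["linear", "poly", "rbf", "sigmoid"]},
    "RF": {"n_estimators": [500, 1000, 2000], "max_depth": [10, 15, 20]},
    "GB": {
        "n_estimators": [500, 1000, 2000],
        "learning_rate": [0.01, 0.1, 0.05],
        "max_depth": [7, 9, 11, 15],
    },
    "MLP": {
        "hidden_layer_sizes": [(80, 80, 80), (100, 100, 100), (150, 150, 150)],
        "alpha": [1e-3, 1e-4],
        "solver": ["adam", "sgd"],
        "tol": [1e-8, 1e-7, 1e-6],
    },
    "GNB": {"var_smoothing": [1e-16, 1e-14, 1e-12]},
}

# Shrunk grids for quick runs; same families minus the slow ones.
FAST_GRIDS: dict[str, dict[str, list]] = {
    "KNN": {"n_neighbors": [4, 8]},
    "RF": {"n_estimators": [100], "max_depth": [10]},
    "GNB": {"var_smoothing": [1e-12]},
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family + hyperparameter combination."""

    family: str
    params: tuple[tuple[str, object], ...]  # hashable param mapping

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def label(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({inner})"


def expand_grids(grids: Mapping[str, Mapping[str, list]]) -> list[ModelSpec]:
    """All combinations, in declaration order (families, then grid product)."""
    specs = []
    for family, grid in grids.items():
        names = list(grid)
        for combo in itertools.product(*(grid[n] for n in names)):
            specs.append(ModelSpec(family, tuple(zip(names, combo))))
    return specs


def build_classifier(spec: ModelSpec, random_state: int):
    p = spec.param_dict
    if spec.family == "KNN":
        return KNeighborsClassifier(**p)
    if spec.family == "SVM":
        return SVC(random_state=random_state, **p)
    if spec.family == "RF":
        return RandomForestClassifier(random_state=random_state, **p)
    if spec.family == "GB":
        return GradientBoostingClassifier(random_state=random_state, **p)
    if spec.family == "MLP":
        return MLPClassifier(random_state=random_state, max_iter=400, **p)
    if spec.family == "GNB":
        return GaussianNB(**p)
    raise ValueError(f"unknown classifier family {spec.family!r}")


@dataclass
class SplitSpec:
    """Disjoint, exhaustive train/test id partition."""

    train_ids: list
    test_ids: list
    test_fraction: float
    stratified: bool
    seed: int


def split_dataset(
    ids: Sequence,
    families: Sequence,
    test_fraction: float = 0.3,
    stratified: bool = True,
    rng_seed: int = 0,
) -> SplitSpec:
    """Random train/test split, stratified by family by default.

    Per-family test counts are ``round(fraction * n)``; a singleton family
    goes wholly to training with a warning so every family stays trainable.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    ids = list(ids)
    families = list(families)
    if not ids:
        raise ValueError("empty input")
    rng = substream(rng_seed, "split")
    train: list = []
    test: list = []
    if stratified:
        fam_order = list(dict.fromkeys(families))
        for fam in fam_order:
            members = [i for i, f in zip(ids, families) if f == fam]
            if len(members) == 1:
                warnings.warn(f"family {fam!r} has a single member; kept in training")
                train.extend(members)
                continue
            perm = rng.permutation(len(members))
            n_test = min(int(round(test_fraction * len(members))), len(members) - 1)
            test.extend(members[j] for j in perm[:n_test])
            train.extend(members[j] for j in perm[n_test:])
    else:
        perm = rng.permutation(len(ids))
        n_test = int(round(test_fraction * len(ids)))
        test = [ids[j] for j in perm[:n_test]]
        train = [ids[j] for j in perm[n_test:]]
    return SplitSpec(
        train_ids=train, test_ids=test, test_fraction=test_fraction,
        stratified=stratified, seed=rng_seed,
    )


def valid_score(f_macro: float, recall_macro: float, precision_macro: float) -> float:
    """Composite model-selection score 0.6*F + 0.2*recall + 0.2*precision."""
    for name, v in (("f_macro", f_macro), ("recall_macro", recall_macro),
                    ("precision_macro", precision_macro)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return 0.6 * f_macro + 0.2 * recall_macro + 0.2 * precision_macro


def fold_partition(y: Sequence, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Stratified fold assignment tolerant of classes smaller than `folds`.

    Members of each class are shuffled and dealt round-robin, so a class with
    fewer members than folds appears in as many folds as it has members; the
    remaining validation folds simply lack that class.
    """
    y = np.asarray(y)
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    assignment = np.empty(len(y), dtype=np.int64)
    start = 0
    for c in list(dict.fromkeys(y)):
        members = np.flatnonzero(y == c)
        perm = rng.permutation(len(members))
        for pos, j in enumerate(perm):
            assignment[members[j]] = (start + pos) % folds
        start += len(members)  # stagger classes across folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


@dataclass
class GridResult:
    """Cross-validation outcome for a whole grid."""

    entries: list[dict]  # per combo: spec, per-fold (f, recall, precision), mean_valid
    winner: ModelSpec
    fold_val_indices: list[np.ndarray]
    audit: list[dict] = field(default_factory=list)  # per fold: leakage evidence

    def to_dict(self) -> dict:
        return {
            "winner": self.winner.label(),
            "combinations": [
                {
                    "model": e["spec"].label(),
                    "mean_valid_score": round(e["mean_valid"], 6),
                    "fold_scores": [
                        {"f_macro": round(f, 6), "recall_macro": round(r, 6),
                         "precision_macro": round(p, 6)}
                        for f, r, p in e["fold_scores"]
                    ],
                }
                for e in self.entries
            ],
        }


def _macro_scores(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """Macro precision/recall/F over the classes present in y_true."""
    labels = np.unique(y_true)
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    return float(f), float(r), float(p)


def grid_search_cv(
    X_train,
    y_train,
    grids: Mapping[str, Mapping[str, list]] = DEFAULT_GRIDS,
    folds: int = 10,
    balance: bool = True,
    rng_seed: int = 0,
    k_neighbors: int = 5,
) -> GridResult:
    """Grid search scored by the mean per-fold valid score.

    The fold partition is a deterministic function of (y_train, folds,
    rng_seed) alone, so balanced and imbalanced arms — and every combination —
    share it. With ``balance=True`` each fold's 9/10 training portion is
    SMOTE-balanced before fitting; the held-out fold is scored untouched.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    fold_val = fold_partition(y_train, folds, substream(rng_seed, "folds"))
    n = len(y_train)

    # Prepare per-fold training data once; identical across combinations.
    prepared = []
    audit = []
    for f, val_idx in enumerate(fold_val):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        if balance:
            res = smote_balance(
                X_train[train_idx], y_train[train_idx],
                k_neighbors=k_neighbors,
                random_state=substream_int(rng_seed, f"smote-fold-{f}"),
            )
            Xf, yf, n_synth = res.X, res.y, res.n_synthetic
        else:
            Xf, yf, n_synth = X_train[train_idx], y_train[train_idx], 0
        prepared.append((Xf, yf, val_idx))
        audit.append(
            {
                "fold": f,
                "val_indices": val_idx.tolist(),
                "train_indices": train_idx.tolist(),
                "n_train_original": int(len(train_idx)),
                "n_train_synthetic": int(n_synth),
            }
        )

    clf_seed = substream_int(rng_seed, "clf")
    entries = []
    for spec in expand_grids(grids):
        fold_scores = []
        for Xf, yf, val_idx in prepared:
            clf = build_classifier(spec, clf_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # MLP convergence on tiny folds
                clf.fit(Xf, yf)
                y_hat = clf.predict(X_train[val_idx])
            fold_scores.append(_macro_scores(y_train[val_idx], y_hat))
        mean_valid = float(np.mean([valid_score(*s) for s in fold_scores]))
        entries.append({"spec": spec, "fold_scores": fold_scores, "mean_valid": mean_valid})

    best = max(range(len(entries)), key=lambda i: entries[i]["mean_valid"])  # first max wins
    return GridResult(
        entries=entries, winner=entries[best]["spec"], fold_val_indices=fold_val, audit=audit
    )


def fit_predict(
    winner: ModelSpec,
    X_train,
    y_train,
    X_test,
    balance: bool = True,
    rng_seed: int = 0,
    k_neighbors: int = 5,
) -> np.ndarray:
    """Fit the winning model on the (optionally balanced) training split and
    predict the untouched test split."""
    if isinstance(X_train, pd.DataFrame) and isinstance(X_test, pd.DataFrame):
        if list(X_train.columns) != list(X_test.columns):
            raise ValueError("train and test feature columns differ in names or order")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[0] == 0:
        raise ValueError("empty test set")
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train and test feature counts differ")
    y_train = np.asarray(y_train)
    if balance:
        res = smote_balance(
            X_train, y_train, k_neighbors=k_neighbors,
            random_state=substream_int(rng_seed, "smote-final"),
        )
        X_fit, y_fit = res.X, res.y
    else:
        X_fit, y_fit = X_train, y_train
    clf = build_classifier(winner, substream_int(rng_seed, "clf"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_fit, y_fit)
        return clf.predict(X_test)


class ValidScoreGridSearchCV(ClassifierMixin, BaseEstimator):
    """Grid-searched classifier selected by the composite valid score.

    ``fit`` runs the leakage-safe cross-validated grid search, stores the full
    ``grid_result_``, then refits the winner on the (optionally balanced)
    training data. ``predict`` uses that final model.
    """

    def __init__(
        self,
        grids: Mapping[str, Mapping[str, list]] | None = None,
        folds: int = 10,
        balance: bool = True,
        k_neighbors: int = 5,
        random_state: int = 0,
    ):
        self.grids = grids
        self.folds = folds
        self.balance = balance
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit(self, X, y) -> "ValidScoreGridSearchCV":
        grids = DEFAULT_GRIDS if self.grids is None else self.grids
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.grid_result_ = grid_search_cv(
            X, y, grids=grids, folds=self.folds, balance=self.balance,
            rng_seed=self.random_state, k_neighbors=self.k_neighbors,
        )
        self.best_spec_ = self.grid_result_.winner
        if self.balance:
            res = smote_balance(
                X, y, k_neighbors=self.k_neighbors,
                random_state=substream_int(self.random_state, "smote-final"),
            )
            X_fit, y_fit = res.X, res.y
        else:
            X_fit, y_fit = X, y
        self.classifier_ = build_classifier(
            self.best_spec_, substream_int(self.random_state, "clf")
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.classifier_.fit(X_fit, y_fit)
        self.classes_ = self.classifier_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        return self.classifier_.predict(np.asarray(X, dtype=float))
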