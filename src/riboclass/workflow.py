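"""End-to-end experiment: featurize -> select -> (balance/train) x 2 arms ->
evaluate -> compare.

Both arms (SMOTE-balanced and imbalanced) run on the identical train/test
split and identical cross-validation folds; the only difference is whether
the training portions are resampled. The comparison is a per-metric Wilcoxon
signed-rank test over per-family values on the held-out test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cfs import CFSSelector, FeatureSubset
from .io import SequenceRecord
from .kmers import build_feature_matrix
from .metrics import MetricsTable, compare_metric_tables, confusion_matrix, per_class_metrics
from .pipeline import (
    DEFAULT_GRIDS,
    FAST_GRIDS,
    GridResult,
    fit_predict,
    grid_search_cv,
    split_dataset,
)

__all__ = ["ExperimentConfig", "ArmResult", "ExperimentResult", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Tunable knobs of a full run; ``fast()`` is the scaled-down profile."""

    k_min: int = 1
    k_max: int = 6
    n_bins: int = 10
    max_stale: int = 5
    folds: int = 10
    test_fraction: float = 0.3
    stratified: bool = True
    k_neighbors: int = 5
    metric_mode: str = "standard"
    grids: Mapping[str, Mapping[str, list]] = field(default_factory=lambda: DEFAULT_GRIDS)

    @classmethod
    def fast(cls, metric_mode: str = "standard") -> "ExperimentConfig":
        return cls(k_max=4, grids=FAST_GRIDS, metric_mode=metric_mode)

    def to_dict(self) -> dict:
        return {
            "k_min": self.k_min, "k_max": self.k_max, "n_bins": self.n_bins,
            "max_stale": self.max_stale, "folds": self.folds,
            "test_fraction": self.test_fraction, "stratified": self.stratified,
            "k_neighbors": self.k_neighbors, "metric_mode": self.metric_mode,
            "grids": {f: {k: [str(v) for v in vals] for k, vals in g.items()}
                      for f, g in self.grids.items()},
        }


@dataclass
class ArmResult:
    balanced: bool
    grid_result: GridResult
    predictions: pd.Series  # index: test ids, values: predicted family
    metrics: MetricsTable


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seed: int
    families: list[str]
    split_train_ids: list
    split_test_ids: list
    selected: FeatureSubset
    arms: dict[str, ArmResult]  # "balanced" | "imbalanced"
    comparison: dict  # per-metric Wilcoxon between the two arms


def run_experiment(
    records: Sequence[SequenceRecord],
    seed: int = 0,
    config: ExperimentConfig | None = None,
) -> ExperimentResult:
    """Run the full two-arm study on a labeled record set."""
    config = config or ExperimentConfig()
    matrix = build_feature_matrix(records, config.k_min, config.k_max)
    families = list(dict.fromkeys(matrix.families))

    split = split_dataset(
        matrix.ids, list(matrix.families), test_fraction=config.test_fraction,
        stratified=config.stratified, rng_seed=seed,
    )
    X_train = matrix.X.loc[split.train_ids]
    y_train = matrix.families.loc[split.train_ids].to_numpy()
    X_test = matrix.X.loc[split.test_ids]
    y_test = matrix.families.loc[split.test_ids].to_numpy()

    # Feature selection fits on the training split only (leakage-free) and is
    # shared by both arms, mirroring a selection step upstream of balancing.
    selector = CFSSelector(n_bins=config.n_bins, max_stale=config.max_stale).fit(
        X_train, y_train
    )
    Xtr = selector.transform(X_train)
    Xte = selector.transform(X_test)

    arms: dict[str, ArmResult] = {}
    for name, balance in (("imbalanced", False), ("balanced", True)):
        grid = grid_search_cv(
            Xtr.to_numpy(), y_train, grids=config.grids, folds=config.folds,
            balance=balance, rng_seed=seed, k_neighbors=config.k_neighbors,
        )
        y_hat = fit_predict(
            grid.winner, Xtr, y_train, Xte, balance=balance,
            rng_seed=seed, k_neighbors=config.k_neighbors,
        )
        cm = confusion_matrix(y_test, y_hat, families=families)
        arms[name] = ArmResult(
            balanced=balance,
            grid_result=grid,
            predictions=pd.Series(y_hat, index=split.test_ids, name="predicted"),
            metrics=per_class_metrics(cm, mode=config.metric_mode),
        )

    comparison = compare_metric_tables(arms["balanced"].metrics, arms["imbalanced"].metrics)
    return ExperimentResult(
        config=config,
        seed=seed,
        families=families,
        split_train_ids=split.train_ids,
        split_test_ids=split.test_ids,
        selected=selector.subset_,
        arms=arms,
        comparison=comparison,
    )
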