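"""Permutation feature importance, top-p% retention, and retraining.

Importance of a feature is the drop in the deployed ensemble's score
(negative MSE) when that feature's column is randomly permuted, averaged
over several independent shuffle sets on a (sub)sample of the data. The
shuffle-set distribution also yields a dispersion and a one-sided p-value
(H0: importance <= 0). Features are then ranked and the top fraction
(presets 20%, 10% and 3% — RF20/RF10/RF3) is retained for a full retraining
on the restricted columns, which controls the feature-to-sample ratio and
with it the overfitting risk of wide omics feature tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import PredictorBundle, fit_predictor

__all__ = [
    "ImportanceRanking",
    "ReductionPlan",
    "permutation_importance",
    "reduce_features",
    "retrain_reduced",
]

DEFAULT_N_SHUFFLE_SETS = 10
DEFAULT_SUBSAMPLE_SIZE = 5000
_MAX_SEED = 2**31 - 1


@dataclass
class ImportanceRanking:
    """Per-feature permutation importance with shuffle-set statistics."""

    table: pd.DataFrame  # columns: feature, importance, dispersion, p_value, rank
    n_shuffle_sets: int
    subsample_size: int

    @property
    def ordering(self) -> list[str]:
        return list(self.table["feature"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_shuffle_sets: int = 0, subsample_size: int = 0):
        return cls(pd.read_csv(path, sep="\t"), n_shuffle_sets, subsample_size)


@dataclass
class ReductionPlan:
    """Top-fraction feature retention derived from an importance ordering."""

    fraction: float
    retained: list[str]


def permutation_importance(
    bundle: PredictorBundle,
    features: pd.DataFrame,
    labels: np.ndarray,
    n_shuffle_sets: int = DEFAULT_N_SHUFFLE_SETS,
    subsample_size: int = DEFAULT_SUBSAMPLE_SIZE,
    seed: int = 0,
) -> ImportanceRanking:
    """Rank features by ensemble-score drop under column permutation.

    ``features`` is samples x features of raw enrichment scores with labels
    aligned; ``subsample_size`` is capped at the number of samples. The
    permutation RNG for each feature is derived from the master seed and the
    feature index so rankings are reproducible feature-by-feature.
    """
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples for permutation importance")
    if features.shape[0] != n:
        raise ValueError("features and labels are misaligned")
    missing = [f for f in bundle.feature_names if f not in features.columns]
    if missing:
        raise ValueError(f"features absent from the provided data: {missing[:10]}")

    rng = np.random.default_rng(seed % _MAX_SEED)
    size = min(subsample_size, n)
    idx = rng.choice(n, size=size, replace=False) if size < n else np.arange(n)
    sub = features.iloc[idx].loc[:, bundle.feature_names].reset_index(drop=True)
    y_sub = y[idx]

    base_pred = bundle.predict(sub)
    base_score = -float(np.mean((base_pred - y_sub) ** 2))

    records = []
    for f_idx, feat in enumerate(bundle.feature_names):
        f_rng = np.random.default_rng((seed * 100003 + f_idx) % _MAX_SEED)
        # stack all shuffle sets of this feature into one batched prediction
        tiled = pd.concat([sub] * n_shuffle_sets, ignore_index=True)
        col = sub[feat].to_numpy()
        permuted = np.concatenate([col[f_rng.permutation(size)] for _ in range(n_shuffle_sets)])
        tiled[feat] = permuted
        pred = bundle.predict(tiled).reshape(n_shuffle_sets, size)
        scores = -np.mean((pred - y_sub[None, :]) ** 2, axis=1)
        drops = base_score - scores  # positive = feature mattered
        importance = float(np.mean(drops))
        dispersion = float(np.std(drops, ddof=1)) if n_shuffle_sets > 1 else 0.0
        if n_shuffle_sets > 1 and dispersion > 0:
            p_value = float(stats.ttest_1samp(drops, 0.0, alternative="greater").pvalue)
        else:
            p_value = 1.0 if importance <= 0 else 0.5
        records.append((feat, importance, dispersion, p_value))

    table = pd.DataFrame(records, columns=["feature", "importance", "dispersion", "p_value"])
    table = table.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceRanking(table, n_shuffle_sets=n_shuffle_sets, subsample_size=size)


def reduce_features(ranking: ImportanceRanking, fraction: float) -> ReductionPlan:
    """Retain the top max(1, floor(fraction * F)) features of the ranking."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ordering = ranking.ordering
    n_keep = max(1, math.floor(fraction * len(ordering)))
    return ReductionPlan(fraction=fraction, retained=ordering[:n_keep])


def retrain_reduced(
    features_raw: pd.DataFrame,
    labels: np.ndarray,
    plan: ReductionPlan,
    config,
    compound_id: str = "compound",
) -> PredictorBundle:
    """Full training + ensembling on the plan's restricted feature columns.

    The hyperparameter search is re-run from scratch on the reduced table
    (recorded in provenance); the returned bundle's provenance also records
    the retained fraction.
    """
    missing = [f for f in plan.retained if f not in features_raw.columns]
    if missing:
        raise ValueError(f"plan features absent from data: {missing[:10]}")
    # keep the original column order so a fraction of 1.0 reproduces the
    # unreduced training run exactly (column order can steer tree tie-breaks)
    keep = set(plan.retained)
    reduced = features_raw.loc[:, [f for f in features_raw.columns if f in keep]]
    return fit_predictor(
        reduced, labels, config, compound_id, feature_fraction=plan.fraction
    )
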