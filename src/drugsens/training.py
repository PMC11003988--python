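"""Per-compound supervised regression over nine base learner families.

Every compound is trained independently: its mechanism of action determines
which learning family works best, so the engine runs a random hyperparameter
search within each of nine families — three gradient-boosted tree variants,
two nearest-neighbor variants (uniform / distance weighting), two
feed-forward neural-network architectures, a random forest and extremely
randomized trees — and scores each trial by out-of-fold (OOF) mean squared
error under repeated k-fold cross-validation. The best trial per family is
kept together with its OOF prediction vector, which later feeds the
second-level weighted ensemble.

Validation scores are negative OOF MSE: values closer to zero are better.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from lightgbm import LGBMRegressor
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.compose import TransformedTargetRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "ROSTER",
    "TrainingConfig",
    "BaseModelResult",
    "train_compound",
    "validation_score",
    "cohort_filter",
    "load_search_spaces",
]

#: Fixed roster of the nine base learner families, in tie-break order.
ROSTER: tuple[str, ...] = (
    "lightgbm",
    "lightgbm_xt",
    "lightgbm_large",
    "knn_uniform",
    "knn_distance",
    "mlp",
    "mlp_deep",
    "random_forest",
    "extra_trees",
)

_MAX_SEED = 2**31 - 1


def _derive_seed(*parts) -> int:
    """Deterministic child seed < 2^31 from arbitrary hashable parts."""
    h = 0
    for p in parts:
        for ch in str(p):
            h = (h * 1000003 + ord(ch)) % _MAX_SEED
    return h


def load_search_spaces() -> dict:
    """Load the versioned per-family random-search spaces shipped with the package."""
    text = resources.files("drugsens").joinpath("search_spaces.yaml").read_text()
    spaces = yaml.safe_load(text)
    spaces.pop("version", None)
    return spaces


def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in space.items():
        if isinstance(spec, list):
            params[name] = spec[int(rng.integers(len(spec)))]
        elif isinstance(spec, dict) and "log_uniform" in spec:
            lo, hi = spec["log_uniform"]
            params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif isinstance(spec, dict) and "uniform" in spec:
            lo, hi = spec["uniform"]
            params[name] = float(rng.uniform(lo, hi))
        elif isinstance(spec, dict) and "int_uniform" in spec:
            lo, hi = spec["int_uniform"]
            params[name] = int(rng.integers(lo, hi + 1))
        else:
            raise ValueError(f"unrecognised search-space entry {name}: {spec!r}")
    return params


class StandardizedTargetNet(TransformedTargetRegressor):
    """Target-standardized feed-forward net with a degenerate-target guard.

    A constant label vector standardizes to all zeros; gradient training
    then returns an approximate rather than exact constant, so that case is
    handled by predicting the constant directly.
    """

    def fit(self, X, y, **fit_params):
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            self.constant_ = float(y[0])
            return self
        self.constant_ = None
        return super().fit(X, y, **fit_params)

    def predict(self, X, **predict_params):
        if getattr(self, "constant_", None) is not None:
            return np.full(np.asarray(X).shape[0], self.constant_)
        return super().predict(X, **predict_params)


def build_estimator(family: str, params: dict, seed: int, n_train: int):
    """Construct an unfitted estimator for one family/hyperparameter draw."""
    params = dict(params)
    if family in ("lightgbm", "lightgbm_xt", "lightgbm_large"):
        extra = {"extra_trees": True} if family == "lightgbm_xt" else {}
        return LGBMRegressor(
            random_state=seed, n_jobs=1, deterministic=True, force_row_wise=True,
            verbose=-1, **extra, **params,
        )
    if family in ("knn_uniform", "knn_distance"):
        weights = "uniform" if family == "knn_uniform" else "distance"
        params["n_neighbors"] = int(min(params["n_neighbors"], max(1, n_train)))
        return KNeighborsRegressor(weights=weights, n_jobs=1, **params)
    if family in ("mlp", "mlp_deep"):
        h = int(params.pop("hidden_units"))
        hidden = (h,) if family == "mlp" else (h, h)
        # standardize the regression target: AUC labels sit far from zero and
        # adam on the raw scale stalls at the label mean at desk-scale epochs
        return StandardizedTargetNet(
            regressor=MLPRegressor(
                hidden_layer_sizes=hidden, random_state=seed, solver="adam",
                early_stopping=False, **params,
            ),
            transformer=StandardScaler(),
        )
    if family == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if family == "extra_trees":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown family {family!r}")


@dataclass
class TrainingConfig:
    """Knobs for the per-compound training engine.

    The full-scale settings (``n_trials=512, repeats=3``) match large-cohort
    runs; defaults are desk-scale and overridable.
    """

    k: int = 5
    repeats: int = 1
    n_trials: int = 16
    seed: int = 0
    condition: str = "base"  # base | glioma_plus | metadata_plus
    families: tuple[str, ...] = ROSTER

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1 or self.n_trials < 1:
            raise ValueError("repeats and n_trials must be >= 1")
        if tuple(self.families) != ROSTER:
            raise ValueError("the learner roster is fixed at the nine standard families")
        if self.condition not in ("base", "glioma_plus", "metadata_plus"):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class BaseModelResult:
    """Best random-search trial of one family: OOF predictions + fold models."""

    family: str
    params: dict
    oof: np.ndarray
    validation_score: float  # -MSE of OOF vs labels; <= 0
    fold_models: list = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean prediction over the fitted fold models."""
        with warnings.catch_warnings():
            # lightgbm invents "Column_i" feature names on numpy fits and
            # sklearn then warns on every numpy predict; contract here is
            # positional columns throughout
            warnings.filterwarnings("ignore", message="X does not have valid feature names")
            preds = np.stack([m.predict(X) for m in self.fold_models])
        return preds.mean(axis=0)


def validation_score(oof: np.ndarray, labels: np.ndarray) -> float:
    """Negative mean squared error; closer to zero is better."""
    oof = np.asarray(oof, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if oof.shape != labels.shape or oof.size == 0:
        raise ValueError("oof and labels must have equal nonzero length")
    return float(-np.mean((oof - labels) ** 2))


def _oof_evaluate(family, params, X, y, k, repeats, seed):
    """Fit one trial under r-repeat k-fold CV; return mean OOF vector and fold models."""
    n = len(y)
    oof_sum = np.zeros(n)
    models = []
    for r in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=(seed + r) % _MAX_SEED)
        for train_idx, test_idx in kf.split(X):
            est = build_estimator(family, params, seed=(seed + r) % _MAX_SEED,
                                  n_train=len(train_idx))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # MLP convergence chatter at desk scale
                est.fit(X[train_idx], y[train_idx])
                oof_sum[test_idx] += est.predict(X[test_idx])
            models.append(est)
    return oof_sum / repeats, models


def train_compound(
    features: pd.DataFrame, labels: np.ndarray, config: TrainingConfig
) -> list[BaseModelResult]:
    """Random-search each family and keep its best trial by OOF MSE.

    ``features`` is samples x features on the [0,1] scale; ``labels`` is the
    aligned AUC vector. Results are fully reproducible for a given seed on a
    fixed platform.
    """
    X = np.asarray(features.to_numpy(dtype=float))
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("features and labels are misaligned")
    if n < 2 * config.k:
        raise ValueError(
            f"need at least 2k={2 * config.k} samples (got {n}); use a smaller k"
        )
    if np.ptp(y) == 0:
        warnings.warn("constant label vector; models will fit the constant", stacklevel=2)

    results: list[BaseModelResult] = []
    for family in config.families:
        space = load_search_spaces()[family]
        rng = np.random.default_rng(_derive_seed(config.seed, family, "search"))
        best: BaseModelResult | None = None
        for trial in range(config.n_trials):
            params = _sample_params(space, rng)
            trial_seed = _derive_seed(config.seed, family, trial)
            oof, models = _oof_evaluate(
                family, params, X, y, config.k, config.repeats, trial_seed
            )
            score = validation_score(oof, y)
            if best is None or score > best.validation_score:
                best = BaseModelResult(family, params, oof, score, models)
        assert best is not None
        logger.debug("family %s best score %.5f params %s", family, best.validation_score, best.params)
        results.append(best)
    return results


def cohort_filter(
    features: pd.DataFrame,
    labels: np.ndarray,
    metadata: pd.DataFrame,
    disease_label: str,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Restrict a training table to samples with one disease label.

    Implements the cohort-narrowing condition (e.g. glioma-only training):
    rows whose ``disease_label`` matches are retained; retaining zero rows is
    an error.
    """
    if "disease_label" not in metadata.columns:
        raise ValueError("metadata lacks a disease_label column")
    lab = metadata.reindex(features.index)["disease_label"]
    keep = (lab.astype(str) == disease_label).to_numpy()
    if keep.sum() == 0:
        raise ValueError(f"no samples with disease_label == {disease_label!r}")
    logger.info("cohort filter %r retained %d/%d samples", disease_label, int(keep.sum()), len(keep))
    return features.loc[keep], np.asarray(labels, dtype=float)[keep]
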