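"""Stack-two weighted ensemble over base-model out-of-fold predictions.

The second stacking level is a convex combination of the nine base families.
Weights are found by greedy forward selection with replacement on the OOF
prediction matrix: starting from the empty ensemble, repeatedly add the base
model whose inclusion minimises the OOF MSE of the running average, up to a
fixed budget of picks, and return the best ensemble seen. Because the first
pick is the single best model and the best-so-far is tracked, the ensemble's
OOF MSE can never exceed the best single model's (asserted on every fit).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .enrichment import ScalerState, apply_scaler
from .training import BaseModelResult

__all__ = ["EnsembleModel", "PredictorBundle", "fit_weighted_ensemble", "predict_ensemble"]

DEFAULT_BUDGET = 100


@dataclass
class EnsembleModel:
    """Convex weights over base families plus the greedy selection trace."""

    weights: dict[str, float]
    trace: list[str] = field(default_factory=list)
    oof_mse: float = float("nan")

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
            raise ValueError("ensemble weights must be a probability vector")
        if (vals > 0).sum() == 0:
            raise ValueError("at least one positive weight required")


def fit_weighted_ensemble(
    base_results: list[BaseModelResult],
    labels: np.ndarray,
    budget: int = DEFAULT_BUDGET,
) -> EnsembleModel:
    """Greedy forward selection (with replacement) on the OOF matrix.

    Ties between candidate picks are broken by roster order (the order of
    ``base_results``).
    """
    if not base_results:
        raise ValueError("need at least one base model")
    y = np.asarray(labels, dtype=float)
    preds = np.stack([r.oof for r in base_results])  # models x samples
    if not np.all(np.isfinite(preds)):
        raise ValueError("NaN/inf in base-model OOF predictions")
    if preds.shape[1] != len(y):
        raise ValueError("OOF predictions and labels are misaligned")

    n_models = preds.shape[0]
    counts = np.zeros(n_models, dtype=int)
    running = np.zeros(len(y))
    best_counts, best_mse = None, np.inf
    trace: list[str] = []
    for t in range(1, budget + 1):
        cand_mse = np.mean((((running[None, :] + preds) / t) - y[None, :]) ** 2, axis=1)
        pick = int(np.argmin(cand_mse))  # argmin takes first on ties = roster order
        counts[pick] += 1
        running += preds[pick]
        trace.append(base_results[pick].family)
        if cand_mse[pick] < best_mse:
            best_mse = float(cand_mse[pick])
            best_counts = counts.copy()
    assert best_counts is not None
    weights = best_counts / best_counts.sum()
    model = EnsembleModel(
        weights={r.family: float(w) for r, w in zip(base_results, weights)},
        trace=trace,
        oof_mse=best_mse,
    )
    # never-worse guarantee on the selection data
    min_base = min(float(np.mean((r.oof - y) ** 2)) for r in base_results)
    assert best_mse <= min_base + 1e-12, "ensemble OOF MSE exceeded best base model"
    return model


@dataclass
class PredictorBundle:
    """Everything needed to serve one compound's predictions.

    Holds the post-reduction feature list, the [0,1] scaler fitted on
    training enrichment scores, the nine best-trial base models and the
    weighted ensemble, plus provenance (config, seed, condition, feature
    fraction) for reproducibility.
    """

    compound_id: str
    feature_names: list[str]
    scaler: ScalerState
    base_results: list[BaseModelResult]
    ensemble: EnsembleModel
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.scaler.feature_names) != list(self.feature_names):
            raise ValueError("scaler state and bundle feature list disagree")

    @property
    def validation_scores(self) -> dict[str, float]:
        out = {r.family: r.validation_score for r in self.base_results}
        out["weighted_ensemble"] = -self.ensemble.oof_mse
        return out

    # -- prediction ---------------------------------------------------------

    def predict(self, features: pd.DataFrame, per_family: bool = False):
        """Predict AUC for query samples from raw (unscaled) enrichment features.

        ``features`` is samples x features; missing feature columns are an
        error. Each family predicts as the mean over its fold models; the
        ensemble output is the weight-combined prediction.
        """
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"query features missing: {missing[:20]}")
        X = apply_scaler(self.scaler, features.loc[:, self.feature_names]).to_numpy()
        wanted = (
            self.base_results
            if per_family
            else [r for r in self.base_results if self.ensemble.weights.get(r.family, 0) > 0]
        )
        fam_preds = {r.family: r.predict(X) for r in wanted}
        combined = np.zeros(X.shape[0])
        for fam, w in self.ensemble.weights.items():
            if w > 0:
                combined += w * fam_preds[fam]
        if per_family:
            return combined, pd.DataFrame(fam_preds, index=features.index)
        return combined

    # -- serialization ------------------------------------------------------

    def save(self, directory) -> None:
        """Write manifest JSON (provenance, weights, scores) + model blobs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        blob_path = directory / "models.joblib"
        joblib.dump(
            {r.family: (r.params, r.oof, r.fold_models) for r in self.base_results},
            blob_path,
        )
        manifest = {
            "compound_id": self.compound_id,
            "feature_names": self.feature_names,
            "scaler": {
                "minimum": {k: float(v) for k, v in self.scaler.minimum.items()},
                "maximum": {k: float(v) for k, v in self.scaler.maximum.items()},
                "clip": self.scaler.clip,
                "degenerate": self.scaler.degenerate,
            },
            "ensemble": {
                "weights": self.ensemble.weights,
                "trace": self.ensemble.trace,
                "oof_mse": self.ensemble.oof_mse,
            },
            "validation_scores": self.validation_scores,
            "provenance": self.provenance,
            "models_sha256": hashlib.sha256(blob_path.read_bytes()).hexdigest(),
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def load(cls, directory) -> "PredictorBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        blobs = joblib.load(directory / "models.joblib")
        base_results = []
        for fam, (params, oof, models) in blobs.items():
            score = manifest["validation_scores"][fam]
            base_results.append(BaseModelResult(fam, params, np.asarray(oof), score, models))
        scaler = ScalerState(
            minimum=pd.Series(manifest["scaler"]["minimum"], dtype=float),
            maximum=pd.Series(manifest["scaler"]["maximum"], dtype=float),
            clip=manifest["scaler"]["clip"],
            degenerate=list(manifest["scaler"]["degenerate"]),
        )
        ens = EnsembleModel(
            weights=manifest["ensemble"]["weights"],
            trace=manifest["ensemble"]["trace"],
            oof_mse=manifest["ensemble"]["oof_mse"],
        )
        return cls(
            compound_id=manifest["compound_id"],
            feature_names=list(manifest["feature_names"]),
            scaler=scaler,
            base_results=base_results,
            ensemble=ens,
            provenance=manifest["provenance"],
        )


def predict_ensemble(bundle: PredictorBundle, features: pd.DataFrame, per_family: bool = False):
    """Functional alias for :meth:`PredictorBundle.predict`."""
    return bundle.predict(features, per_family=per_family)


def fit_predictor(
    features_raw: pd.DataFrame,
    labels: np.ndarray,
    config,
    compound_id: str,
    feature_fraction: float = 1.0,
    budget: int = DEFAULT_BUDGET,
) -> PredictorBundle:
    """Fit scaler + nine families + weighted ensemble on raw enrichment features.

    ``features_raw`` is samples x features of unscaled enrichment scores for
    the training cohort; the [0,1] scaler is fitted here and stored in the
    bundle so query cohorts are scaled with the training convention.
    """
    from .enrichment import fit_scaler
    from .training import train_compound

    scaler = fit_scaler(features_raw)
    scaled = apply_scaler(scaler, features_raw)
    base_results = train_compound(scaled, labels, config)
    ens = fit_weighted_ensemble(base_results, labels, budget=budget)
    provenance = {
        "compound_id": compound_id,
        "seed": config.seed,
        "k": config.k,
        "repeats": config.repeats,
        "n_trials": config.n_trials,
        "condition": config.condition,
        "feature_fraction": feature_fraction,
        "validation_on": "out_of_fold_predictions",
        "reduction_research": "full_hyperparameter_research",
    }
    return PredictorBundle(
        compound_id=compound_id,
        feature_names=list(features_raw.columns),
        scaler=scaler,
        base_results=base_results,
        ensemble=ens,
        provenance=provenance,
    )
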