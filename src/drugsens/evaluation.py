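"""Downstream assessment: IC50-vs-prediction regression, embeddings, contrasts.

Measured log2(IC50) values from dose-response experiments are regressed on
predicted AUC by ordinary least squares; the coefficient of determination
summarises how well the predicted resistance ordering matches the measured
potency. Response profiles (compounds over samples, or patients over
compounds) are embedded in 2-D by PCA or t-SNE, and group-wise feature
contrasts rank enrichment features by a standardized one-vs-rest mean
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "RegressionReport",
    "EmbeddingResult",
    "regress_ic50_vs_auc",
    "response_embedding",
    "feature_contrast",
]

VARIANCE_FLOOR = 1e-8


@dataclass
class RegressionReport:
    """OLS fit of log-transformed IC50 on predicted AUC for one condition."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    condition: str = ""
    degenerate_predictor: bool = False

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "degenerate_predictor": self.degenerate_predictor,
        }


def regress_ic50_vs_auc(
    ic50: np.ndarray, predicted_auc: np.ndarray, log_base: float = 2.0, condition: str = ""
) -> RegressionReport:
    """OLS of log(IC50) on predicted AUC; returns slope, intercept and R^2.

    IC50 values must be positive (they are log-transformed); at least three
    paired points are required. A constant predictor leaves R^2 undefined
    and is reported as 0 with the ``degenerate_predictor`` flag set.
    """
    ic50 = np.asarray(ic50, dtype=float)
    auc = np.asarray(predicted_auc, dtype=float)
    if ic50.shape != auc.shape or ic50.ndim != 1:
        raise ValueError("ic50 and predicted_auc must be equal-length vectors")
    if len(ic50) < 3:
        raise ValueError("need at least 3 paired points")
    if not (np.all(np.isfinite(ic50)) and np.all(np.isfinite(auc))):
        raise ValueError("inputs must be finite")
    if (ic50 <= 0).any():
        raise ValueError("IC50 values must be positive for log transformation")
    y = np.log(ic50) / np.log(log_base)
    if np.ptp(auc) == 0:
        return RegressionReport(0.0, float(np.mean(y)), 0.0, len(y), condition, True)
    fit = stats.linregress(auc, y)
    return RegressionReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(y),
        condition=condition,
    )


@dataclass
class EmbeddingResult:
    """2-D embedding of response profiles."""

    method: str
    coordinates: pd.DataFrame  # items x (x, y)
    seed: int
    explained_variance: list[float] = field(default_factory=list)  # pca only

    def to_tsv(self, path) -> None:
        out = self.coordinates.copy()
        out.insert(0, "item", out.index)
        out.to_csv(path, sep="\t", index=False)


def response_embedding(
    profiles: pd.DataFrame,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float | None = None,
    standardize: bool = True,
) -> EmbeddingResult:
    """Embed items (rows) by their response profiles (columns) in 2-D.

    Items are compounds (profiles over samples) or patients (profiles over
    compounds) depending on how the caller orients the matrix. Profiles are
    standardized per column by default before projection. Missing entries
    are an error — imputation is the caller's job. PCA is exact and
    deterministic; t-SNE is reproducible under a fixed seed and requires
    ``perplexity < n_items`` (default 30 capped at (n-1)/3).
    """
    X = profiles.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("profiles contain missing entries; impute before embedding")
    n_items = X.shape[0]
    if n_items < 3:
        raise ValueError("need at least 3 items to embed")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    if method == "pca":
        pca = PCA(n_components=2, random_state=seed)
        coords = pca.fit_transform(X)
        explained = [float(v) for v in pca.explained_variance_ratio_]
    elif method == "tsne":
        if perplexity is None:
            perplexity = min(30.0, max(1.0, (n_items - 1) / 3))
        if perplexity >= n_items:
            raise ValueError(f"perplexity {perplexity} must be < n_items {n_items}")
        tsne = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca",
            max_iter=500,
        )
        coords = tsne.fit_transform(X)
        explained = []
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    coordinates = pd.DataFrame(coords, index=profiles.index, columns=["x", "y"])
    return EmbeddingResult(method, coordinates, seed, explained)


def feature_contrast(
    features: pd.DataFrame,
    groups: pd.Series | dict,
    top_k: int = 10,
) -> dict[str, pd.DataFrame]:
    """Standardized one-vs-rest mean difference per feature and group.

    For each group g and feature f the contrast is
    ``(mean_g - mean_rest) / pooled_sd`` with a small variance floor; the
    per-group ``top_k`` features by contrast are returned with their values.
    This is an interpretability convention: it ranks features, it does not
    claim a biological effect size.
    """
    if not isinstance(groups, pd.Series):
        groups = pd.Series(groups)
    groups = groups.reindex(features.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    X = features.to_numpy(dtype=float)
    out: dict[str, pd.DataFrame] = {}
    for g in labels:
        in_g = (groups == g).to_numpy()
        n1, n2 = int(in_g.sum()), int((~in_g).sum())
        if n1 == 0 or n2 == 0:
            raise ValueError(f"group {g!r} or its complement is empty")
        m1 = X[in_g].mean(axis=0)
        m2 = X[~in_g].mean(axis=0)
        v1 = X[in_g].var(axis=0, ddof=1) if n1 > 1 else np.zeros(X.shape[1])
        v2 = X[~in_g].var(axis=0, ddof=1) if n2 > 1 else np.zeros(X.shape[1])
        dof = max(n1 + n2 - 2, 1)
        pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / dof)
        diff = m1 - m2
        contrast = np.where(
            np.abs(diff) < VARIANCE_FLOOR,
            0.0,
            diff / np.maximum(pooled, np.sqrt(VARIANCE_FLOOR)),
        )
        tab = pd.DataFrame(
            {"feature": features.columns, "contrast": contrast}
        ).sort_values("contrast", ascending=False, kind="stable")
        out[str(g)] = tab.head(top_k).reset_index(drop=True)
    return out
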