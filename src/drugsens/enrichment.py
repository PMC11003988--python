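"""Single-sample gene-set enrichment (ssGSEA) features and [0,1] scaling.

Each sample's genes are ranked by expression (descending); the enrichment
score of a gene set S is the summed difference between a weighted empirical
CDF over in-set genes and an unweighted empirical CDF over out-of-set genes::

    ES(S) = sum_{i=1..N} [ P_hit(i) - P_miss(i) ]
    P_hit(i)  = sum_{g in S, rank(g) <= i} w(g)^alpha / sum_{g in S} w(g)^alpha
    P_miss(i) = |{g not in S, rank(g) <= i}| / (N - |S|)

where w(g) = N - position(g) + 1 is the rank weight on the descending-sorted
list (the top gene has weight N). Rank weights rather than raw expression
make the score invariant to monotone rescaling of the expression values.
Ties in expression are broken by gene-ID lexicographic order so results are
deterministic.

The scores of every retained gene set over all samples form the feature
matrix; features are min-max scaled to [0,1] on the training cohort and
query-cohort values outside the training range are clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentMatrix",
    "ScalerState",
    "MetadataEncoder",
    "ssgsea_score",
    "ssgsea_matrix",
    "fit_scaler",
    "apply_scaler",
    "augment_with_metadata",
]

DEFAULT_ALPHA = 0.75
DEFAULT_SET_SIZE_BOUNDS = (5, 2000)


@dataclass
class EnrichmentMatrix:
    """Gene sets x samples matrix of ssGSEA scores (the model features)."""

    scores: pd.DataFrame  # sets x samples
    alpha: float = DEFAULT_ALPHA
    set_size_bounds: tuple[int, int] = DEFAULT_SET_SIZE_BOUNDS

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValueError("enrichment scores must be finite")

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def as_features(self) -> pd.DataFrame:
        """Samples x features orientation used by the training engine."""
        return self.scores.T


def _rank_order(values: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """Indices sorting genes by expression descending, gene-ID ascending on ties."""
    ids = np.asarray(gene_ids, dtype=object)
    # lexsort: last key is primary
    return np.lexsort((ids, -values))


def ssgsea_score(
    expr: Mapping[str, float] | pd.Series, gene_set: Sequence[str], alpha: float = DEFAULT_ALPHA
) -> float:
    """Enrichment score of one gene set in one sample.

    ``expr`` maps gene ID -> expression value; ``gene_set`` is the set's gene
    list. The intersection with the expressed genes must be non-empty and a
    proper subset (an all-gene set leaves the out-of-set ECDF undefined).
    """
    if not isinstance(expr, pd.Series):
        expr = pd.Series(expr)
    genes = list(expr.index)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes to score a set")
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set has empty intersection with the expression genes")
    if len(members) == n:
        raise ValueError("gene set covers all genes; out-of-set ECDF undefined")

    order = _rank_order(expr.to_numpy(dtype=float), genes)
    sorted_genes = [genes[i] for i in order]
    in_set = np.fromiter((g in members for g in sorted_genes), dtype=bool, count=n)
    weights = np.arange(n, 0, -1, dtype=float)  # N .. 1 down the sorted list
    wpow = weights**alpha
    hit = np.cumsum(np.where(in_set, wpow, 0.0)) / np.sum(wpow[in_set])
    miss = np.cumsum(~in_set) / float(n - len(members))
    return float(np.sum(hit - miss))


def ssgsea_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    set_size_bounds: tuple[int, int] = DEFAULT_SET_SIZE_BOUNDS,
) -> EnrichmentMatrix:
    """Score every retained gene set in every sample.

    Sets whose intersection with the expression genes falls outside
    ``set_size_bounds`` (or covers all genes) are dropped with a logged
    report; if nothing survives, that is an error. Columns are computed
    independently per sample.
    """
    genes = expr.gene_ids
    n = expr.n_genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    lo, hi = set_size_bounds

    retained: list[str] = []
    member_masks: list[np.ndarray] = []
    dropped: list[str] = []
    for gs in sets:
        idx = [gene_pos[g] for g in gs.genes if g in gene_pos]
        size = len(idx)
        if size < lo or size > hi or size == 0 or size == n:
            dropped.append(gs.name)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        retained.append(gs.name)
        member_masks.append(mask)
    if dropped:
        logger.info(
            "dropped %d/%d gene sets outside size bounds %s after intersection: %s",
            len(dropped), len(sets), set_size_bounds, dropped[:10],
        )
    if not retained:
        raise ValueError("all gene sets were dropped by the size bounds")

    masks = np.vstack(member_masks)  # sets x genes (original gene order)
    values = expr.values.to_numpy(dtype=float)
    weights = np.arange(n, 0, -1, dtype=float)
    out = np.empty((len(retained), expr.n_samples), dtype=float)
    for j in range(expr.n_samples):
        order = _rank_order(values[:, j], genes)
        sorted_masks = masks[:, order]  # sets x genes in rank order
        wpow = weights**alpha
        hit_num = np.cumsum(np.where(sorted_masks, wpow[None, :], 0.0), axis=1)
        hit_den = np.sum(np.where(sorted_masks, wpow[None, :], 0.0), axis=1, keepdims=True)
        sizes = sorted_masks.sum(axis=1, keepdims=True).astype(float)
        miss = np.cumsum(~sorted_masks, axis=1) / (n - sizes)
        out[:, j] = np.sum(hit_num / hit_den - miss, axis=1)
    scores = pd.DataFrame(out, index=retained, columns=expr.sample_ids)
    return EnrichmentMatrix(scores, alpha=alpha, set_size_bounds=set_size_bounds)


# ---------------------------------------------------------------------------
# [0,1] min-max scaling with a strict fit/apply split


@dataclass
class ScalerState:
    """Per-feature min/max learned on training features only.

    Training features map exactly onto [0,1]; query values outside the
    training range are clipped so both cohorts share one convention without
    leaking query statistics into the fit. Degenerate features (max == min)
    are flagged and map to 0.
    """

    minimum: pd.Series
    maximum: pd.Series
    clip: bool = True
    degenerate: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.minimum.index)


def fit_scaler(features) -> ScalerState:
    """Learn min-max state from training features (samples x features)."""
    df = features.as_features() if isinstance(features, EnrichmentMatrix) else features
    mn = df.min(axis=0)
    mx = df.max(axis=0)
    degenerate = list(df.columns[(mx - mn).to_numpy() == 0])
    if degenerate:
        logger.warning("degenerate (constant) features mapped to 0: %s", degenerate[:10])
    return ScalerState(minimum=mn.astype(float), maximum=mx.astype(float), degenerate=degenerate)


def _scaler_fingerprint(state: ScalerState) -> str:
    return f"{tuple(state.minimum)}|{tuple(state.maximum)}|{state.clip}"


def apply_scaler(state: ScalerState, features) -> pd.DataFrame:
    """Scale features (samples x features) into [0,1] with the fitted state.

    Output frames are tagged with the fitting state's fingerprint; applying
    the same state to its own output is a no-op (idempotence), which guards
    against accidental double scaling in pipelines.
    """
    df = features.as_features() if isinstance(features, EnrichmentMatrix) else features
    if isinstance(df, pd.DataFrame) and df.attrs.get("scaled_by") == _scaler_fingerprint(state):
        return df.copy()
    have, want = set(df.columns), set(state.feature_names)
    if have != want:
        diff = sorted(have.symmetric_difference(want))
        raise ValueError(f"feature-name mismatch, symmetric difference: {diff[:20]}")
    df = df.loc[:, state.feature_names]
    span = (state.maximum - state.minimum).to_numpy(dtype=float)
    safe_span = np.where(span == 0, 1.0, span)
    scaled = (df.to_numpy(dtype=float) - state.minimum.to_numpy(dtype=float)) / safe_span
    scaled[:, span == 0] = 0.0
    if state.clip:
        scaled = np.clip(scaled, 0.0, 1.0)
    out = pd.DataFrame(scaled, index=df.index, columns=state.feature_names)
    out.attrs["scaled_by"] = _scaler_fingerprint(state)
    return out


# ---------------------------------------------------------------------------
# clinical-metadata augmentation


@dataclass
class MetadataEncoder:
    """Fit/apply encoder for clinical covariates appended as ``meta:`` features.

    Numeric columns are min-max scaled with training-set statistics and
    missing values receive the training median; categorical columns are
    one-hot encoded over training levels with missing values as all-zero
    indicators.
    """

    numeric: Sequence[str] = ()
    categorical: Sequence[str] = ()
    numeric_min_: dict[str, float] = field(default_factory=dict)
    numeric_max_: dict[str, float] = field(default_factory=dict)
    numeric_median_: dict[str, float] = field(default_factory=dict)
    levels_: dict[str, list[str]] = field(default_factory=dict)

    def fit(self, metadata: pd.DataFrame) -> "MetadataEncoder":
        for col in list(self.numeric) + list(self.categorical):
            if col not in metadata.columns:
                raise ValueError(f"metadata column {col!r} absent")
        for col in self.numeric:
            vals = pd.to_numeric(metadata[col], errors="coerce")
            if vals.notna().sum() == 0:
                raise ValueError(f"metadata column {col!r} has no numeric values")
            self.numeric_min_[col] = float(vals.min())
            self.numeric_max_[col] = float(vals.max())
            self.numeric_median_[col] = float(vals.median())
        for col in self.categorical:
            levels = sorted(str(v) for v in metadata[col].dropna().unique())
            self.levels_[col] = levels
        return self

    def transform(self, metadata: pd.DataFrame, sample_ids: Sequence[str]) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {}
        meta = metadata.reindex(sample_ids)
        for col in self.numeric:
            vals = pd.to_numeric(meta[col], errors="coerce")
            vals = vals.fillna(self.numeric_median_[col])
            lo, hi = self.numeric_min_[col], self.numeric_max_[col]
            span = hi - lo if hi > lo else 1.0
            scaled = np.clip((vals.to_numpy(dtype=float) - lo) / span, 0.0, 1.0)
            if hi == lo:
                scaled = np.zeros_like(scaled)
            cols[f"meta:{col}"] = scaled
        for col in self.categorical:
            observed = meta[col].astype(object)
            for level in self.levels_[col]:
                cols[f"meta:{col}={level}"] = (
                    (observed.astype(str) == level) & observed.notna()
                ).to_numpy(dtype=float)
        return pd.DataFrame(cols, index=list(sample_ids))


def augment_with_metadata(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    numeric: Sequence[str] = (),
    categorical: Sequence[str] = (),
    encoder: MetadataEncoder | None = None,
) -> tuple[pd.DataFrame, MetadataEncoder]:
    """Append encoded clinical covariates to a samples x features table.

    Pass a fitted ``encoder`` to reuse training statistics on a query
    cohort; otherwise the encoder is fit on ``metadata`` restricted to the
    feature samples.
    """
    if encoder is None:
        encoder = MetadataEncoder(numeric=tuple(numeric), categorical=tuple(categorical))
        encoder.fit(metadata.reindex(features.index))
    extra = encoder.transform(metadata, list(features.index))
    return pd.concat([features, extra], axis=1), encoder
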