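"""End-to-end workflow orchestration with provenance.

``run_workflow`` wires the stages together: read inputs -> ssGSEA features
-> [0,1] scaling -> per-compound nine-family training -> weighted ensemble
-> optional importance/reduction/retraining -> downstream evaluation. Each
compound is an independent work unit with its own derived seed, so a stage
error aborts only that compound (recorded in the manifest) and scheduling
cannot change numeric results. The run manifest captures package/library
versions, the master seed, a config hash, per-compound validation scores
and a checksum for every emitted file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .enrichment import (
    DEFAULT_ALPHA,
    DEFAULT_SET_SIZE_BOUNDS,
    augment_with_metadata,
    ssgsea_matrix,
)
from .ensemble import PredictorBundle, fit_predictor
from .evaluation import feature_contrast, response_embedding
from .reduction import permutation_importance, reduce_features, retrain_reduced
from .training import TrainingConfig, _derive_seed

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_workflow"]


@dataclass
class RunConfig:
    """Paths and parameters for one workflow run."""

    expression_path: str
    gmt_path: str
    labels_path: str
    out_dir: str
    metadata_path: str | None = None
    query_expression_path: str | None = None
    alpha: float = DEFAULT_ALPHA
    set_size_bounds: tuple[int, int] = DEFAULT_SET_SIZE_BOUNDS
    k: int = 5
    repeats: int = 1
    n_trials: int = 16
    condition: str = "base"  # base | glioma_plus | metadata_plus
    cohort_label: str = "glioma"  # disease label retained under glioma_plus
    metadata_numeric: tuple[str, ...] = ("age",)  # appended under metadata_plus
    metadata_categorical: tuple[str, ...] = ("sex",)
    reduction_fractions: tuple[float, ...] = ()
    n_shuffle_sets: int = 10
    subsample_size: int = 5000
    embed_method: str = "pca"
    seed: int = 0
    compounds: tuple[str, ...] = ()  # empty = all in the label table

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict:
    import lightgbm
    import sklearn

    from . import __version__

    return {
        "drugsens": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "lightgbm": lightgbm.__version__,
    }


def run_workflow(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Global input errors (missing paths, unreadable tables) abort the run
    before anything is written; per-compound failures are recorded in the
    manifest and do not stop other compounds. Reruns skip compounds whose
    bundle directory already exists (per-compound resumability).
    """
    for attr in ("expression_path", "gmt_path", "labels_path"):
        p = getattr(config, attr)
        if not Path(p).exists():
            raise FileNotFoundError(f"{attr}: {p}")
    for attr in ("metadata_path", "query_expression_path"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{attr}: {p}")

    expression = dio.read_expression(config.expression_path)
    sets = dio.read_gmt(config.gmt_path)
    labels = dio.read_drug_response(config.labels_path)
    metadata = dio.read_metadata(config.metadata_path) if config.metadata_path else None
    query_expr = (
        dio.read_expression(config.query_expression_path)
        if config.query_expression_path
        else None
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundles_dir = out_dir / "bundles"
    bundles_dir.mkdir(exist_ok=True)

    enrich = ssgsea_matrix(expression, sets, alpha=config.alpha,
                           set_size_bounds=config.set_size_bounds)
    features = enrich.as_features()
    feat_path = out_dir / "features.tsv"
    enrich.scores.to_csv(feat_path, sep="\t")

    query_features = None
    if query_expr is not None:
        query_enrich = ssgsea_matrix(query_expr, sets, alpha=config.alpha,
                                     set_size_bounds=config.set_size_bounds)
        query_features = query_enrich.as_features()
        missing = set(features.columns) - set(query_features.columns)
        if missing:
            raise ValueError(f"query cohort lacks retained sets: {sorted(missing)[:10]}")
        query_features = query_features.loc[:, features.columns]

    # workflow conditions: cohort narrowing and clinical-covariate features
    if config.condition in ("glioma_plus", "metadata_plus") and metadata is None:
        raise ValueError(f"condition {config.condition!r} requires a metadata table")
    if config.condition == "glioma_plus":
        from .training import cohort_filter

        features, _ = cohort_filter(
            features, np.zeros(len(features)), metadata, config.cohort_label
        )
    elif config.condition == "metadata_plus":
        features, encoder = augment_with_metadata(
            features, metadata,
            numeric=config.metadata_numeric,
            categorical=config.metadata_categorical,
        )
        if query_features is not None:
            query_features, _ = augment_with_metadata(
                query_features, metadata, encoder=encoder
            )

    compounds = list(config.compounds) or labels.compounds
    statuses: dict[str, dict] = {}
    final_bundles: dict[str, PredictorBundle] = {}
    for compound in compounds:
        bundle_dir = bundles_dir / compound
        try:
            if (bundle_dir / "manifest.json").exists():
                logger.info("resuming: bundle for %s already present", compound)
                bundle = PredictorBundle.load(bundle_dir)
                statuses[compound] = {
                    "status": "resumed",
                    "validation_scores": bundle.validation_scores,
                }
                final_bundles[compound] = _load_final(bundle_dir, config, bundle)
                continue
            compound_seed = _derive_seed(config.seed, compound)
            tcfg = TrainingConfig(
                k=config.k, repeats=config.repeats, n_trials=config.n_trials,
                seed=compound_seed, condition=config.condition,
            )
            paired, y = dio.align_training_pairs(features.T, labels, compound)
            feats_c = features.loc[paired]
            bundle = fit_predictor(feats_c, y, tcfg, compound)
            bundle.save(bundle_dir)
            record = {"status": "trained", "validation_scores": bundle.validation_scores}
            final = bundle
            if config.reduction_fractions:
                ranking = permutation_importance(
                    bundle, feats_c, y,
                    n_shuffle_sets=config.n_shuffle_sets,
                    subsample_size=config.subsample_size,
                    seed=compound_seed,
                )
                ranking.to_tsv(bundle_dir / "importance.tsv")
                record["reduced"] = {}
                for fraction in config.reduction_fractions:
                    plan = reduce_features(ranking, fraction)
                    reduced = retrain_reduced(feats_c, y, plan, tcfg, compound)
                    tag = f"rf{int(round(fraction * 100))}"
                    reduced.save(bundle_dir / tag)
                    record["reduced"][tag] = reduced.validation_scores
                    final = reduced  # smallest-fraction bundle serves downstream
            statuses[compound] = record
            final_bundles[compound] = final
        except Exception as exc:  # per-compound isolation
            logger.exception("compound %s failed", compound)
            statuses[compound] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}

    # downstream: predictions, embedding, contrasts
    eval_features = query_features if query_features is not None else features
    succeeded = [c for c in compounds if statuses[c].get("status") != "failed"]
    if succeeded:
        preds = pd.DataFrame(
            {c: final_bundles[c].predict(eval_features) for c in succeeded},
            index=eval_features.index,
        )
        preds.to_csv(out_dir / "predictions.csv")
        if len(succeeded) >= 3:
            emb = response_embedding(preds.T, method=config.embed_method, seed=config.seed)
            emb.to_tsv(out_dir / "compound_embedding.tsv")
    if metadata is not None and "disease_label" in metadata.columns:
        groups = metadata.reindex(features.index)["disease_label"].dropna()
        if groups.nunique() >= 2:
            contrasts = feature_contrast(features.loc[groups.index], groups,
                                         top_k=min(10, features.shape[1]))
            rows = []
            for group, tab in contrasts.items():
                tab = tab.copy()
                tab.insert(0, "group", group)
                rows.append(tab)
            pd.concat(rows).to_csv(out_dir / "feature_contrasts.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "versions": _versions(),
        "compounds": statuses,
        "files": {
            str(p.relative_to(out_dir)): _sha256(p)
            for p in sorted(out_dir.rglob("*"))
            if p.is_file() and p.name != "run_manifest.json"
        },
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return out_dir


def _load_final(bundle_dir: Path, config: RunConfig, bundle: PredictorBundle) -> PredictorBundle:
    """The bundle used downstream: the last reduction fraction if present."""
    if config.reduction_fractions:
        tag = f"rf{int(round(config.reduction_fractions[-1] * 100))}"
        sub = bundle_dir / tag
        if (sub / "manifest.json").exists():
            return PredictorBundle.load(sub)
    return bundle
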