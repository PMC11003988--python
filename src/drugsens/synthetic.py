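"""Synthetic pharmacogenomic cohorts with known ground truth.

The generator emulates the statistical shape of the real inputs: a
CCLE-like log2(TPM+1) expression matrix, CTRP-like per-compound AUC labels
with missing entries, and a latent pathway-activity structure linking gene
sets to drug response. Each sample carries one standard-normal latent
activity per gene set; member genes of a set are shifted by
``loading * activity`` log2 units on top of a per-gene baseline, and each
compound's AUC is a linear function of its driver sets' activities plus
noise. A held-out "query" cohort receives an additive per-gene batch shift,
emulating the train/apply batch effect between public training cohorts and
locally profiled samples.

Because the latent activities are known, every downstream stage can be
scored for recovery: held-out R^2 per compound, the fraction of true driver
sets inside the top-3% importance ranking, and robustness to the batch
shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DrugResponseTable, ExpressionMatrix, GeneSetCollection, GeneSet

__all__ = ["SyntheticSpec", "GroundTruth", "simulate_cohort", "recovery_report"]


@dataclass
class SyntheticSpec:
    """Study conditions for a simulated cohort.

    Defaults describe a small but realistic desk-scale cohort: 1000 genes,
    50 sets of 20 genes, moderate expression/label noise, 10% missing
    labels and a mild additive batch shift on the query cohort. Effect
    sizes ``beta`` are in AUC units per unit (standard-normal) pathway
    activity; the AUC baseline of 8 keeps labels on a positive CTRP-like
    scale where larger AUC means greater resistance.
    """

    n_samples: int = 120
    n_query: int = 0
    n_genes: int = 1000
    n_sets: int = 50
    set_size: int = 20
    drivers: dict[str, dict[str, float]] = field(default_factory=dict)  # compound -> {set: beta}
    beta0: dict[str, float] = field(default_factory=dict)  # compound -> baseline AUC
    default_beta0: float = 8.0
    loading: float = 0.8  # log2 units expression shift per unit activity
    expr_noise_sd: float = 0.3
    auc_noise_sd: float = 0.3
    missing_fraction: float = 0.1
    batch_shift_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_fraction <= 1):
            raise ValueError("missing_fraction must be in [0,1]")
        for sd in (self.expr_noise_sd, self.auc_noise_sd, self.batch_shift_sd):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")
        if self.n_sets * 1 > self.n_genes:
            pass  # sets may overlap; no hard constraint
        if not self.drivers:
            self.drivers = {"compound_1": {self._set_name(0): 1.5}}

    @staticmethod
    def _set_name(i: int) -> str:
        return f"SET{i + 1:04d}"

    @property
    def compounds(self) -> list[str]:
        return list(self.drivers)


@dataclass
class GroundTruth:
    """Latent state behind a simulated cohort."""

    activities: pd.DataFrame  # samples x sets (train + query)
    drivers: dict[str, dict[str, float]]
    beta0: dict[str, float]
    batch: pd.Series  # sample -> "train" | "query"
    clean_auc: pd.DataFrame  # samples x compounds, noiseless labels

    def auc_for(self, compound_id: str, sample_ids) -> np.ndarray:
        if compound_id not in self.clean_auc.columns:
            raise KeyError(f"compound {compound_id!r} absent from ground truth")
        return self.clean_auc.loc[list(sample_ids), compound_id].to_numpy(dtype=float)


def simulate_cohort(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, GeneSetCollection, DrugResponseTable, pd.DataFrame, GroundTruth]:
    """Draw one cohort (expression, gene sets, labels, metadata, truth).

    Deterministic under ``spec.seed``. Expression is clipped at 0 after
    noise so the log2(TPM+1) nonnegativity invariant holds; the query
    cohort (if any) receives the additive batch shift. Noisy AUC labels are
    generated for training samples and thinned at the missing fraction;
    noiseless AUC for every sample (train and query) is stored in the
    ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    set_names = [spec._set_name(i) for i in range(spec.n_sets)]
    for compound, sets in spec.drivers.items():
        unknown = [s for s in sets if s not in set_names]
        if unknown:
            raise ValueError(f"driver of {compound!r} references undefined set(s) {unknown}")

    genes = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    n_total = spec.n_samples + spec.n_query
    sample_ids = [f"S{i + 1:04d}" for i in range(n_total)]
    batch = pd.Series(
        ["train"] * spec.n_samples + ["query"] * spec.n_query, index=sample_ids, name="batch"
    )

    # gene-set membership: each set samples genes without replacement
    membership = np.zeros((spec.n_sets, spec.n_genes), dtype=bool)
    entries = {}
    for i, name in enumerate(set_names):
        idx = rng.choice(spec.n_genes, size=min(spec.set_size, spec.n_genes - 1), replace=False)
        membership[i, idx] = True
        entries[name] = GeneSet(name, "synthetic pathway", tuple(genes[j] for j in sorted(idx)))
    collection = GeneSetCollection(entries)

    activities = rng.standard_normal((n_total, spec.n_sets))  # samples x sets
    baseline = rng.uniform(2.0, 8.0, size=spec.n_genes)
    expr = np.tile(baseline, (n_total, 1))
    expr += spec.loading * (activities @ membership)
    if spec.expr_noise_sd > 0:
        expr += rng.normal(0.0, spec.expr_noise_sd, size=expr.shape)
    if spec.n_query > 0 and spec.batch_shift_sd > 0:
        shift = rng.normal(0.0, spec.batch_shift_sd, size=spec.n_genes)
        expr[spec.n_samples:, :] += shift[None, :]
    expr = np.clip(expr, 0.0, None)
    expression = ExpressionMatrix(
        pd.DataFrame(expr.T, index=genes, columns=sample_ids), scale_tag="log2tpm1"
    )

    act_df = pd.DataFrame(activities, index=sample_ids, columns=set_names)
    set_pos = {s: i for i, s in enumerate(set_names)}
    clean = {}
    for compound, sets in spec.drivers.items():
        b0 = spec.beta0.get(compound, spec.default_beta0)
        auc = np.full(n_total, b0)
        for set_name, beta in sets.items():
            auc = auc + beta * activities[:, set_pos[set_name]]
        clean[compound] = auc
    clean_auc = pd.DataFrame(clean, index=sample_ids)

    records = []
    train_ids = sample_ids[: spec.n_samples]
    for compound in spec.compounds:
        noisy = clean_auc.loc[train_ids, compound].to_numpy()
        if spec.auc_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.auc_noise_sd, size=spec.n_samples)
        observed = rng.random(spec.n_samples) >= spec.missing_fraction
        for sid, val, keep in zip(train_ids, noisy, observed):
            if keep:
                records.append((sid, compound, float(val)))
    labels = DrugResponseTable(
        pd.DataFrame(records, columns=["sample_id", "compound_id", "auc"])
    )

    metadata = pd.DataFrame(
        {
            "age": np.round(rng.normal(55, 12, size=n_total)).astype(int),
            "sex": rng.choice(["F", "M"], size=n_total),
            "idh1_mut": rng.integers(0, 2, size=n_total),
            "disease_label": rng.choice(["glioma", "other"], size=n_total, p=[0.7, 0.3]),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = GroundTruth(
        activities=act_df,
        drivers={c: dict(s) for c, s in spec.drivers.items()},
        beta0={c: spec.beta0.get(c, spec.default_beta0) for c in spec.compounds},
        batch=batch,
        clean_auc=clean_auc,
    )
    return expression, collection, labels, metadata, truth


def _r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - np.mean(y_true)) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def recovery_report(
    bundle,
    truth: GroundTruth,
    features: pd.DataFrame,
    ranking=None,
    top_fraction: float = 0.03,
) -> dict:
    """Score a trained bundle against the simulator's ground truth.

    ``features`` holds raw enrichment features (samples x features) for the
    samples to evaluate; predictions are compared with the noiseless AUC.
    Reports held-out R^2 split by batch (train/query) and, when an
    importance ``ranking`` is supplied, the fraction of the compound's true
    driver sets inside the top ``top_fraction`` of the ranking.
    """
    compound = bundle.compound_id
    if compound not in truth.clean_auc.columns:
        raise KeyError(f"compound {compound!r} absent from ground truth")
    sample_ids = list(features.index)
    y_true = truth.auc_for(compound, sample_ids)
    y_pred = bundle.predict(features)
    report = {"compound_id": compound, "r2": _r_squared(y_true, y_pred)}

    batches = truth.batch.reindex(sample_ids)
    for tag in ("train", "query"):
        mask = (batches == tag).to_numpy()
        if mask.sum() >= 3:
            report[f"r2_{tag}"] = _r_squared(y_true[mask], y_pred[mask])

    if ranking is not None:
        ordering = ranking.ordering
        n_top = max(1, int(np.floor(top_fraction * len(ordering))))
        top = set(ordering[:n_top])
        driver_sets = list(truth.drivers[compound])
        hits = sum(1 for s in driver_sets if s in top)
        report["driver_recovery"] = hits / len(driver_sets)
        report["n_top"] = n_top
    return report
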