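import numpy as np
import pandas as pd
import pytest

from drugsens import (
    SyntheticSpec,
    TrainingConfig,
    fit_predictor,
    simulate_cohort,
    ssgsea_matrix,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small simulated cohort shared by training-stage tests."""
    spec = SyntheticSpec(
        n_samples=60, n_query=20, n_genes=150, n_sets=12, set_size=10,
        drivers={"cpdA": {"SET0001": 1.5}, "cpdB": {"SET0002": 1.0, "SET0003": 0.8}},
        seed=11,
    )
    expr, sets, labels, metadata, truth = simulate_cohort(spec)
    return {"spec": spec, "expr": expr, "sets": sets, "labels": labels,
            "metadata": metadata, "truth": truth}


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    enrich = ssgsea_matrix(tiny_cohort["expr"], tiny_cohort["sets"])
    return enrich.as_features()


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cohort, tiny_features):
    """One trained predictor bundle at minimal search effort."""
    labels = tiny_cohort["labels"].for_compound("cpdA")
    train_ids = [s for s in tiny_features.index
                 if tiny_cohort["truth"].batch[s] == "train" and s in labels.index]
    feats = tiny_features.loc[train_ids]
    y = labels.loc[train_ids].to_numpy()
    cfg = TrainingConfig(k=5, repeats=1, n_trials=1, seed=5)
    return fit_predictor(feats, y, cfg, "cpdA"), feats, y


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def direct_features():
    """Feature table built directly (no ssGSEA) for fast model-level tests."""
    gen = np.random.default_rng(42)
    X = gen.uniform(size=(80, 6))
    return pd.DataFrame(X, index=[f"S{i}" for i in range(80)],
                        columns=[f"F{j}" for j in range(6)])
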