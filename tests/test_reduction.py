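import numpy as np
import pandas as pd
import pytest

from drugsens import (
    ImportanceRanking,
    TrainingConfig,
    fit_predictor,
    permutation_importance,
    reduce_features,
    retrain_reduced,
)


def _ranking(features):
    table = pd.DataFrame({
        "feature": features,
        "importance": np.linspace(1.0, 0.0, len(features)),
        "dispersion": 0.1,
        "p_value": 0.01,
        "rank": np.arange(1, len(features) + 1),
    })
    return ImportanceRanking(table, n_shuffle_sets=5, subsample_size=100)


class TestReduceFeatures:
    @pytest.mark.parametrize("n_features, fraction, expected", [
        (100, 0.20, 20),
        (100, 0.10, 10),
        (10, 0.03, 1),   # floor would give 0; minimum-1 guard applies
        (7, 1.0, 7),
    ])
    def test_retained_count(self, n_features, fraction, expected):
        plan = reduce_features(_ranking([f"f{i}" for i in range(n_features)]), fraction)
        assert len(plan.retained) == expected

    def test_retained_is_prefix_of_ordering(self):
        ranking = _ranking([f"f{i}" for i in range(50)])
        plan = reduce_features(ranking, 0.2)
        assert plan.retained == ranking.ordering[:10]

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_fraction_out_of_range(self, fraction):
        with pytest.raises(ValueError):
            reduce_features(_ranking(["a", "b"]), fraction)

    def test_sample_to_feature_ratio_presets(self):
        """With F ~= 5.5 n, the 20/10/3% presets give ~1:1, 2:1 and 6:1 ratios."""
        n, F = 100, 550
        ranking = _ranking([f"f{i}" for i in range(F)])
        for fraction, target in [(0.20, 1.0), (0.10, 2.0), (0.03, 6.0)]:
            kept = len(reduce_features(ranking, fraction).retained)
            assert n / kept == pytest.approx(target, rel=0.15)


def _fit_small(features, y, seed=0, n_trials=1):
    cfg = TrainingConfig(k=4, repeats=1, n_trials=n_trials, seed=seed)
    return fit_predictor(features, y, cfg, "cpd"), cfg


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(7)
    n = 80
    X = pd.DataFrame({
        "driver": rng.uniform(size=n),
        "noise1": rng.uniform(size=n),
        "noise2": rng.uniform(size=n),
        "flat": np.full(n, 0.5),
    })
    y = 4.0 * X["driver"].to_numpy() + rng.normal(scale=0.05, size=n) + 8.0
    bundle, cfg = _fit_small(X, y)
    return bundle, X, y, cfg


class TestPermutationImportance:
    def test_planted_driver_ranks_first(self, planted):
        bundle, X, y, _ = planted
        ranking = permutation_importance(bundle, X, y, n_shuffle_sets=5, seed=1)
        assert ranking.table.iloc[0]["feature"] == "driver"
        assert ranking.table.iloc[0]["importance"] > 0

    def test_constant_feature_has_null_importance(self, planted):
        bundle, X, y, _ = planted
        ranking = permutation_importance(bundle, X, y, n_shuffle_sets=5, seed=1)
        row = ranking.table.set_index("feature").loc["flat"]
        assert abs(row["importance"]) <= max(2 * row["dispersion"], 1e-12)

    def test_label_copy_feature_is_significant(self):
        rng = np.random.default_rng(3)
        n = 80
        y = rng.normal(8, 1, size=n)
        X = pd.DataFrame({
            "label_copy": (y - y.min()) / (y.max() - y.min()),
            "noise": rng.uniform(size=n),
        })
        bundle, _ = _fit_small(X, y, seed=2)
        ranking = permutation_importance(bundle, X, y, n_shuffle_sets=10, seed=4)
        row = ranking.table.set_index("feature").loc["label_copy"]
        assert row["importance"] > 0
        assert row["p_value"] < 0.05

    def test_seeded_rankings_reproduce(self, planted):
        bundle, X, y, _ = planted
        a = permutation_importance(bundle, X, y, n_shuffle_sets=3, seed=9)
        b = permutation_importance(bundle, X, y, n_shuffle_sets=3, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_single_sample_rejected(self, planted):
        bundle, X, y, _ = planted
        with pytest.raises(ValueError, match="2 samples"):
            permutation_importance(bundle, X.iloc[:1], y[:1])

    def test_ranking_tsv_round_trip(self, planted, tmp_path):
        bundle, X, y, _ = planted
        ranking = permutation_importance(bundle, X, y, n_shuffle_sets=3, seed=9)
        ranking.to_tsv(tmp_path / "r.tsv")
        back = ImportanceRanking.from_tsv(tmp_path / "r.tsv")
        assert back.ordering == ranking.ordering


class TestRetrainReduced:
    def test_full_fraction_reproduces_unreduced_run(self, rng):
        X = pd.DataFrame(rng.uniform(size=(60, 5)), columns=[f"F{i}" for i in range(5)])
        y = 2 * X["F0"].to_numpy() + rng.normal(scale=0.1, size=60)
        bundle, cfg = _fit_small(X, y, seed=11)
        ranking = permutation_importance(bundle, X, y, n_shuffle_sets=3, seed=1)
        plan = reduce_features(ranking, 1.0)
        again = retrain_reduced(X, y, plan, cfg, "cpd")
        assert again.validation_scores == bundle.validation_scores

    def test_dropping_all_drivers_degrades_score(self, rng):
        X = pd.DataFrame(rng.uniform(size=(60, 4)), columns=["driver", "n1", "n2", "n3"])
        y = 5 * X["driver"].to_numpy() + rng.normal(scale=0.05, size=60)
        bundle, cfg = _fit_small(X, y, seed=13)
        adversarial = ImportanceRanking(
            pd.DataFrame({"feature": ["n1", "n2", "n3", "driver"],
                          "importance": [1.0, 0.9, 0.8, 0.0],
                          "dispersion": 0.0, "p_value": 1.0, "rank": [1, 2, 3, 4]}),
            n_shuffle_sets=1, subsample_size=60)
        plan = reduce_features(adversarial, 0.5)  # keeps n1, n2 only
        worse = retrain_reduced(X, y, plan, cfg, "cpd")
        assert (worse.validation_scores["weighted_ensemble"]
                < bundle.validation_scores["weighted_ensemble"])

    def test_missing_plan_feature_errors(self, rng):
        X = pd.DataFrame(rng.uniform(size=(30, 2)), columns=["a", "b"])
        plan = reduce_features(_ranking(["a", "zz"]), 1.0)
        with pytest.raises(ValueError, match="absent"):
            retrain_reduced(X, np.zeros(30), plan, TrainingConfig(k=3, n_trials=1), "c")


def test_label_independent_feature_importance_centered_on_zero():
    """Across seeds, a feature unrelated to the label by construction averages ~0."""
    rng = np.random.default_rng(0)
    vals = []
    n = 60
    for seed in range(6):
        X = pd.DataFrame({
            "driver": rng.uniform(size=n),
            "unrelated": rng.uniform(size=n),
        })
        y = 3 * X["driver"].to_numpy() + rng.normal(scale=0.1, size=n)
        bundle, _ = _fit_small(X, y, seed=seed)
        ranking = permutation_importance(bundle, X, y, n_shuffle_sets=4, seed=seed)
        vals.append(ranking.table.set_index("feature").loc["unrelated", "importance"])
    vals = np.array(vals)
    driver_scale = 1.0  # importances are on the MSE scale of y (var ~ 0.75)
    assert abs(vals.mean()) < 0.1 * driver_scale
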