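import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

from drugsens import feature_contrast, regress_ic50_vs_auc, response_embedding
from tests.oracles import least_squares_r2_reference


class TestIc50Regression:
    def test_perfect_line_gives_unit_r2(self):
        auc = np.array([1.0, 2.0, 3.0, 4.0])
        ic50 = 2.0 ** (3.0 * auc - 1.0)  # log2(ic50) = 3*auc - 1 exactly
        rep = regress_ic50_vs_auc(ic50, auc)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.slope == pytest.approx(3.0)
        assert rep.intercept == pytest.approx(-1.0)

    def test_orthogonalized_predictor_gives_zero_r2(self):
        auc = np.array([-1.0, 1.0, -1.0, 1.0])
        ic50 = np.array([1.0, 1.0, 4.0, 4.0])  # log2 in {0, 2}, orthogonal to auc
        rep = regress_ic50_vs_auc(ic50, auc)
        assert rep.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle_and_pearson_identity(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            auc = rng.normal(size=n)
            ic50 = np.exp(rng.normal(size=n))
            rep = regress_ic50_vs_auc(ic50, auc)
            oracle = least_squares_r2_reference(auc, np.log2(ic50))
            assert rep.r_squared == pytest.approx(oracle, abs=1e-10)
            pearson = stats.pearsonr(auc, np.log2(ic50)).statistic
            assert rep.r_squared == pytest.approx(pearson**2, abs=1e-10)

    def test_nonpositive_ic50_and_short_input_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            regress_ic50_vs_auc([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="3 paired"):
            regress_ic50_vs_auc([1.0, 2.0], [1.0, 2.0])

    def test_constant_predictor_flagged(self):
        rep = regress_ic50_vs_auc([1.0, 2.0, 4.0], [5.0, 5.0, 5.0])
        assert rep.degenerate_predictor
        assert rep.r_squared == 0.0


class TestResponseEmbedding:
    def _two_cluster_profiles(self, rng):
        a = rng.normal(0, 0.2, size=(6, 12)) + 2.0
        b = rng.normal(0, 0.2, size=(6, 12)) - 2.0
        items = [f"cpd{i}" for i in range(12)]
        return pd.DataFrame(np.vstack([a, b]), index=items[:12]), [0] * 6 + [1] * 6

    def test_planted_clusters_have_positive_silhouette(self, rng):
        profiles, grouping = self._two_cluster_profiles(rng)
        emb = response_embedding(profiles, method="pca", seed=0)
        assert silhouette_score(emb.coordinates.to_numpy(), grouping) > 0

    def test_rank_one_matrix_has_vanishing_second_component(self, rng):
        u = rng.normal(size=8)
        v = rng.normal(size=5)
        profiles = pd.DataFrame(np.outer(u, v))
        emb = response_embedding(profiles, method="pca", seed=0)
        assert emb.explained_variance[1] == pytest.approx(0.0, abs=1e-9)

    def test_tsne_deterministic_under_seed(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(10, 6)))
        a = response_embedding(profiles, method="tsne", seed=3, perplexity=3)
        b = response_embedding(profiles, method="tsne", seed=3, perplexity=3)
        np.testing.assert_array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())

    def test_perplexity_and_missing_entry_validation(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="perplexity"):
            response_embedding(profiles, method="tsne", perplexity=10)
        profiles.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            response_embedding(profiles, method="pca")

    def test_pca_invariant_to_column_reordering_up_to_sign(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(9, 7)))
        a = response_embedding(profiles, method="pca", seed=0).coordinates.to_numpy()
        perm = rng.permutation(7)
        b = response_embedding(profiles.iloc[:, perm], method="pca",
                               seed=0).coordinates.to_numpy()
        for col in range(2):
            assert (np.allclose(a[:, col], b[:, col], atol=1e-8)
                    or np.allclose(a[:, col], -b[:, col], atol=1e-8))


class TestFeatureContrast:
    def test_identical_groups_have_zero_contrast(self, rng):
        block = rng.uniform(size=(4, 5))
        feats = pd.DataFrame(np.vstack([block, block]),
                             index=[f"s{i}" for i in range(8)],
                             columns=[f"f{j}" for j in range(5)])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=feats.index)
        out = feature_contrast(feats, groups, top_k=5)
        assert np.allclose(out["A"]["contrast"], 0.0)

    def test_shifted_feature_ranks_first_with_positive_sign(self, rng):
        feats = pd.DataFrame(rng.normal(size=(20, 6)),
                             index=[f"s{i}" for i in range(20)],
                             columns=[f"f{j}" for j in range(6)])
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=feats.index)
        pooled_sd = feats["f2"].std()
        feats.loc[groups == "A", "f2"] += 3 * pooled_sd
        out = feature_contrast(feats, groups, top_k=6)
        assert out["A"].iloc[0]["feature"] == "f2"
        assert out["A"].iloc[0]["contrast"] > 0

    def test_two_group_antisymmetry(self, rng):
        feats = pd.DataFrame(rng.normal(size=(10, 3)),
                             index=[f"s{i}" for i in range(10)])
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=feats.index)
        out = feature_contrast(feats, groups, top_k=3)
        swapped = feature_contrast(feats, groups.map({"A": "B", "B": "A"}), top_k=3)
        a = out["A"].set_index("feature")["contrast"]
        b = swapped["B"].set_index("feature")["contrast"]
        pd.testing.assert_series_equal(a, b)

    def test_affine_rescaling_invariance(self, rng):
        feats = pd.DataFrame(rng.normal(size=(16, 4)),
                             index=[f"s{i}" for i in range(16)],
                             columns=list("wxyz"))
        feats.iloc[:8, 1] += 1.5
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=feats.index)
        base = feature_contrast(feats, groups, top_k=4)
        rescaled = feats.copy()
        rescaled["x"] = 10.0 * rescaled["x"] + 3.0
        again = feature_contrast(rescaled, groups, top_k=4)
        a = base["A"].set_index("feature")["contrast"]
        b = again["A"].set_index("feature")["contrast"]
        pd.testing.assert_series_equal(a, b)

    def test_single_group_rejected(self, rng):
        feats = pd.DataFrame(rng.normal(size=(4, 2)), index=list("abcd"))
        with pytest.raises(ValueError, match="2 groups"):
            feature_contrast(feats, pd.Series(["A"] * 4, index=feats.index))
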