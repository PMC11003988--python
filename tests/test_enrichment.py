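import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drugsens import (
    ExpressionMatrix,
    GeneSetCollection,
    MetadataEncoder,
    apply_scaler,
    augment_with_metadata,
    fit_scaler,
    ssgsea_matrix,
    ssgsea_score,
)
from tests.oracles import ssgsea_reference


def _expr(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestSsgseaScore:
    @pytest.mark.parametrize(
        "members, expected",
        [(["a", "b"], 2.0), (["c", "d"], -2.0), (["b", "c"], 0.0)],
    )
    def test_hand_enumerated_four_gene_cases(self, members, expected):
        expr = pd.Series({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        assert ssgsea_score(expr, members, alpha=0.0) == pytest.approx(expected)

    def test_matches_double_loop_oracle_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 61))
            gene_ids = [f"g{i:03d}" for i in range(n)]
            values = rng.normal(size=n)
            size = int(rng.integers(1, min(20, n - 1) + 1))
            members = list(rng.choice(gene_ids, size=size, replace=False))
            alpha = float(rng.choice([0.0, 0.25, 0.75, 1.0]))
            engine = ssgsea_score(pd.Series(values, index=gene_ids), members, alpha)
            oracle = ssgsea_reference(values, gene_ids, members, alpha)
            assert engine == pytest.approx(oracle, abs=1e-9)

    def test_shift_invariance_at_alpha_zero(self, rng):
        values = rng.normal(size=12)
        ids = [f"g{i}" for i in range(12)]
        members = ids[2:6]
        base = ssgsea_score(pd.Series(values, index=ids), members, alpha=0.0)
        shifted = ssgsea_score(pd.Series(values + 7.5, index=ids), members, alpha=0.0)
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_sign_symmetry_for_half_sets(self, rng):
        values = rng.normal(size=10)
        ids = [f"g{i}" for i in range(10)]
        members = list(rng.choice(ids, size=5, replace=False))
        fwd = ssgsea_score(pd.Series(values, index=ids), members, alpha=0.0)
        rev = ssgsea_score(pd.Series(-values, index=ids), members, alpha=0.0)
        assert rev == pytest.approx(-fwd, abs=1e-9)

    def test_full_coverage_and_empty_intersection_rejected(self):
        expr = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="all genes"):
            ssgsea_score(expr, ["a", "b"], alpha=0.0)
        with pytest.raises(ValueError, match="empty intersection"):
            ssgsea_score(expr, ["zzz"], alpha=0.0)


class TestSsgseaMatrix:
    def test_single_cell_consistency_with_score(self, rng):
        genes = [f"g{i}" for i in range(20)]
        vals = rng.uniform(0, 10, size=(20, 1))
        expr = _expr(vals, genes, ["s1"])
        sets = GeneSetCollection.from_lists({"S": genes[3:9]})
        enrich = ssgsea_matrix(expr, sets, alpha=0.75, set_size_bounds=(1, 100))
        direct = ssgsea_score(expr.values["s1"], genes[3:9], alpha=0.75)
        assert enrich.scores.loc["S", "s1"] == pytest.approx(direct, abs=1e-12)

    def test_matrix_matches_per_cell_oracle(self, rng):
        genes = [f"g{i:02d}" for i in range(50)]
        samples = [f"s{j}" for j in range(5)]
        vals = rng.uniform(0, 12, size=(50, 5))
        sets = {f"S{k}": list(rng.choice(genes, size=int(rng.integers(3, 15)),
                                         replace=False)) for k in range(10)}
        expr = _expr(vals, genes, samples)
        enrich = ssgsea_matrix(expr, GeneSetCollection.from_lists(sets),
                               alpha=0.25, set_size_bounds=(1, 100))
        for name, members in sets.items():
            for j, s in enumerate(samples):
                oracle = ssgsea_reference(vals[:, j], genes, members, 0.25)
                assert enrich.scores.loc[name, s] == pytest.approx(oracle, abs=1e-9)

    def test_sample_permutation_permutes_columns(self, rng):
        genes = [f"g{i}" for i in range(30)]
        samples = [f"s{j}" for j in range(6)]
        vals = rng.uniform(0, 8, size=(30, 6))
        sets = GeneSetCollection.from_lists({"S": genes[:7]})
        a = ssgsea_matrix(_expr(vals, genes, samples), sets)
        perm = [3, 0, 5, 1, 4, 2]
        b = ssgsea_matrix(_expr(vals[:, perm], genes, [samples[p] for p in perm]), sets)
        np.testing.assert_allclose(
            a.scores[[samples[p] for p in perm]].to_numpy(), b.scores.to_numpy()
        )

    def test_size_bounds_drop_sets_and_all_dropped_errors(self, rng):
        genes = [f"g{i}" for i in range(30)]
        expr = _expr(rng.uniform(size=(30, 2)), genes, ["s1", "s2"])
        sets = GeneSetCollection.from_lists({"small": genes[:2], "ok": genes[:10]})
        enrich = ssgsea_matrix(expr, sets, set_size_bounds=(5, 2000))
        assert enrich.set_names == ["ok"]
        with pytest.raises(ValueError, match="dropped"):
            ssgsea_matrix(expr, GeneSetCollection.from_lists({"small": genes[:2]}))


class TestScaler:
    def test_affine_map_and_clipping(self):
        train = pd.DataFrame({"f": [2.0, 4.0, 6.0]}, index=["a", "b", "c"])
        state = fit_scaler(train)
        np.testing.assert_allclose(apply_scaler(state, train)["f"], [0.0, 0.5, 1.0])
        query = pd.DataFrame({"f": [1.0, 7.0]}, index=["q1", "q2"])
        np.testing.assert_allclose(apply_scaler(state, query)["f"], [0.0, 1.0])

    def test_constant_feature_flagged_and_zeroed(self):
        train = pd.DataFrame({"f": [3.0, 3.0], "g": [0.0, 1.0]}, index=["a", "b"])
        state = fit_scaler(train)
        assert state.degenerate == ["f"]
        assert (apply_scaler(state, train)["f"] == 0.0).all()

    def test_scaling_idempotence(self, rng):
        train = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("wxyz"))
        state = fit_scaler(train)
        once = apply_scaler(state, train)
        twice = apply_scaler(state, once)
        pd.testing.assert_frame_equal(once, twice)

    def test_feature_mismatch_lists_symmetric_difference(self):
        state = fit_scaler(pd.DataFrame({"a": [0.0, 1.0]}))
        with pytest.raises(ValueError, match="b"):
            apply_scaler(state, pd.DataFrame({"b": [0.5]}))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30, unique=True))
    def test_training_features_always_land_in_unit_interval(self, values):
        train = pd.DataFrame({"f": values})
        scaled = apply_scaler(fit_scaler(train), train)["f"]
        assert ((scaled >= 0) & (scaled <= 1)).all()
        assert scaled.min() == pytest.approx(0.0)
        assert scaled.max() == pytest.approx(1.0)


class TestMetadataAugmentation:
    def _features(self, samples):
        return pd.DataFrame({"F1": np.linspace(0, 1, len(samples))}, index=samples)

    def test_numeric_minmax(self):
        meta = pd.DataFrame({"age": [30, 50, 70]}, index=["a", "b", "c"])
        out, _ = augment_with_metadata(self._features(["a", "b", "c"]), meta,
                                       numeric=["age"])
        np.testing.assert_allclose(out["meta:age"], [0.0, 0.5, 1.0])

    def test_categorical_one_hot_sums_to_one(self):
        meta = pd.DataFrame({"sex": ["F", "M", "F"]}, index=["a", "b", "c"])
        out, _ = augment_with_metadata(self._features(["a", "b", "c"]), meta,
                                       categorical=["sex"])
        ind = out[["meta:sex=F", "meta:sex=M"]]
        np.testing.assert_allclose(ind.sum(axis=1), 1.0)

    def test_missing_categorical_becomes_all_zero_indicator(self):
        meta = pd.DataFrame({"mut": ["yes", None, "no"]}, index=["a", "b", "c"])
        out, _ = augment_with_metadata(self._features(["a", "b", "c"]), meta,
                                       categorical=["mut"])
        assert out.loc["b", ["meta:mut=no", "meta:mut=yes"]].sum() == 0.0

    def test_missing_numeric_gets_training_median(self):
        meta = pd.DataFrame({"age": [40.0, np.nan, 60.0]}, index=["a", "b", "c"])
        out, _ = augment_with_metadata(self._features(["a", "b", "c"]), meta,
                                       numeric=["age"])
        assert out.loc["b", "meta:age"] == pytest.approx(0.5)  # median 50 -> midpoint

    def test_absent_column_errors(self):
        meta = pd.DataFrame({"age": [1]}, index=["a"])
        with pytest.raises(ValueError, match="height"):
            MetadataEncoder(numeric=("height",)).fit(meta)

    def test_query_reuses_training_statistics(self):
        meta = pd.DataFrame({"age": [30, 50, 70]}, index=["a", "b", "c"])
        _, enc = augment_with_metadata(self._features(["a", "b", "c"]), meta,
                                       numeric=["age"])
        qmeta = pd.DataFrame({"age": [90]}, index=["q"])
        out, _ = augment_with_metadata(self._features(["q"]), qmeta, encoder=enc)
        assert out.loc["q", "meta:age"] == 1.0  # clipped to training max
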