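"""Normalization, training-set selection, cross-validation, meshiness."""

import numpy as np
import pandas as pd
import pytest

from valvemorph import classify as cl
from valvemorph.morphometry import FEATURE_NAMES
from valvemorph.synthgen import ClassTableSpec, generate_feature_table


def _table(values_first_col, n=3):
    data = pd.DataFrame(
        np.tile(np.linspace(1, 2, n)[:, None], (1, len(FEATURE_NAMES))),
        columns=FEATURE_NAMES,
    )
    data.iloc[:, 0] = values_first_col
    return cl.FeatureTable(data)


class TestNormalization:
    def test_min_max_scaling(self):
        t = _table([2.0, 4.0, 6.0])
        out, _ = cl.normalize_features(t)
        np.testing.assert_allclose(out.data.iloc[:, 0].values, [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        t = _table([5.0, 5.0, 5.0])
        out, _ = cl.normalize_features(t)
        np.testing.assert_allclose(out.data.iloc[:, 0].values, 0.0)

    def test_round_trip(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=10, seed=2))
        out, rec = cl.normalize_features(t)
        back = rec.invert(out.data)
        non_const = t.data.max() > t.data.min()
        np.testing.assert_allclose(
            back.loc[:, non_const].values, t.data.loc[:, non_const].values, atol=1e-9
        )

    def test_idempotent_on_normalized_table(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=10, seed=2))
        out, _ = cl.normalize_features(t)
        again, rec2 = cl.normalize_features(out)
        non_const = out.data.max() > out.data.min()
        np.testing.assert_allclose(
            again.data.loc[:, non_const].values, out.data.loc[:, non_const].values,
            atol=1e-12,
        )

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            cl.normalize_features(
                cl.FeatureTable(pd.DataFrame(columns=FEATURE_NAMES, dtype=float))
            )


class TestTrainingSelection:
    def test_split_sizes(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=50, seed=0))
        labels = t.labels.iloc[
            list(range(10)) + list(range(50, 60))
        ]  # 10 tree + 10 mesh
        t_unlabeled = cl.FeatureTable(t.data)
        train, rest = cl.select_training_set(t_unlabeled, labels)
        assert len(train) == 20
        assert len(rest) == 80

    def test_single_class_raises(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=10, seed=0))
        only_tree = t.labels[t.labels == "tree"]
        with pytest.raises(ValueError):
            cl.select_training_set(cl.FeatureTable(t.data), only_tree)

    def test_empty_labels_raise(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=10, seed=0))
        with pytest.raises(ValueError):
            cl.select_training_set(cl.FeatureTable(t.data), pd.Series(dtype=object))


class TestCrossValidation:
    def test_separated_classes_are_learnable(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=30, separation=4.0, seed=1))
        nt, _ = cl.normalize_features(t)
        for method in ("RFC", "ETC"):
            res = cl.cross_validate(nt, method, k=5, repeats=5, seed=0)
            assert res.mean >= 0.95

    def test_permuted_labels_at_chance(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=30, separation=4.0, seed=1))
        nt, _ = cl.normalize_features(t)
        rng = np.random.default_rng(0)
        nt.labels = pd.Series(
            rng.permutation(nt.labels.values), index=nt.labels.index
        )
        res = cl.cross_validate(nt, "ETC", k=5, repeats=10, seed=0)
        se = 3 * np.sqrt(0.25 / len(t))
        assert abs(res.mean - 0.5) < 3 * max(se, res.sd)

    def test_duplicated_rows_perfectly_learnable(self):
        row = np.linspace(1, 22, len(FEATURE_NAMES))
        data = pd.DataFrame(
            np.vstack([row] * 10 + [row * 3] * 10), columns=FEATURE_NAMES
        )
        labels = pd.Series(["tree"] * 10 + ["mesh"] * 10)
        t = cl.FeatureTable(data, labels=labels)
        res = cl.cross_validate(t, "RFC", k=5, repeats=3, seed=0)
        assert res.mean == 1.0

    def test_k_below_two_raises(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=10, seed=0))
        with pytest.raises(ValueError):
            cl.cross_validate(t, "ETC", k=1)

    def test_determinism(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=20, separation=1.0, seed=4))
        nt, _ = cl.normalize_features(t)
        a = cl.cross_validate(nt, "RFC", k=5, repeats=3, seed=9)
        b = cl.cross_validate(nt, "RFC", k=5, repeats=3, seed=9)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_dtc_is_deprecated(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=10, separation=4.0, seed=0))
        with pytest.warns(DeprecationWarning):
            cl.EnsembleModel("DTC", seed=0).fit(t)


class TestMeshiness:
    @pytest.fixture
    def fitted(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=40, separation=4.0, seed=3))
        nt, rec = cl.normalize_features(t)
        model = cl.EnsembleModel("ETC", n_estimators=100, seed=0).fit(nt)
        return model, nt

    def test_probabilities_complementary(self, fitted):
        model, nt = fitted
        res = cl.predict_meshiness(model, nt)
        np.testing.assert_allclose(
            res.per_image["p_mesh"] + res.per_image["p_tree"], 1.0
        )
        assert res.per_image["p_mesh"].between(0, 1).all()

    def test_single_tree_probability_is_hard_vote(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=20, separation=4.0, seed=5))
        nt, _ = cl.normalize_features(t)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DeprecationWarning)
            model = cl.EnsembleModel("DTC", seed=0).fit(nt)
        res = cl.predict_meshiness(model, nt)
        assert set(np.unique(res.per_image["p_mesh"])) <= {0.0, 1.0}

    def test_condition_aggregation(self, fitted):
        model, nt = fitted
        nt.condition = pd.Series(
            ["A"] * 40 + ["B"] * 40, index=nt.data.index
        )
        res = cl.predict_meshiness(model, nt)
        assert set(res.per_condition.index) == {"A", "B"}
        assert (res.per_condition["n"] == 40).all()

    def test_unfitted_model_raises(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=5, seed=0))
        with pytest.raises(ValueError):
            cl.predict_meshiness(cl.EnsembleModel("ETC"), t)


class TestImportances:
    def test_importances_sum_to_one(self):
        t = generate_feature_table(ClassTableSpec(n_per_class=20, separation=2.0, seed=0))
        nt, _ = cl.normalize_features(t)
        model = cl.EnsembleModel("RFC", seed=0).fit(nt)
        assert cl.feature_importances(model).sum() == pytest.approx(1.0, abs=1e-9)

    def test_constructed_separability_ranks_known_features_top(self):
        # only total_mesh_area and total_branch_length differ between classes
        from valvemorph.synthgen import _BASE_MEANS

        base = np.array([_BASE_MEANS[f] for f in FEATURE_NAMES])
        sds = 0.15 * np.abs(base)
        means = {"tree": base.copy(), "mesh": base.copy()}
        for f, sign in (("total_mesh_area", 1), ("total_branch_length", -1)):
            j = FEATURE_NAMES.index(f)
            means["mesh"][j] += sign * 5 * sds[j]
        t = generate_feature_table(
            ClassTableSpec(n_per_class=40, feature_means=means,
                           feature_sds={"tree": sds, "mesh": sds}, seed=1)
        )
        nt, _ = cl.normalize_features(t)
        imp = cl.importance_report(nt, "ETC", repeats=5, seed=0).mean()
        assert set(imp.nlargest(2).index) == {"total_mesh_area", "total_branch_length"}

    def test_noise_feature_ranks_low(self):
        # every feature informative except one replaced by pure noise
        from valvemorph.synthgen import _BASE_MEANS

        base = np.array([_BASE_MEANS[f] for f in FEATURE_NAMES])
        sds = 0.15 * np.abs(base)
        means = {"tree": base.copy(), "mesh": base + 2.0 * sds}
        t = generate_feature_table(
            ClassTableSpec(n_per_class=30, feature_means=means,
                           feature_sds={"tree": sds, "mesh": sds}, seed=2)
        )
        rng = np.random.default_rng(0)
        data = t.data.copy()
        data["rimoportulae_per_area"] = rng.normal(0.5, 0.1, len(t))  # pure noise
        nt, _ = cl.normalize_features(cl.FeatureTable(data, t.labels))
        rep = cl.importance_report(nt, "RFC", repeats=40, seed=0)
        below_median = (
            rep["rimoportulae_per_area"] < rep.median(axis=1)
        ).mean()
        assert below_median >= 0.9
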