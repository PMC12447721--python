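"""Shapley attribution: exact oracle, kernel estimator, biomarker catalog."""

import numpy as np
import pytest

import symptomap as sm
from symptomap.shapley import AttributionMatrix, _all_proper_masks


def linear_f(X):
    return X[:, 0] + 2 * X[:, 1]


def product_f(X):
    return X[:, 0] * X[:, 1]


ZERO_BG2 = np.zeros((1, 2))


class TestExactShapley:
    def test_single_feature_gets_full_gap(self):
        phi = sm.exact_shapley(lambda X: 3 * X[:, 0], np.array([2.0]), np.zeros((1, 1)))
        np.testing.assert_allclose(phi, [6.0])

    def test_linear_function_splits_by_coefficient(self):
        phi = sm.exact_shapley(linear_f, np.array([1.0, 1.0]), ZERO_BG2)
        np.testing.assert_allclose(phi, [1.0, 2.0], atol=1e-12)

    def test_product_interaction_split_equally(self):
        phi = sm.exact_shapley(product_f, np.array([1.0, 1.0]), ZERO_BG2)
        np.testing.assert_allclose(phi, [0.5, 0.5], atol=1e-12)

    def test_efficiency_axiom(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        bg = rng.normal(size=(10, 5))

        def f(X):
            return np.sin(X[:, 0]) + X[:, 1] * X[:, 2] - X[:, 3] ** 2 + 0.5 * X[:, 4]

        phi = sm.exact_shapley(f, x, bg)
        ref = bg.mean(axis=0)
        assert phi.sum() == pytest.approx((f(x[None]) - f(ref[None])).item(), abs=1e-9)

    def test_symmetry_axiom(self):
        def f(X):
            return X[:, 0] + X[:, 1] + X[:, 2] ** 2

        phi = sm.exact_shapley(f, np.array([1.5, 1.5, 0.3]), np.zeros((1, 3)))
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_dummy_axiom(self):
        phi = sm.exact_shapley(lambda X: X[:, 0] * 2, np.array([1.0, 9.0]), ZERO_BG2)
        assert phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_linearity_axiom(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4)
        bg = rng.normal(size=(8, 4))
        f = lambda X: X[:, 0] * X[:, 1] + X[:, 2]
        g = lambda X: np.cos(X[:, 3]) + X[:, 0]
        phi_sum = sm.exact_shapley(lambda X: f(X) + g(X), x, bg)
        np.testing.assert_allclose(
            phi_sum, sm.exact_shapley(f, x, bg) + sm.exact_shapley(g, x, bg), atol=1e-9
        )

    def test_too_many_features_redirects_to_kernel(self):
        with pytest.raises(ValueError, match="kernel"):
            sm.exact_shapley(linear_f, np.zeros(16), np.zeros((1, 16)))


class TestKernelShapley:
    def test_full_enumeration_matches_exact_nonlinear(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=6)
        bg = rng.normal(size=(12, 6))

        def f(X):
            return np.tanh(X[:, 0]) + X[:, 1] * X[:, 2] + X[:, 3] - X[:, 4] * X[:, 5] ** 2

        exact = sm.exact_shapley(f, x, bg)
        kernel = sm.kernel_shapley(f, x, bg, n_coalitions=2**6 - 2, seed=0)
        np.testing.assert_allclose(kernel, exact, atol=1e-6)

    def test_local_accuracy_constraint(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        bg = rng.normal(size=(20, 10))
        f = lambda X: (X**2).sum(axis=1) + X[:, 0]
        phi = sm.kernel_shapley(f, x, bg, n_coalitions=200, seed=1)
        ref = bg.mean(axis=0)
        total = (f(x[None]) - f(ref[None])).item()
        assert phi.sum() == pytest.approx(total, abs=1e-6)

    def test_dummy_feature_zero(self):
        phi = sm.kernel_shapley(
            lambda X: X[:, 0], np.array([1.0, 5.0, -2.0]),
            np.zeros((1, 3)), n_coalitions=6, seed=0,
        )
        np.testing.assert_allclose(phi[1:], 0.0, atol=1e-6)

    def test_underdetermined_budget_rejected(self):
        with pytest.raises(ValueError, match="n_coalitions"):
            sm.kernel_shapley(linear_f, np.ones(8), np.zeros((1, 8)), n_coalitions=5)

    def test_estimate_improves_with_budget(self):
        rng = np.random.default_rng(4)
        m = 8
        x = rng.normal(size=m)
        bg = rng.normal(size=(10, m))

        def f(X):
            return X[:, 0] * X[:, 1] + np.abs(X[:, 2:]).sum(axis=1)

        exact = sm.exact_shapley(f, x, bg)
        errs = []
        for budget in (2 * m + 2, 8 * m, 2**m - 2):
            phi = sm.kernel_shapley(f, x, bg, n_coalitions=budget, seed=5)
            errs.append(np.abs(phi - exact).max())
        assert errs[-1] < errs[0]
        assert errs[-1] < 1e-6


class TestSubmodels:
    def test_submodel_matches_full_output_exactly(self, fitted_fixture_model, worked_fixture):
        X, Y, *_ = worked_fixture
        rng = np.random.default_rng(0)
        inputs = rng.normal(size=(100, 6))
        Xr = sm.OmicsMatrix(
            __import__("pandas").DataFrame(
                inputs, index=[f"r{i}" for i in range(100)],
                columns=fitted_fixture_model.feature_ids,
            )
        )
        full = sm.predict_scores(fitted_fixture_model, Xr)
        for i, name in enumerate(Y.schema.names):
            f = sm.extract_submodel(fitted_fixture_model, i)
            np.testing.assert_array_equal(f(inputs), full[name])

    def test_extraction_is_pure(self, fitted_fixture_model, worked_fixture):
        X, *_ = worked_fixture
        before = sm.predict_scores(fitted_fixture_model, X)
        sm.extract_submodel(fitted_fixture_model, 1)
        after = sm.predict_scores(fitted_fixture_model, X)
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_index_out_of_range(self, fitted_fixture_model):
        with pytest.raises(IndexError):
            sm.extract_submodel(fitted_fixture_model, 99)


class TestExplainAll:
    def test_one_attribution_matrix_per_output(self, fitted_fixture_model, worked_fixture):
        X, Y, *_ = worked_fixture
        atts = sm.explain_all(fitted_fixture_model, X, background_size=6, seed=0)
        assert [a.output_name for a in atts] == Y.schema.names

    def test_zero_weight_model_all_zero_phi(self, worked_fixture):
        X, Y, *_ = worked_fixture
        model = sm.build_model(sm.ArchitectureSpec(n_features=6), Y.schema, seed=0)
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        model.feature_ids = X.feature_ids
        atts = sm.explain_all(model, X, background_size=6, seed=0)
        np.testing.assert_allclose(atts[0].phi, 0.0, atol=1e-9)

    def test_deterministic_repeat(self, fitted_fixture_model, worked_fixture):
        X, *_ = worked_fixture
        a = sm.explain_all(fitted_fixture_model, X, background_size=6, seed=9)
        b = sm.explain_all(fitted_fixture_model, X, background_size=6, seed=9)
        np.testing.assert_array_equal(a[0].phi, b[0].phi)

    def test_local_accuracy_on_fixture(self, fitted_fixture_model, worked_fixture):
        X, *_ = worked_fixture
        atts = sm.explain_all(fitted_fixture_model, X, background_size=6, seed=0)
        for i, att in enumerate(atts):
            f = sm.extract_submodel(fitted_fixture_model, i)
            pred = f(X.data[fitted_fixture_model.feature_ids].to_numpy())
            np.testing.assert_allclose(att.base_value + att.phi.sum(axis=1), pred, atol=1e-3)

    def test_background_larger_than_data_errors(self, fitted_fixture_model, worked_fixture):
        X, *_ = worked_fixture
        with pytest.raises(ValueError, match="background"):
            sm.explain_all(fitted_fixture_model, X, background_size=500, seed=0)


def _att(name, phi, feats):
    return AttributionMatrix(
        output_name=name, phi=phi, base_value=0.0,
        feature_ids=feats, sample_ids=[f"s{i}" for i in range(phi.shape[0])],
    )


class TestCatalog:
    def _make_atts(self, importance_by_output, feats):
        return [
            _att(name, np.tile(np.asarray(imp, dtype=float), (3, 1)), feats)
            for name, imp in importance_by_output.items()
        ]

    def test_nine_of_twelve_boundary_is_disease_specific(self):
        feats = [f"f{i}" for i in range(6)]
        imp = {}
        for i in range(12):
            # f0 ranks top-2 in the first 9 outputs only; top_k=2
            imp[f"y{i}"] = [3.0 if i < 9 else 0.0, 2.0, 0.1, 0.1, 0.1, 1.0]
        atts = self._make_atts(imp, feats)
        cat = sm.categorize_biomarkers(atts, top_k=2, cutoff=0.75)
        assert "f0" in cat.disease_specific  # 9/12 = 0.75 qualifies (inclusive)
        assert "f1" in cat.disease_specific  # 12/12

    def test_single_output_contributor_is_symptom_specific(self):
        feats = ["a", "b", "c"]
        imp = {f"y{i}": [1.0, 0.9, 0.8 if i == 0 else 0.0] for i in range(4)}
        atts = self._make_atts(imp, feats)
        cat = sm.categorize_biomarkers(atts, top_k=2, cutoff=0.75)
        assert cat.symptom_specific["y0"] == []  # a, b are disease-level there
        # c only reaches top-2 nowhere (rank 3); never counted
        assert "c" not in cat.top_rank_counts

    def test_never_ranked_feature_in_neither_set(self):
        feats = ["a", "b", "never"]
        imp = {f"y{i}": [1.0, 0.9, 0.0] for i in range(3)}
        cat = sm.categorize_biomarkers(self._make_atts(imp, feats), top_k=2, cutoff=0.75)
        assert "never" not in cat.disease_specific
        assert all("never" not in v for v in cat.symptom_specific.values())

    def test_disease_and_symptom_sets_disjoint_per_output(self, fitted_fixture_model, worked_fixture):
        X, *_ = worked_fixture
        atts = sm.explain_all(fitted_fixture_model, X, background_size=6, seed=0)
        cat = sm.categorize_biomarkers(atts, top_k=3, cutoff=0.75)
        for out, feats in cat.symptom_specific.items():
            assert not set(feats) & set(cat.disease_specific)

    def test_top_k_exceeding_features_errors(self):
        feats = ["a", "b"]
        imp = {"y0": [1.0, 0.5], "y1": [1.0, 0.5]}
        with pytest.raises(ValueError):
            sm.categorize_biomarkers(self._make_atts(imp, feats), top_k=3)


class TestVarianceDecomposition:
    def test_shares_sum_to_one(self, fitted_fixture_model, worked_fixture):
        X, *_ = worked_fixture
        atts = sm.explain_all(fitted_fixture_model, X, background_size=6, seed=0)
        cat = sm.categorize_biomarkers(atts, top_k=3, cutoff=0.75)
        f = sm.extract_submodel(fitted_fixture_model, 0)
        pred = f(X.data[fitted_fixture_model.feature_ids].to_numpy())
        d, s, r = sm.variance_decomposition(atts[0], cat, pred)
        assert d + s + r == pytest.approx(1.0, abs=1e-9)
        assert min(d, s, r) >= 0

    def test_constant_predictor_is_all_residual(self):
        att = _att("y", np.zeros((5, 2)), ["a", "b"])
        cat = sm.BiomarkerCatalog(
            disease_specific=["a"], symptom_specific={"y": ["b"]},
            top_rank_counts={}, rankings={}, top_k=1, cutoff=0.75,
        )
        assert sm.variance_decomposition(att, cat, np.ones(5)) == (0.0, 0.0, 1.0)

    def test_shared_signal_dominates_disease_share(self):
        # prediction equals the summed phi of the disease features by construction
        rng = np.random.default_rng(0)
        phi = rng.normal(size=(50, 3))
        pred = phi[:, 0] + phi[:, 1]
        att = _att("y", phi, ["d1", "d2", "s1"])
        cat = sm.BiomarkerCatalog(
            disease_specific=["d1", "d2"], symptom_specific={"y": ["s1"]},
            top_rank_counts={}, rankings={}, top_k=2, cutoff=0.75,
        )
        d, s, r = sm.variance_decomposition(att, cat, pred)
        assert d > 0.8
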