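"""Architecture, losses, training mechanics, and the auxiliary score layer."""

import numpy as np
import pandas as pd
import pytest

import symptomap as sm
from symptomap.io import OutputSpec, ScoreSchema, standardize
from symptomap.model import head_dim, loss_and_grads, _forward


def twelve_continuous():
    return ScoreSchema(
        [OutputSpec(f"y{i}", "continuous", raw_min=0, raw_max=1) for i in range(12)]
    )


class TestArchitecture:
    def test_parameter_count_matches_layer_shape_sum(self):
        # (m*64+64) + (64*32+32) + n*(32*8+8) + n*(8*1+1) for linear heads
        arch = sm.ArchitectureSpec(n_features=100)
        model = sm.build_model(arch, twelve_continuous(), seed=0)
        expected = (100 * 64 + 64) + (64 * 32 + 32) + 12 * (32 * 8 + 8) + 12 * (8 * 1 + 1)
        assert model.n_parameters() == expected == 11820

    def test_one_sublayer_and_head_per_output(self, worked_fixture):
        X, Y, *_ = worked_fixture
        model = sm.build_model(sm.ArchitectureSpec(n_features=6), Y.schema, seed=0)
        for spec in Y.schema.outputs:
            assert model.params[f"W3:{spec.name}"].shape == (32, 8)
            assert model.params[f"W4:{spec.name}"].shape == (8, head_dim(spec))

    def test_widths_default_64_32_8(self):
        arch = sm.ArchitectureSpec(n_features=10)
        assert (arch.width_z1, arch.width_z2, arch.width_z3) == (64, 32, 8)

    def test_he_normal_initialization_scale(self):
        arch = sm.ArchitectureSpec(n_features=400)
        model = sm.build_model(arch, twelve_continuous(), seed=3)
        w = model.params["W1"]
        assert w.std() == pytest.approx(np.sqrt(2.0 / 400), rel=0.1)
        assert abs(w.mean()) < 0.01
        assert np.all(model.params["b1"] == 0)

    def test_same_seed_identical_init(self):
        arch = sm.ArchitectureSpec(n_features=20)
        a = sm.build_model(arch, twelve_continuous(), seed=5)
        b = sm.build_model(arch, twelve_continuous(), seed=5)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_zero_output_schema_rejected(self):
        with pytest.raises(ValueError):
            sm.build_model(sm.ArchitectureSpec(n_features=5), ScoreSchema([]), seed=0)

    def test_dropout_train_mode_only(self):
        arch = sm.ArchitectureSpec(n_features=8, dropout_rate=0.5)
        schema = twelve_continuous()
        model = sm.build_model(arch, schema, seed=0)
        X = np.random.default_rng(0).normal(size=(40, 8))
        infer = _forward(model.params, arch, schema, X, train=False)
        again = _forward(model.params, arch, schema, X, train=False)
        np.testing.assert_array_equal(infer["out"]["y0"]["pred"], again["out"]["y0"]["pred"])
        rng = np.random.default_rng(1)
        trained = _forward(model.params, arch, schema, X, train=True, rng=rng)
        assert "M1" in trained and "M2" in trained
        # inverted dropout: zeros appear in the mask, survivors are upscaled
        assert (trained["M1"] == 0).any() and trained["M1"].max() == pytest.approx(2.0)


class TestLosses:
    @pytest.mark.parametrize(
        "dtype,expected", [("binary", "bce"), ("categorical", "cce"), ("continuous", "huber")]
    )
    def test_loss_assignment_by_type(self, dtype, expected):
        spec = OutputSpec("s", dtype, n_levels=5 if dtype == "categorical" else None)
        assert sm.assign_loss(spec) == expected

    @pytest.mark.parametrize("e,expected", [(0.0, 0.0), (0.5, 0.125), (3.0, 2.5), (-3.0, 2.5)])
    def test_huber_piecewise_values(self, e, expected):
        assert sm.huber(e, 0.0, delta=1.0) == pytest.approx(expected)

    def test_huber_requires_positive_delta(self):
        with pytest.raises(ValueError):
            sm.huber(1.0, 0.0, delta=0.0)

    def test_l2_penalty_zero_for_zero_weights(self):
        arch = sm.ArchitectureSpec(n_features=4, dropout_rate=0.0)
        schema = ScoreSchema([OutputSpec("y", "continuous")])
        model = sm.build_model(arch, schema, seed=0)
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        X = np.zeros((3, 4))
        total, _, per = loss_and_grads(model.params, arch, schema, X, {"y": np.zeros(3)})
        assert total == pytest.approx(0.0)

    def test_l2_applies_to_kernels_not_biases(self):
        arch = sm.ArchitectureSpec(n_features=4, dropout_rate=0.0, l2_lambda=0.01)
        schema = ScoreSchema([OutputSpec("y", "continuous")])
        model = sm.build_model(arch, schema, seed=0)
        X = np.zeros((2, 4))
        y = {"y": np.array([np.nan, np.nan])}  # no data loss: only the penalty remains
        total, grads, _ = loss_and_grads(model.params, arch, schema, X, y)
        expected = 0.005 * sum(
            (v**2).sum() for k, v in model.params.items() if k.startswith("W")
        )
        assert total == pytest.approx(expected)
        np.testing.assert_allclose(grads["b1"], 0.0)
        np.testing.assert_allclose(grads["W2"], 0.01 * model.params["W2"])

    def test_gradients_match_finite_differences(self, worked_fixture):
        X, Y, *_ = worked_fixture
        arch = sm.ArchitectureSpec(n_features=6, dropout_rate=0.0)
        model = sm.build_model(arch, Y.schema, seed=2)
        Xs, _ = standardize(X)
        targets = {n: Y.data[n].to_numpy() for n in Y.schema.names}
        _, grads, _ = loss_and_grads(model.params, arch, Y.schema, Xs.values, targets)
        rng = np.random.default_rng(0)
        for key in ["W1", "W2", "W3:fatigue", "W4:flare", "b2", "b4:fatigue"]:
            p = model.params[key]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps = 1e-6
                p[idx] += eps
                up, *_ = loss_and_grads(model.params, arch, Y.schema, Xs.values, targets)
                p[idx] -= 2 * eps
                dn, *_ = loss_and_grads(model.params, arch, Y.schema, Xs.values, targets)
                p[idx] += eps
                fd = (up - dn) / (2 * eps)
                denom = max(abs(fd) + abs(grads[key][idx]), 1e-8)
                assert abs(fd - grads[key][idx]) / denom < 1e-4


class TestTraining:
    def test_training_reduces_loss_on_signal(self, small_cohort):
        X, Y, labels, truth = small_cohort
        model = sm.build_model(sm.ArchitectureSpec(n_features=X.n_features), Y.schema, seed=0)
        fitted = sm.train(model, X, Y, sm.Hyperparams(epochs=60, batch_size=16, seed=0))
        assert fitted.history["total"][-1] < 0.5 * fitted.history["total"][0]

    def test_seeded_determinism(self, worked_fixture):
        X, Y, *_ = worked_fixture
        hp = sm.Hyperparams(epochs=10, batch_size=4, seed=3)
        arch = sm.ArchitectureSpec(n_features=6)
        a = sm.train(sm.build_model(arch, Y.schema, seed=3), X, Y, hp)
        b = sm.train(sm.build_model(arch, Y.schema, seed=3), X, Y, hp)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_output_permutation_leaves_loss_trajectories(self, worked_fixture):
        # outputs carry equal weight: reordering the schema must not change any
        # output's own loss trace (per-output init streams are keyed by name)
        X, Y, *_ = worked_fixture
        hp = sm.Hyperparams(epochs=5, batch_size=4, seed=3)
        arch = sm.ArchitectureSpec(n_features=6)
        fwd = sm.train(sm.build_model(arch, Y.schema, seed=3), X, Y, hp)
        perm_schema = ScoreSchema(list(reversed(Y.schema.outputs)))
        Yp = sm.ScoreMatrix(Y.data[perm_schema.names], perm_schema)
        rev = sm.train(sm.build_model(arch, perm_schema, seed=3), X, Yp, hp)
        for name in Y.schema.names:
            np.testing.assert_allclose(fwd.history[name], rev.history[name], rtol=1e-6)

    def test_missing_targets_are_masked(self, worked_fixture):
        X, Y, *_ = worked_fixture
        Ymiss = Y.data.copy()
        Ymiss.iloc[:3, 0] = np.nan
        Ym = sm.ScoreMatrix(Ymiss, Y.schema)
        fitted = sm.train(
            sm.build_model(sm.ArchitectureSpec(n_features=6), Y.schema, seed=1),
            X, Ym, sm.Hyperparams(epochs=5, batch_size=4, seed=1),
        )
        assert np.isfinite(fitted.history["total"]).all()


class TestPrediction:
    def test_categorical_probabilities_sum_to_one(self, fitted_fixture_model, worked_fixture):
        X, Y, *_ = worked_fixture
        preds = sm.predict_scores(fitted_fixture_model, X)
        # the fixture schema has no categorical head; use a fresh 3-level one
        schema = ScoreSchema([OutputSpec("c", "categorical", n_levels=3)])
        model = sm.build_model(sm.ArchitectureSpec(n_features=6), schema, seed=0)
        model.feature_ids = X.feature_ids
        p = sm.predict_scores(model, X)["c"]
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert preds["flare"].min() > 0 and preds["flare"].max() < 1

    def test_duplicated_row_gets_identical_prediction(self, fitted_fixture_model, worked_fixture):
        X, *_ = worked_fixture
        dup = sm.OmicsMatrix(
            pd.DataFrame(
                np.vstack([X.values[0], X.values[0]]),
                index=["a", "b"], columns=X.feature_ids,
            )
        )
        preds = sm.predict_scores(fitted_fixture_model, dup)
        for v in preds.values():
            np.testing.assert_array_equal(v[0], v[1])

    def test_zero_weight_continuous_head_predicts_zero(self, worked_fixture):
        X, Y, *_ = worked_fixture
        model = sm.build_model(sm.ArchitectureSpec(n_features=6), Y.schema, seed=0)
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        model.feature_ids = X.feature_ids
        preds = sm.predict_scores(model, X)
        np.testing.assert_array_equal(preds["fatigue"], 0.0)

    def test_serialization_roundtrip_bitwise(self, fitted_fixture_model, worked_fixture, tmp_path):
        X, *_ = worked_fixture
        fitted_fixture_model.save(tmp_path / "bundle")
        back = sm.TrainedModel.load(tmp_path / "bundle")
        a = sm.predict_scores(fitted_fixture_model, X)
        b = sm.predict_scores(back, X)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_width_mismatch_errors(self, fitted_fixture_model):
        bad = sm.OmicsMatrix(pd.DataFrame(np.zeros((2, 3)), columns=list("abc")))
        with pytest.raises(ValueError):
            sm.predict_scores(fitted_fixture_model, bad)


class TestScoreLayer:
    def test_zero_eta_rejected_and_zero_steps_identity(self):
        w0 = sm.ScoreLayerWeights(w=np.ones(3), bias=0.0)
        with pytest.raises(ValueError):
            sm.score_layer_fit(np.zeros((4, 3)), np.zeros(4), w0, eta=0.0)
        w, trace = sm.score_layer_fit(np.ones((4, 3)), np.ones(4), w0, n_steps=0, eta=0.1)
        np.testing.assert_array_equal(w.w, w0.w)

    def test_zero_weights_predict_half(self):
        w = sm.ScoreLayerWeights(w=np.zeros(3), bias=0.0)
        np.testing.assert_allclose(w.predict(np.random.default_rng(0).normal(size=(5, 3))), 0.5)

    def test_converges_on_separable_scores(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 20)
        scores = y[:, None] + rng.normal(0, 0.05, size=(40, 3))
        w0 = sm.score_layer_init(scores, y)
        w, trace = sm.score_layer_fit(scores, y, w0, n_steps=500, eta=0.5)
        acc = ((w.predict(scores) >= 0.5).astype(int) == y).mean()
        assert acc == 1.0
        assert trace[-1] <= trace[0]

    def test_clinical_init_unit_norm(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 30)
        scores = y[:, None] * 0.5 + rng.normal(0, 0.3, size=(60, 4))
        w0 = sm.score_layer_init(scores, y)
        assert np.linalg.norm(w0.w) == pytest.approx(1.0)


class TestCombinedOmics:
    def _atts(self, X, strengths):
        return [
            sm.AttributionMatrix(
                output_name="y",
                phi=np.tile(strengths, (X.n_samples, 1)),
                base_value=0.0,
                feature_ids=X.feature_ids,
                sample_ids=X.sample_ids,
            )
        ]

    def test_top_counts_select_by_mean_abs_attribution(self):
        df = pd.DataFrame(np.ones((4, 3)), columns=["a", "b", "c"], index=list("wxyz"))
        X = sm.OmicsMatrix(df, kind="immune")
        atts = {"immune": self._atts(X, np.array([0.1, 0.9, 0.5]))}
        combined = sm.build_combined_omics(atts, {"immune": X}, {"immune": 2})
        assert combined.feature_ids == ["b", "c"]
        assert combined.kind == "combined"

    def test_counts_exceeding_features_error(self):
        df = pd.DataFrame(np.ones((2, 2)), columns=["a", "b"], index=["s", "t"])
        X = sm.OmicsMatrix(df, kind="immune")
        atts = {"immune": self._atts(X, np.array([1.0, 2.0]))}
        with pytest.raises(ValueError):
            sm.build_combined_omics(atts, {"immune": X}, {"immune": 3})

    def test_duplicate_names_get_kind_prefix(self):
        dfa = pd.DataFrame(np.ones((2, 1)), columns=["shared_name"], index=["s", "t"])
        dfb = pd.DataFrame(np.zeros((2, 1)), columns=["shared_name"], index=["s", "t"])
        Xa = sm.OmicsMatrix(dfa, kind="immune")
        Xb = sm.OmicsMatrix(dfb, kind="blood")
        atts = {
            "immune": self._atts(Xa, np.array([1.0])),
            "blood": self._atts(Xb, np.array([1.0])),
        }
        combined = sm.build_combined_omics(
            atts, {"immune": Xa, "blood": Xb}, {"immune": 1, "blood": 1}
        )
        assert len(set(combined.feature_ids)) == 2
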