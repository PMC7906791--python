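"""GRU cell equations, losses, training, cross-validation, hidden-state PCA.

The gate equations are checked against an independent scalar
re-implementation (the oracle), gradients against finite differences, and
the training loop against analytic limits and its determinism contract.
"""

import numpy as np
import pytest

from slowosc.gru import (
    GRUForecaster,
    GRUParams,
    LayerParams,
    TrainConfig,
    cc_objective,
    crossvalidate,
    gru_step,
    hidden_state_pca,
    hyperparameter_search,
    readout,
    _backward_sequence,
    _forward_sequence,
    _loss_and_grad,
)
from slowosc.preprocess import TargetPair
from slowosc.timeseries import TimeSeries


def scalar_gru_oracle(layer: LayerParams, x: float, h_prev: np.ndarray):
    """Element-by-element evaluation of the four gate equations."""
    H = layer.hidden_size
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    r = np.empty(H)
    z = np.empty(H)
    n = np.empty(H)
    h = np.empty(H)
    for i in range(H):
        pre_r = layer.W_ir[i, 0] * x + layer.b_ir[i] + layer.b_hr[i]
        pre_z = layer.W_iz[i, 0] * x + layer.b_iz[i] + layer.b_hz[i]
        a = layer.b_hn[i]
        for j in range(H):
            pre_r += layer.W_hr[i, j] * h_prev[j]
            pre_z += layer.W_hz[i, j] * h_prev[j]
            a += layer.W_hn[i, j] * h_prev[j]
        r[i] = sig(pre_r)
        z[i] = sig(pre_z)
        n[i] = np.tanh(layer.W_in[i, 0] * x + layer.b_in[i] + r[i] * a)
        h[i] = (1.0 - z[i]) * n[i] + z[i] * h_prev[i]
    return r, z, n, h


def _tiny_pairs(rng, n_pairs=6, T=160, label="tr"):
    pairs = []
    for k in range(n_pairs):
        x = np.sin(2 * np.pi * 0.03 * np.arange(T) + rng.uniform(0, 2 * np.pi))
        x = x + 0.1 * rng.standard_normal(T)
        pairs.append(TargetPair(
            input=TimeSeries(x[:T - 10], dt=1.0, label=f"{label}{k}"),
            target=TimeSeries(x[10:], dt=1.0, label=f"{label}{k}_t"),
            shift=10.0,
        ))
    return pairs


TINY = TrainConfig(hidden_size=8, n_layers=1, loss="cc", learning_rate=0.01,
                   l2=0.0, batch_size=3, n_epochs=8, washout=20)


class TestGruStep:
    def test_matches_scalar_oracle_on_random_instances(self, rng):
        for _ in range(100):
            H = int(rng.integers(1, 5))
            layer = LayerParams.init(1, H, rng)
            x = float(rng.standard_normal())
            h_prev = rng.standard_normal(H)
            state = gru_step(layer, [x], h_prev)
            r, z, n, h = scalar_gru_oracle(layer, x, h_prev)
            np.testing.assert_allclose(state.r, r, atol=1e-10)
            np.testing.assert_allclose(state.z, z, atol=1e-10)
            np.testing.assert_allclose(state.n, n, atol=1e-10)
            np.testing.assert_allclose(state.h, h, atol=1e-10)

    def test_zero_parameters_halve_state_each_step(self):
        layer = LayerParams.zeros(1, 4)
        h = np.array([1.0, -2.0, 0.5, 3.0])
        h0 = h.copy()
        for t in range(1, 21):
            state = gru_step(layer, [0.7], h)
            np.testing.assert_allclose(state.r, 0.5)
            np.testing.assert_allclose(state.z, 0.5)
            np.testing.assert_allclose(state.n, 0.0)
            h = state.h
            np.testing.assert_allclose(h, h0 / 2.0**t, rtol=0, atol=0)

    def test_gates_strictly_inside_unit_interval(self, rng):
        layer = LayerParams.init(1, 6, rng)
        state = gru_step(layer, [10.0], 5 * rng.standard_normal(6))
        assert np.all((state.r > 0) & (state.r < 1))
        assert np.all((state.z > 0) & (state.z < 1))
        assert np.all((state.n > -1) & (state.n < 1))

    def test_forced_update_gate_preserves_state(self, rng):
        # z == 1 (large positive update-gate bias): pure memory, h(t) = h(0)
        layer = LayerParams.init(1, 4, rng)
        layer.b_iz[:] = 50.0
        layer.b_hz[:] = 50.0
        layer.W_iz[:] = 0.0
        layer.W_hz[:] = 0.0
        h0 = rng.standard_normal(4)
        h = h0.copy()
        for _ in range(30):
            h = gru_step(layer, [rng.standard_normal()], h).h
        np.testing.assert_allclose(h, h0, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        layer = LayerParams.init(1, 4, rng)
        with pytest.raises(ValueError):
            gru_step(layer, [1.0], np.zeros(5))


class TestReadout:
    def test_zero_weights_zero_output(self, rng):
        params = GRUParams.init(4, seed=0)
        params.w_out[:] = 0.0
        params.b_out = 0.0
        assert readout(params, rng.standard_normal(4)) == 0.0

    def test_one_hot_selects_state_entry(self, rng):
        params = GRUParams.init(4, seed=0)
        params.w_out[:] = 0.0
        params.w_out[2] = 1.0
        params.b_out = 0.0
        h = rng.standard_normal(4)
        assert readout(params, h) == pytest.approx(h[2])

    def test_residual_identity_path(self):
        params = GRUParams.init(4, residual=True, seed=0)
        params.w_out[:] = 0.0
        params.w_out[4] = 1.0  # residual weight
        params.b_out = 0.0
        assert readout(params, np.zeros(4), [0.73]) == pytest.approx(0.73)


class TestCcObjective:
    def test_perfect_prediction(self, rng):
        x = rng.standard_normal(50)
        assert cc_objective(x, x) == pytest.approx(-1.0)

    def test_anticorrelated(self, rng):
        x = rng.standard_normal(50)
        assert cc_objective(x, -x) == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        x = rng.standard_normal(50)
        assert cc_objective(x + 5.0, x) == pytest.approx(-1.0)

    def test_mse_plus_cc_combination(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        expected = np.mean((x - y) ** 2) - np.corrcoef(x, y)[0, 1]
        assert cc_objective(x, y, kind="mse+cc") == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cc_objective(np.ones(10), np.arange(10.0))


class TestGradients:
    @pytest.mark.parametrize("loss", ["mse", "cc", "mse+cc"])
    def test_backward_matches_finite_differences(self, rng, loss):
        T, B, H = 25, 2, 4
        X = rng.standard_normal((T, B))
        Y = rng.standard_normal((T, B))
        params = GRUParams.init(H, n_layers=2, residual=True, seed=1)
        wash = 5

        def total_loss():
            y, _, _ = _forward_sequence(params, X, store=False)
            return np.mean([
                _loss_and_grad(y[wash:, b], Y[wash:, b], loss)[0]
                for b in range(B)
            ])

        y, h_seq, caches = _forward_sequence(params, X, store=True)
        dY = np.zeros_like(y)
        for b in range(B):
            _, g = _loss_and_grad(y[wash:, b], Y[wash:, b], loss)
            dY[wash:, b] = g / B
        grads = _backward_sequence(params, X, caches, h_seq, dY)

        eps = 1e-6
        checks = [
            (params.w_out, grads["w_out"], (1,)),
            (params.layers[0].W_hn, grads["layers"][0]["W_hn"], (2, 1)),
            (params.layers[1].W_ir, grads["layers"][1]["W_ir"], (0, 2)),
            (params.layers[0].b_in, grads["layers"][0]["b_in"], (3,)),
        ]
        for arr, g_arr, idx in checks:
            old = arr[idx]
            arr[idx] = old + eps
            lp = total_loss()
            arr[idx] = old - eps
            lm = total_loss()
            arr[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert g_arr[idx] == pytest.approx(fd, abs=1e-6)


class TestTraining:
    def test_deterministic_loss_trajectory(self, rng):
        pairs = _tiny_pairs(rng)
        r1 = GRUForecaster(pairs, TINY).fit(params_init_seed=4)
        r2 = GRUForecaster(pairs, TINY).fit(params_init_seed=4)
        np.testing.assert_array_equal(r1.loss_history, r2.loss_history)

    def test_cc_loss_invariant_to_affine_target_rescaling(self, rng):
        pairs = _tiny_pairs(rng)
        scaled = [
            TargetPair(
                input=p.input.copy_with(),
                target=p.target.copy_with(values=3.0 * p.target.values + 2.0),
                shift=p.shift,
            )
            for p in pairs
        ]
        r1 = GRUForecaster(pairs, TINY).fit(params_init_seed=4)
        r2 = GRUForecaster(scaled, TINY).fit(params_init_seed=4)
        np.testing.assert_allclose(r1.loss_history, r2.loss_history, atol=1e-9)

    def test_training_reduces_cc_loss(self, rng):
        pairs = _tiny_pairs(rng, n_pairs=8)
        cfg = TrainConfig(hidden_size=12, loss="cc", learning_rate=0.02,
                          l2=0.0, batch_size=4, n_epochs=25, washout=20)
        res = GRUForecaster(pairs, cfg).fit(params_init_seed=0)
        assert res.loss_history[-1] < res.loss_history[0] - 0.2

    def test_multilayer_dropout_residual_trains_and_reduces_loss(self, rng):
        # rat-like architecture at toy scale: 2 layers, inter-layer
        # dropout, residual readout
        pairs = _tiny_pairs(rng, n_pairs=6)
        cfg = TrainConfig(hidden_size=10, n_layers=2, loss="cc",
                          learning_rate=0.02, l2=1e-4, dropout=0.13,
                          residual_connection=True, batch_size=3,
                          n_epochs=15, washout=20)
        res = GRUForecaster(pairs, cfg).fit(params_init_seed=1)
        assert np.isfinite(res.loss_history).all()
        assert res.loss_history[-1] < res.loss_history[0]
        rec = res.predict(pairs[0])
        assert np.isfinite(rec.prediction.values).all()

    def test_washout_excluded_from_scores(self, rng):
        pairs = _tiny_pairs(rng)
        res = GRUForecaster(pairs, TINY).fit(params_init_seed=0)
        rec = res.predict(pairs[0])
        # post-washout length: (T - shift) - washout
        assert len(rec.prediction) == len(pairs[0].input) - TINY.washout
        assert len(rec.target) == len(rec.prediction)

    def test_prewashout_perturbation_keeps_score_lengths(self, rng):
        pairs = _tiny_pairs(rng)
        res = GRUForecaster(pairs, TINY).fit(params_init_seed=0)
        rec0 = res.predict(pairs[0])
        perturbed = TargetPair(
            input=pairs[0].input.copy_with(
                values=np.concatenate([
                    pairs[0].input.values[:10] + 5.0,
                    pairs[0].input.values[10:],
                ])
            ),
            target=pairs[0].target.copy_with(),
            shift=10.0,
        )
        rec1 = res.predict(perturbed)
        assert len(rec1.prediction) == len(rec0.prediction)

    def test_trace_shorter_than_washout_rejected(self, rng):
        pairs = _tiny_pairs(rng, T=30)
        with pytest.raises(ValueError, match="washout"):
            GRUForecaster(pairs, TINY.__class__(**{
                **TINY.__dict__, "washout": 50}))

    def test_save_load_roundtrip(self, rng, tmp_path):
        pairs = _tiny_pairs(rng)
        res = GRUForecaster(pairs, TINY).fit(params_init_seed=0)
        path = tmp_path / "model.json"
        res.save(path)
        loaded = res.__class__.load(path)
        rec_a = res.predict(pairs[0])
        rec_b = loaded.predict(pairs[0])
        np.testing.assert_allclose(rec_a.prediction.values,
                                   rec_b.prediction.values, atol=1e-12)

    def test_summary_mentions_architecture(self, rng):
        res = GRUForecaster(_tiny_pairs(rng), TINY).fit(params_init_seed=0)
        text = res.summary()
        assert "hidden size" in text and "washout" in text


class TestCrossValidation:
    def test_fold_accounting(self, rng):
        subjects = [_tiny_pairs(rng, n_pairs=3, label=f"s{i}_")
                    for i in range(4)]
        table = crossvalidate(subjects, TINY)
        assert len(table) == 12
        assert sorted(table["fold"].unique()) == [0, 1, 2, 3]
        # every trace scored exactly once
        assert table["label"].is_unique

    def test_fold_scores_invariant_to_subject_permutation(self, rng):
        subjects = [_tiny_pairs(rng, n_pairs=3, label=f"s{i}_")
                    for i in range(3)]
        t1 = crossvalidate(subjects, TINY)
        t2 = crossvalidate(subjects[::-1], TINY)
        m1 = t1.set_index("label")["cc"].sort_index()
        m2 = t2.set_index("label")["cc"].sort_index()
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-12)

    def test_homogeneous_data_heldout_close_to_training_scores(self, rng):
        subjects = [_tiny_pairs(rng, n_pairs=4, label=f"s{i}_")
                    for i in range(3)]
        cfg = TrainConfig(hidden_size=12, loss="cc", learning_rate=0.02,
                          l2=0.0, batch_size=4, n_epochs=25, washout=20)
        table = crossvalidate(subjects, cfg)
        res = GRUForecaster([p for s in subjects for p in s], cfg).fit(0)
        train_cc = res.score_pairs([p for s in subjects for p in s])["cc"].mean()
        assert abs(table["cc"].mean() - train_cc) < 0.1

    def test_single_fold_rejected(self, rng):
        with pytest.raises(ValueError, match="folds"):
            crossvalidate([_tiny_pairs(rng)], TINY)

    def test_empty_fold_rejected(self, rng):
        with pytest.raises(ValueError, match="no traces"):
            crossvalidate([_tiny_pairs(rng), []], TINY)


class TestHyperparameterSearch:
    def test_collapsed_space_returns_single_point(self, rng):
        subjects = [_tiny_pairs(rng, n_pairs=2, label=f"s{i}_")
                    for i in range(2)]
        space = {"hidden_size": 6, "n_layers": 1, "loss": ["cc"],
                 "learning_rate": 0.01, "l2": 0.0, "batch_size": 2,
                 "n_epochs": 3}
        cfg, log = hyperparameter_search(subjects, space, n_evals=1, seed=0,
                                         washout=20)
        assert cfg.hidden_size == 6
        assert len(log) == 1

    def test_degenerate_config_loses_to_sane_one(self, rng):
        subjects = [_tiny_pairs(rng, n_pairs=2, label=f"s{i}_")
                    for i in range(2)]
        # two-point space: lr 1e5 diverges, lr 0.01 trains
        space = {"hidden_size": 6, "n_layers": 1, "loss": ["cc"],
                 "learning_rate": ("log", 1e-2, 1e-2 + 1e-9), "l2": 0.0,
                 "batch_size": 2, "n_epochs": 3}
        bad_space = dict(space, learning_rate=1e6)
        cfg_good, log_good = hyperparameter_search(subjects, space, n_evals=2,
                                                   seed=0, washout=20)
        _, log_bad = hyperparameter_search(subjects, bad_space, n_evals=1,
                                           seed=0, washout=20)
        assert log_good["score"].max() > -np.inf
        assert np.isneginf(log_bad["score"]).all() or (
            log_bad["score"] < log_good["score"].max()).all()

    def test_zero_evals_rejected(self, rng):
        with pytest.raises(ValueError):
            hyperparameter_search([_tiny_pairs(rng)], {}, n_evals=0)

    def test_table_presets_available(self):
        from slowosc.gru import HUMAN_PRESET, RAT_PRESET

        assert HUMAN_PRESET.n_layers == 1
        assert HUMAN_PRESET.hidden_size == 88
        assert HUMAN_PRESET.loss == "cc"
        assert HUMAN_PRESET.learning_rate == pytest.approx(0.00121)
        assert HUMAN_PRESET.l2 == pytest.approx(0.0221)
        assert HUMAN_PRESET.batch_size == 10
        assert HUMAN_PRESET.n_epochs == 69
        assert HUMAN_PRESET.washout == 250
        assert RAT_PRESET.n_layers == 2
        assert RAT_PRESET.hidden_size == 290
        assert RAT_PRESET.dropout == pytest.approx(0.128)
        assert RAT_PRESET.residual_connection is True
        assert RAT_PRESET.batch_size == 22
        assert RAT_PRESET.n_epochs == 87


class TestHiddenStatePca:
    def test_explained_variance_properties(self, rng):
        pairs = _tiny_pairs(rng)
        res = GRUForecaster(pairs, TINY).fit(params_init_seed=0)
        scores, ratio = hidden_state_pca(res, pairs[0])
        assert scores.shape[0] == len(pairs[0].input) - TINY.washout
        assert np.all(np.diff(ratio) <= 1e-12)
        assert ratio.sum() == pytest.approx(1.0)

    def test_rank_one_states_first_component_explains_all(self, rng):
        pairs = _tiny_pairs(rng)
        res = GRUForecaster(pairs, TINY).fit(params_init_seed=0)
        H = res.hidden_states(pairs[0])
        direction = rng.standard_normal(H.shape[1])
        line = np.outer(H[:, 0], direction)  # rank-1 surrogate states
        centered = line - line.mean(axis=0)
        _, s, _ = np.linalg.svd(centered, full_matrices=False)
        var = s**2
        assert var[0] / var.sum() == pytest.approx(1.0)

    def test_pc1_tracks_input_better_than_pc3(self, rng):
        pairs = _tiny_pairs(rng, n_pairs=8)
        cfg = TrainConfig(hidden_size=12, loss="cc", learning_rate=0.02,
                          l2=0.0, batch_size=4, n_epochs=25, washout=20)
        res = GRUForecaster(pairs, cfg).fit(params_init_seed=0)
        scores, _ = hidden_state_pca(res, pairs[0])
        x = pairs[0].input.values[cfg.washout:]
        c1 = abs(np.corrcoef(scores[:, 0], x)[0, 1])
        c3 = abs(np.corrcoef(scores[:, 2], x)[0, 1])
        assert c1 > c3
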