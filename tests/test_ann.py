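"""Network core: input assembly, forward pass, cost, and
Levenberg–Marquardt training with Bayesian regularization."""

import math

import numpy as np
import pytest

import gaitmode as gm
from gaitmode.ann import (N_DELAYS, NetworkModel, TrainConfig, TrainingSet,
                          build_input_matrix, build_input_vector, cost,
                          forward, logsig, predict_stream, train)
from gaitmode.streams import ProcessedSignals


def _model(rng=None, mean=None, scale=None):
    rng = rng or np.random.default_rng(0)
    return NetworkModel(
        w_h=rng.normal(size=(10, 12)), b_h=rng.normal(size=10),
        w_o=rng.normal(size=(3, 10)), b_o=rng.normal(size=3),
        input_mean=np.zeros(12) if mean is None else mean,
        input_scale=np.ones(12) if scale is None else scale,
    )


class TestLogsig:
    def test_zero_maps_to_half(self):
        assert logsig(0.0) == 0.5

    @pytest.mark.parametrize("n", [1.0, 3.7, 50.0])
    def test_symmetry(self, n):
        assert np.isclose(logsig(-n), 1.0 - logsig(n), atol=1e-15)

    def test_closed_form_at_ten(self):
        assert np.isclose(logsig(10.0), 1.0 / (1.0 + math.exp(-10.0)), atol=1e-15)
        assert round(logsig(10.0), 7) == 0.9999546

    def test_stable_at_extremes(self):
        assert logsig(-750.0) == 0.0
        assert logsig(750.0) == 1.0


class TestBuildInput:
    def test_windows_at_means_give_zero_vector(self):
        mean = np.arange(12, dtype=float)
        m = _model(mean=mean, scale=np.full(12, 2.0))
        x, padded = build_input_vector(mean[:6], mean[6:], m)
        assert np.allclose(x, 0.0) and not padded

    def test_concatenation_order_and_length(self):
        m = _model()
        x, _ = build_input_vector(np.full(6, 0.1), np.full(6, 5.0), m)
        assert x.shape == (12,)
        assert np.allclose(x[:6], 0.1) and np.allclose(x[6:], 5.0)

    def test_short_window_padded_with_first_sample(self):
        m = _model()
        x, padded = build_input_vector([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], m)
        assert padded
        assert np.allclose(x[:6], [1, 1, 1, 1, 2, 3])

    def test_matrix_matches_per_sample_assembly(self):
        rng = np.random.default_rng(3)
        v, th = rng.normal(size=40), rng.normal(size=40)
        X = build_input_matrix(v, th)
        m = _model()
        for t in [0, 3, 17, 39]:
            lo = max(0, t - N_DELAYS + 1)
            x, _ = build_input_vector(v[lo:t + 1], th[lo:t + 1], m)
            assert np.allclose((X[t] - m.input_mean) / m.input_scale, x)


class TestForward:
    def test_zero_model_outputs_zero(self):
        m = _model()
        m.unpack(np.zeros(m.n_params))
        y = forward(m, np.ones(12))
        assert np.allclose(y, 0.0)  # w_o (=0) * logsig(0)=0.5 + b_o (=0)

    def test_single_unit_hand_case(self):
        # hidden pre-activation 0 -> a = 0.5; y = 2*0.5 + 1 = 2
        m = _model()
        m.unpack(np.zeros(m.n_params))
        m.w_o[0, :] = 0.0
        m.w_o[0, 0] = 2.0
        m.b_o[0] = 1.0
        assert np.isclose(forward(m, np.zeros(12))[0], 2.0)

    def test_matches_bruteforce_oracle(self, rng):
        # independent re-implementation with plain Python loops
        for _ in range(5):
            m = _model(rng)
            x = rng.normal(size=12)
            a = [1.0 / (1.0 + math.exp(-(sum(m.w_h[j, i] * x[i] for i in range(12))
                                         + m.b_h[j]))) for j in range(10)]
            y_expected = [sum(m.w_o[k, j] * a[j] for j in range(10)) + m.b_o[k]
                          for k in range(3)]
            assert np.allclose(forward(m, x), y_expected, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            forward(_model(), np.ones(7))


class TestCost:
    def test_zero_model_zero_targets(self):
        m = _model()
        m.unpack(np.zeros(m.n_params))
        E, E_D, E_w = cost(m, TrainingSet(X=np.zeros((4, 12)), T=np.zeros((4, 3))))
        assert E == E_D == E_w == 0.0

    def test_single_unit_arithmetic(self):
        m = _model()
        m.unpack(np.zeros(m.n_params))
        m.alpha, m.beta = 1.0, 1.0
        E, E_D, E_w = cost(m, TrainingSet(X=np.zeros((1, 12)),
                                          T=np.array([[0.0, 1.0, 0.0]])))
        assert E_D == 1.0 and E_w == 0.0 and E == 1.0

    def test_matches_bruteforce_summation(self, rng):
        m = _model(rng)
        X = rng.normal(size=(20, 12))
        codes = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0, 0, 0)]
        T = np.array([codes[i % 4] for i in range(20)], float)
        E, E_D, E_w = cost(m, TrainingSet(X=X, T=T))
        Y = forward(m, (X - m.input_mean) / m.input_scale)
        ed = sum((T[i, k] - Y[i, k]) ** 2 for i in range(20) for k in range(3))
        ew = sum(float(w ** 2) for arr in (m.w_h, m.b_h, m.w_o, m.b_o)
                 for w in np.ravel(arr))
        assert np.isclose(E_D, ed, atol=1e-10)
        assert np.isclose(E_w, ew, atol=1e-10)
        assert np.isclose(E, m.alpha * ed + m.beta * ew, atol=1e-10)


def _toy_two_class(n=20, seed=5):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-2, 0.3, size=(n // 2, 12)),
                   rng.normal(2, 0.3, size=(n // 2, 12))])
    T = np.vstack([np.tile([1.0, 0, 0], (n // 2, 1)),
                   np.tile([0, 1.0, 0], (n // 2, 1))])
    return TrainingSet(X=X, T=T)


class TestTrain:
    def test_separable_toy_classified(self):
        data = _toy_two_class()
        model, _ = train(data, TrainConfig(max_epochs=50, seed=2))
        Y = forward(model, (data.X - model.input_mean) / model.input_scale)
        assert np.all((Y[:10, 0] > 0.5) & (Y[:10, 1] < 0.5))
        assert np.all((Y[10:, 1] > 0.5) & (Y[10:, 0] < 0.5))

    def test_cost_never_increases_on_accepted_steps(self):
        _, record = train(_toy_two_class(), TrainConfig(max_epochs=40, seed=3))
        for entry in record["trace"]:
            assert entry["E_after"] < entry["E_before"]

    def test_beta_dominated_limit_shrinks_weights(self):
        data = _toy_two_class()
        free, _ = train(data, TrainConfig(max_epochs=40, seed=4,
                                          alpha_init=1.0, beta_init=1e-8,
                                          reestimate_every=10_000))
        shrunk, _ = train(data, TrainConfig(max_epochs=40, seed=4,
                                            alpha_init=1.0, beta_init=1e6,
                                            reestimate_every=10_000))
        w_free = float(free.pack() @ free.pack())
        w_shrunk = float(shrunk.pack() @ shrunk.pack())
        assert w_shrunk < 1e-4 * w_free

    def test_determinism_bit_identical(self):
        data = _toy_two_class()
        cfg = TrainConfig(max_epochs=30, seed=7)
        m1, _ = train(data, cfg)
        m2, _ = train(data, cfg)
        assert np.array_equal(m1.pack(), m2.pack())
        assert m1.alpha == m2.alpha and m1.beta == m2.beta

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 12))
        T = np.tile([1.0, 0, 0], (20, 1))
        with pytest.raises(ValueError):
            train(TrainingSet(X=X, T=T))

    def test_too_few_samples_rejected(self):
        X = np.zeros((5, 12))
        T = np.tile([1.0, 0, 0], (5, 1))
        T[0] = (0, 1, 0)
        with pytest.raises(ValueError):
            train(TrainingSet(X=X, T=T))


class TestPredictStream:
    def test_constant_signals_constant_output(self):
        m = _model()
        sig = ProcessedSignals(v_z=np.full(30, 0.2), theta=np.full(30, 3.0))
        Y = predict_stream(m, sig)
        assert Y.shape == (30, 3)
        assert np.allclose(Y, Y[0])  # constant everywhere incl. padding region

    def test_equals_per_sample_forward(self, rng):
        m = _model(rng)
        v, th = rng.normal(size=25), rng.normal(size=25)
        sig = ProcessedSignals(v_z=v, theta=th)
        Y = predict_stream(m, sig)
        for t in [0, 1, 6, 24]:
            lo = max(0, t - N_DELAYS + 1)
            x, _ = build_input_vector(v[lo:t + 1], th[lo:t + 1], m)
            assert np.allclose(Y[t], forward(m, x), atol=1e-12)
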