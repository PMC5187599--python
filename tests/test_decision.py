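"""Decision layer: output filtering, Gaussian risk thresholds,
binarization and mode mapping."""

import numpy as np
import pytest
from scipy.stats import norm

import gaitmode as gm
from gaitmode.decision import (InvalidTrainingDataError, ModeLabel,
                               binarize, filter_stream, fit_class_gaussians,
                               fit_decision_model, map_mode, map_mode_stream,
                               solve_threshold)


class TestFilterStream:
    def test_constant_input_fixed_point(self):
        y = np.full((100, 3), 2.5)
        assert np.allclose(filter_stream(y, 0.02, 200.0), 2.5)

    def test_step_response_closed_form(self):
        # unit step from rest: value at t = eps is 1 - 1/e
        fs, eps = 200.0, 0.02
        n = int(100 * eps * fs)
        y = np.ones((n, 1))
        y[0] = 0.0  # y̅[0] = y[0] = 0, step starts at the next sample
        out = filter_stream(y, eps, fs)
        k = int(round(eps * fs))
        assert abs(out[k, 0] - (1 - np.exp(-1))) < 1e-3 * 5  # discretization
        assert abs(out[-1, 0] - 1.0) < 1e-6

    def test_dc_gain(self):
        y = np.vstack([np.zeros((1, 2)), np.ones((5000, 2))])
        out = filter_stream(y, 0.02, 200.0)
        assert np.max(np.abs(out[-1] - 1.0)) < 1e-9

    def test_output_within_running_envelope(self, rng):
        y = rng.normal(size=(400, 3))
        out = filter_stream(y, 0.05, 200.0)
        run_min = np.minimum.accumulate(y, axis=0)
        run_max = np.maximum.accumulate(y, axis=0)
        assert np.all(out >= run_min - 1e-12) and np.all(out <= run_max + 1e-12)


class TestFitClassGaussians:
    def test_worked_example_with_floor(self):
        vals = np.array([0.0, 0.0, 0.2, -0.2, 1.0, 1.0])
        is2 = np.array([False, False, False, False, True, True])
        mu1, s1, mu2, s2 = fit_class_gaussians(vals, is2)
        assert mu1 == 0.0 and mu2 == 1.0
        assert np.isclose(s1, 0.1633, atol=5e-4)
        assert s2 == 1e-3  # identical samples -> floored SD

    def test_label_swap_symmetry(self, rng):
        vals = rng.normal(size=60)
        is2 = rng.random(60) > 0.5
        a = fit_class_gaussians(vals, is2)
        b = fit_class_gaussians(vals, ~is2)
        assert a[:2] == b[2:] and a[2:] == b[:2]

    def test_recovers_generating_parameters(self, rng):
        n = 20000
        z1 = rng.normal(0.1, 0.2, n)
        z2 = rng.normal(0.9, 0.3, n)
        vals = np.concatenate([z1, z2])
        is2 = np.arange(2 * n) >= n
        mu1, s1, mu2, s2 = fit_class_gaussians(vals, is2)
        se_mu = 0.3 / np.sqrt(n)
        assert abs(mu1 - 0.1) < 3 * se_mu and abs(mu2 - 0.9) < 3 * se_mu
        assert abs(s1 - 0.2) < 0.01 and abs(s2 - 0.3) < 0.01

    def test_absent_class_rejected(self):
        with pytest.raises(InvalidTrainingDataError):
            fit_class_gaussians(np.ones(5), np.ones(5, bool))


def _risk(z, mu1, s1, mu2, s2, lam12, lam21):
    """Expected risk of threshold z (equal priors, constant factor dropped)."""
    return lam12 * (1 - norm.cdf(z, mu1, s1)) + lam21 * norm.cdf(z, mu2, s2)


class TestSolveThreshold:
    def test_symmetric_case_exact_midpoint(self):
        z, clean = solve_threshold(0.0, 0.1, 1.0, 0.1, lam12=1.0, lam21=1.0)
        assert clean and z == 0.5

    def test_conservative_loss_shifts_threshold(self):
        # sigma = 0.1, lam12 = 2 lam21: z = 0.5 + sigma^2 ln 2
        z, _ = solve_threshold(0.0, 0.1, 1.0, 0.1, lam12=1.0, lam21=0.5)
        assert np.isclose(z, 0.5 + 0.01 * np.log(2.0), atol=1e-12)
        assert np.isclose(z, 0.5069, atol=1e-4)

    @pytest.mark.parametrize("mu2", [0.3, 1.0, 4.0])
    def test_always_above_midpoint_for_conservative_loss(self, mu2):
        z, _ = solve_threshold(0.0, 0.2, mu2, 0.2, lam12=1.0, lam21=0.5)
        assert z > mu2 / 2

    def test_monotone_in_lam12(self):
        zs = [solve_threshold(0.0, 0.15, 1.0, 0.15, lam12=l12, lam21=0.5)[0]
              for l12 in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(zs) > 0)

    def test_agrees_with_dense_grid_risk_minimizer(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            mu1 = rng.uniform(-1, 0.2)
            mu2 = mu1 + rng.uniform(0.5, 2.0)
            s1, s2 = rng.uniform(0.05, 0.4, size=2)
            lam12, lam21 = rng.uniform(0.3, 2.0, size=2)
            z, clean = solve_threshold(mu1, s1, mu2, s2, lam12, lam21)
            grid = np.linspace(mu1 - s1, mu2 + s2, 4001)
            risks = _risk(grid, mu1, s1, mu2, s2, lam12, lam21)
            z_grid = grid[np.argmin(risks)]
            if clean:
                # position agreement, or (for widely separated classes whose
                # risk is flat near zero) agreement in achieved risk
                close = abs(z - z_grid) < 2 * (grid[1] - grid[0])
                risk_z = _risk(z, mu1, s1, mu2, s2, lam12, lam21)
                assert close or risk_z <= risks.min() + 1e-9 * (lam12 + lam21)

    def test_ordering_precondition(self):
        with pytest.raises(ValueError):
            solve_threshold(1.0, 0.1, 0.0, 0.1)


class TestBinarizeAndMap:
    def test_binarize_examples(self):
        thr = np.full(3, 0.5)
        assert binarize([0.9, 0.1, 0.1], thr).tolist() == [1, 0, 0]
        assert binarize([0.2, 0.2, 0.2], thr).tolist() == [0, 0, 0]
        assert binarize([0.5, 0.5, 0.5], thr).tolist() == [1, 1, 1]  # tie -> 1

    @pytest.mark.parametrize("code,label", [
        ((1, 0, 0), ModeLabel.Ascent),
        ((0, 1, 0), ModeLabel.Level),
        ((0, 0, 1), ModeLabel.Descent),
        ((0, 0, 0), ModeLabel.Undetermined),
        ((1, 1, 0), ModeLabel.Undetermined),
        ((1, 1, 1), ModeLabel.Undetermined),
    ])
    def test_map_mode(self, code, label):
        assert map_mode(np.array(code)) is label

    def test_roundtrip_on_defined_labels(self):
        for label in ModeLabel:
            assert map_mode(np.array(label.coding)) is label

    def test_stream_mapping_matches_scalar(self, rng):
        Y = (rng.random((50, 3)) > 0.5).astype(int)
        out = map_mode_stream(Y)
        assert all(out[i] == int(map_mode(Y[i])) for i in range(50))


class TestFitDecisionModel:
    def test_defaults_and_structure(self, trained_recognizer, stair_trial):
        rec, _ = trained_recognizer
        dec = rec.decision
        assert dec.lam12 == 1.0 and dec.lam21 == 0.5  # lam12 = 2*lam21
        assert dec.thresholds.shape == (3,)
        assert np.all(np.isfinite(dec.thresholds))
        for el in range(3):
            mu1, s1, mu2, s2 = dec.class_stats[el]
            assert mu1 < dec.thresholds[el] < mu2 + s2

    def test_missing_mode_rejected(self, trained_recognizer, stair_trial):
        rec, _ = trained_recognizer
        stream, truth = stair_trial
        sig = gm.process_stream(stream, rec.zupt)
        level_only = np.full(len(stream), int(ModeLabel.Level))
        with pytest.raises(InvalidTrainingDataError):
            fit_decision_model(rec.network, sig, level_only)

    def test_classify_level_trial_mostly_level(self, trained_recognizer):
        rec, _ = trained_recognizer
        # a trial consisting only of level walking, same subject
        from gaitmode.simulate import ScenarioConfig, generate_trial
        cfg = ScenarioConfig(scenario="stairs", seed=42)
        stream, truth = generate_trial(cfg, subject_id=1, trial_id=3)
        sig = gm.process_stream(stream, rec.zupt)
        pred = gm.classify_stream(rec.network, rec.decision, sig, stream.fs)
        assert pred.shape == (len(stream),)
        level_swing = (truth.mode == int(ModeLabel.Level)) & ~truth.stance
        frac = np.mean(pred[level_swing] == int(ModeLabel.Level))
        assert frac >= 0.95
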