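"""Frequency binning, model fitting, AICc selection and lack-of-fit tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtr

from reprotraj import simulate
from reprotraj.activation import (ActivationCurveModel, ActivationFit,
                                  FrequencyCurve, activation_window, aicc,
                                  bin_frequencies, bootstrap_ftest,
                                  lack_of_fit_ftest, select_model)


def curve_from_values(x, y, counts=50, n_eff=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    counts = np.full(len(x), counts)
    return FrequencyCurve(gene="toy", bin_centers=x, bin_counts=counts,
                          freqs=y, bin_width=x[1] - x[0] if len(x) > 1 else 1.0,
                          n_eff=n_eff if n_eff is not None else float(len(x)))


def sigmoid(x, base, amp, mu, sigma):
    return base + amp * ndtr((np.asarray(x) - mu) / sigma)


class TestBinFrequencies:
    def test_all_detected_gives_unit_freqs(self):
        c = bin_frequencies(np.ones(100), np.linspace(0, 1, 100))
        assert np.allclose(c.y, 1.0)

    def test_full_width_bins_equal_global_fraction(self, rng):
        det = rng.integers(0, 2, 200)
        c = bin_frequencies(det, rng.random(200), bin_width=2.0, n_bins=5)
        assert np.allclose(c.y, det.mean())

    def test_no_cells_rejected(self):
        with pytest.raises(ValueError):
            bin_frequencies(np.empty(0), np.empty(0))

    def test_unclamped_progression_rejected(self):
        with pytest.raises(ValueError):
            bin_frequencies(np.ones(3), np.array([0.0, 0.5, 1.2]))

    def test_binned_freqs_track_true_curve(self, rng):
        g = simulate.GeneSimParams("G", "pluripotency", 0.1, 0.9, 0.5, 0.1)
        p = rng.uniform(0, 1, 1000)
        det = rng.random(1000) < simulate.true_frequency(g, p)
        c = bin_frequencies(det, p)
        truth = simulate.true_frequency(g, c.x)
        assert np.max(np.abs(c.y - truth)) <= 0.06 + 0.05  # bin-window smear


class TestUniformFit:
    def test_perfect_line_zero_mse(self):
        x = np.linspace(0, 1, 20)
        fit = ActivationCurveModel(curve_from_values(x, x)).fit_uniform()
        assert fit.mse == pytest.approx(0.0, abs=1e-20)
        assert fit.baseline == pytest.approx(0.0, abs=1e-12)
        assert fit.endpoint == pytest.approx(1.0, abs=1e-12)

    def test_constant_curve(self):
        x = np.linspace(0, 1, 20)
        fit = ActivationCurveModel(curve_from_values(x, np.full(20, 0.4))
                                   ).fit_uniform()
        assert fit.baseline == fit.endpoint == pytest.approx(0.4)
        assert fit.mse == pytest.approx(0.0, abs=1e-20)

    def test_step_curve_mse_by_direct_arithmetic(self):
        x = np.linspace(0, 1, 20)
        y = (x > 0.5).astype(float)
        fit = ActivationCurveModel(curve_from_values(x, y)).fit_uniform()
        # oracle: anchors pooled over bins within 0.15 of the ends (all 0
        # resp. all 1 here), prediction = x, residual = step - line
        expected = sum((yi - xi) ** 2 for xi, yi in zip(x, y)) / len(x)
        assert fit.mse == pytest.approx(expected)

    def test_far_anchor_warns(self):
        x = np.array([0.4, 0.5, 0.6])
        with pytest.warns(UserWarning, match="anchor"):
            ActivationCurveModel(curve_from_values(x, x)).fit_uniform()


class TestGaussianFit:
    def test_noise_free_parameter_recovery(self):
        x = np.linspace(0, 1, 25)
        y = sigmoid(x, 0.1, 0.8, 0.5, 0.1)
        fit = ActivationCurveModel(curve_from_values(x, y)).fit_gaussian(1)
        amp, mu, sig = fit.components[0]
        assert mu == pytest.approx(0.5, abs=0.02)
        assert fit.mse < 1e-4

    def test_constant_curve_fits_flat(self):
        x = np.linspace(0, 1, 25)
        fit = ActivationCurveModel(curve_from_values(x, np.full(25, 0.3))
                                   ).fit_gaussian(1)
        assert fit.mse < 1e-6
        assert np.ptp(fit.predict(np.linspace(0, 1, 50))) < 0.02

    def test_transient_pulse_needs_two_components(self):
        x = np.linspace(0, 1, 25)
        y = sigmoid(x, 0.05, 0.8, 0.3, 0.06) + sigmoid(x, 0, -0.8, 0.7, 0.06)
        m = ActivationCurveModel(curve_from_values(x, y))
        fits = m.fit_all()
        assert fits["gauss2"].mse < fits["gauss1"].mse
        assert fits["gauss2"].mse < 1e-4

    def test_nesting_of_model_classes(self, rng):
        # gauss2 never fits worse than gauss1, which never fits worse than
        # the best constant (its zero-amplitude limit), up to tolerance
        x = np.linspace(0, 1, 25)
        for _ in range(3):
            y = np.clip(rng.random(25), 0, 1)
            fits = ActivationCurveModel(curve_from_values(x, y)).fit_all()
            const_mse = np.mean((y - y.mean()) ** 2)
            assert fits["gauss2"].mse <= fits["gauss1"].mse + 1e-9
            assert fits["gauss1"].mse <= const_mse + 1e-6

    def test_prediction_respects_unit_interval(self):
        x = np.linspace(0, 1, 25)
        y = np.clip(sigmoid(x, 0.0, 1.0, 0.5, 0.03), 0, 1)
        fit = ActivationCurveModel(curve_from_values(x, y)).fit_gaussian(1)
        pred = fit.predict(np.linspace(0, 1, 200))
        assert pred.min() > -0.02 and pred.max() < 1.02

    def test_large_sigma_limit_is_a_straight_line(self):
        fit = ActivationFit(gene="g", kind="gauss1", baseline=0.1,
                            components=[(0.8, 0.5, 10.0)], endpoint=None,
                            mse=0.0, k=4, n_eff=12.5)
        x = np.linspace(0, 1, 101)
        pred = fit.predict(x)
        chord = pred[0] + (pred[-1] - pred[0]) * x
        assert np.max(np.abs(pred - chord)) < 0.01

    def test_invalid_component_count(self):
        x = np.linspace(0, 1, 25)
        with pytest.raises(ValueError):
            ActivationCurveModel(curve_from_values(x, x)).fit_gaussian(3)


class TestAICc:
    def test_direct_formula_value(self):
        # 30 ln(0.01) + 2*2 + 2*2*3/27, computed by hand
        assert aicc(30, 2, 0.01) == pytest.approx(
            30 * math.log(0.01) + 4 + 12 / 27)
        assert aicc(30, 2, 0.01) == pytest.approx(-133.7106, abs=1e-3)

    @given(st.integers(2, 6), st.floats(1e-6, 1.0), st.integers(10, 200))
    def test_penalty_monotone_in_k(self, k, mse, n):
        if n > k + 2:
            assert aicc(n, k + 1, mse) > aicc(n, k, mse)

    def test_halving_mse_drops_score_by_n_ln2(self):
        drop = aicc(40, 3, 0.02) - aicc(40, 3, 0.01)
        assert drop == pytest.approx(40 * math.log(2))

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            aicc(5, 4, 0.1)
        with pytest.raises(ValueError):
            aicc(30, 2, 0.0)


class TestModelSelection:
    def fit_gene(self, g, rng, n=1000):
        p = rng.uniform(0, 1, n)
        det = rng.random(n) < simulate.true_frequency(g, p)
        curve = bin_frequencies(det, p, gene=g.name)
        return ActivationCurveModel(curve).fit_all()

    def test_sigmoidal_gene_selects_gauss1(self, rng):
        g = simulate.GeneSimParams("S", "pluripotency", 0.1, 0.9, 0.5, 0.1)
        chosen, _ = select_model(self.fit_gene(g, rng))
        assert chosen == "gauss1"

    def test_linear_gene_retains_uniform(self, rng):
        # truly linear detection frequency f(p) = 0.1 + 0.8 p; retention is
        # a statistical property (the anchored line carries estimation
        # noise), so check the median over replicate draws
        deltas = []
        for _ in range(5):
            p = rng.uniform(0, 1, 1000)
            det = rng.random(1000) < 0.1 + 0.8 * p
            fits = ActivationCurveModel(
                bin_frequencies(det, p, gene="L")).fit_all()
            deltas.append(select_model(fits)[1]["uniform"])
        assert np.median(deltas) <= 2.0

    def test_transient_gene_selects_gauss2(self, rng):
        g = simulate.GeneSimParams("T", "intermediate", 0.05, 0.85, 0.3, 0.07,
                                   amp2=-0.75, mu2=0.7, sigma2=0.07)
        chosen, _ = select_model(self.fit_gene(g, rng))
        assert chosen == "gauss2"


class TestActivationWindow:
    def test_normal_quantile_intervals(self):
        fit = ActivationFit(gene="g", kind="gauss1", baseline=0.1,
                            components=[(0.8, 0.5, 0.1)], endpoint=None,
                            mse=0.0, k=4, n_eff=12.5)
        mu, (l50, h50), (l95, h95) = activation_window(fit)
        assert mu == 0.5
        assert (l95, h95) == (pytest.approx(0.304, abs=1e-3),
                              pytest.approx(0.696, abs=1e-3))
        assert (l50, h50) == (pytest.approx(0.4326, abs=1e-3),
                              pytest.approx(0.5674, abs=1e-3))

    def test_zero_spread_collapses_and_no_clamping(self):
        fit = ActivationFit(gene="g", kind="gauss1", baseline=0.0,
                            components=[(1.0, 0.0, 1e-9)], endpoint=None,
                            mse=0.0, k=4, n_eff=12.5)
        mu, i50, i95 = activation_window(fit)
        assert i95[0] == pytest.approx(0.0, abs=1e-6)
        assert i95[0] < 0  # raw value below the trajectory bound is kept

    def test_uniform_model_rejected(self):
        fit = ActivationFit(gene="g", kind="uniform", baseline=0.1,
                            components=[], endpoint=0.9, mse=0.0, k=2,
                            n_eff=12.5)
        with pytest.raises(ValueError):
            activation_window(fit)


class TestLackOfFit:
    def make_fit_and_data(self, rng, n=1000):
        g = simulate.GeneSimParams("S", "pluripotency", 0.1, 0.9, 0.5, 0.1)
        p = rng.uniform(0, 1, n)
        det = rng.random(n) < simulate.true_frequency(g, p)
        fit = ActivationCurveModel(bin_frequencies(det, p, gene="S")
                                   ).fit_gaussian(1)
        return fit

    def test_single_shot_test_calibrated_under_null(self, rng):
        fit = self.make_fit_and_data(rng)
        rej = 0
        reps = 500
        for _ in range(reps):
            p = rng.uniform(0, 1, 1000)
            det = rng.random(1000) < np.clip(fit.predict(p), 0, 1)
            rej += lack_of_fit_ftest(fit, det, p)[2]
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) <= 3 * se

    def test_step_gene_rejects_uniform_model(self, rng):
        p = rng.uniform(0, 1, 500)
        det = p > 0.5
        uni = ActivationCurveModel(bin_frequencies(det, p, gene="st")
                                   ).fit_uniform()
        assert lack_of_fit_ftest(uni, det, p)[2]
        assert bootstrap_ftest(uni, det, p, reps=200, seed=1) > 0.95

    def test_perfect_model_with_zero_noise_never_rejects(self):
        # all cells detected, model predicts exactly 1 everywhere
        fit = ActivationFit(gene="g", kind="uniform", baseline=1.0,
                            components=[], endpoint=1.0, mse=0.0, k=2,
                            n_eff=12.5)
        p = np.linspace(0, 1, 200)
        rate = bootstrap_ftest(fit, np.ones(200), p, reps=100, seed=0)
        assert rate == 0.0

    def test_bad_arguments(self, rng):
        fit = self.make_fit_and_data(rng, n=200)
        with pytest.raises(ValueError):
            bootstrap_ftest(fit, np.ones(10), np.linspace(0, 1, 10), reps=0)
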