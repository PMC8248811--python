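"""Gompertz growth-curve fitting and 4D atlas evaluation."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from mcatlas.errors import InsufficientDataError
from mcatlas.images import DisplacementField
from mcatlas import temporal

CENTERS = np.arange(37.0, 44.01, 0.5)


class TestGompertzFunction:
    def test_value_at_peak_time(self):
        alpha, delta = 2.0, 0.5
        val = temporal.gompertz(41.0, alpha, delta, 1.3, 41.0)
        assert np.isclose(val, (alpha - delta) / np.e + delta)

    def test_asymptotes(self):
        assert np.isclose(temporal.gompertz(-1e4, 2.0, 0.5, 1.0, 40.0), 2.0)
        assert np.isclose(temporal.gompertz(1e4, 2.0, 0.5, 1.0, 40.0), 0.5)

    def test_equal_asymptotes_are_constant(self):
        t = np.linspace(30, 50, 41)
        assert np.allclose(temporal.gompertz(t, 0.7, 0.7, 2.0, 40.0), 0.7)

    def test_monotone_between_asymptotes(self):
        t = np.linspace(34, 47, 400)
        rising = temporal.gompertz(t, 0.2, 0.9, 1.1, 40.0)  # alpha < delta
        assert np.all(np.diff(rising) >= 0) and rising[-1] > rising[0]
        falling = temporal.gompertz(t, 0.9, 0.2, 1.1, 40.0)
        assert np.all(np.diff(falling) <= 0) and falling[-1] < falling[0]


class TestFitRecovery:
    def test_noiseless_parameters_recovered(self, rng):
        v = 400
        alpha = rng.uniform(0.2, 0.6, v)
        delta = alpha + rng.uniform(0.2, 0.5, v) * rng.choice([-1, 1], v)
        gamma = rng.uniform(0.5, 2.0, v)
        tau = rng.uniform(38.5, 42.5, v)
        series = temporal.gompertz(CENTERS[:, None], alpha, delta, gamma, tau)
        fit = temporal.fit_gompertz_series(CENTERS, series)
        for truth, est in [(alpha, fit.alpha), (delta, fit.delta), (gamma, fit.gamma), (tau, fit.tau)]:
            assert np.max(np.abs(est - truth) / np.maximum(np.abs(truth), 1e-9)) < 1e-3

    def test_constant_series_degenerate_rule(self):
        fit = temporal.fit_gompertz_series(CENTERS, np.full((15, 4), 3.25))
        assert np.allclose(fit.alpha, 3.25) and np.allclose(fit.delta, 3.25)
        assert np.all(fit.r_squared == 0)  # zero-variance convention

    def test_matches_scipy_least_squares_per_voxel(self, rng):
        """Dual-route check: the batched fitter against scipy on single
        noisy series."""
        alpha, delta, gamma, tau = 0.3, 0.8, 1.2, 40.4
        clean = temporal.gompertz(CENTERS, alpha, delta, gamma, tau)
        noisy = clean + 0.02 * (delta - alpha) * rng.standard_normal(15)
        fit = temporal.fit_gompertz_series(CENTERS, noisy[:, None])

        def resid(p):
            return temporal.gompertz(CENTERS, *p) - noisy

        ref = least_squares(
            resid, [clean[0], clean[-1], 1.0, 40.5],
            bounds=([-np.inf, -np.inf, -5, 33], [np.inf, np.inf, 5, 48]),
        )
        assert (resid(np.array([fit.alpha[0], fit.delta[0], fit.gamma[0], fit.tau[0]])) ** 2).sum() <= (
            ref.cost * 2 + 1e-12
        )
        assert abs(fit.tau[0] - ref.x[3]) < 0.05
        assert abs(fit.gamma[0] - ref.x[2]) < 0.05

    def test_time_recentering_invariance(self, rng):
        v = 50
        alpha = rng.uniform(0.2, 0.6, v)
        delta = alpha + 0.4
        gamma = rng.uniform(0.6, 1.5, v)
        tau = rng.uniform(39.0, 42.0, v)
        series = temporal.gompertz(CENTERS[:, None], alpha, delta, gamma, tau)
        base = temporal.fit_gompertz_series(CENTERS, series)
        shifted = temporal.fit_gompertz_series(CENTERS + 5.0, series)
        assert np.abs(shifted.tau - base.tau - 5.0).max() < 1e-6
        assert np.abs(shifted.gamma - base.gamma).max() < 1e-6
        assert np.abs(shifted.alpha - base.alpha).max() < 1e-6
        assert np.abs(shifted.r_squared - base.r_squared).max() < 1e-6

    def test_median_r2_gompertz_beats_linear_on_gompertz_data(self, rng):
        v = 500
        alpha = rng.uniform(0.2, 0.6, v)
        delta = alpha + rng.uniform(0.2, 0.4, v) * rng.choice([-1, 1], v)
        gamma = rng.uniform(0.6, 1.5, v)
        tau = rng.uniform(39.5, 41.5, v)
        clean = temporal.gompertz(CENTERS[:, None], alpha, delta, gamma, tau)
        noisy = clean + 0.05 * np.abs(alpha - delta) * rng.standard_normal(clean.shape)
        fit = temporal.fit_gompertz_series(CENTERS, noisy)
        assert np.median(fit.r_squared) >= np.median(fit.linear_r_squared)

    def test_too_few_windows_rejected(self):
        with pytest.raises(InsufficientDataError):
            temporal.fit_gompertz_series(np.array([37.0, 38, 39, 40.0]), np.zeros((4, 2)))


class TestWarpAndAffineFits:
    def test_constant_warps_reproduced(self):
        vecs = np.zeros((6, 6, 6, 3))
        vecs[..., 0] = 1.4
        warps = [DisplacementField(vecs.copy()) for _ in range(15)]
        fit = temporal.fit_gompertz_warps(CENTERS, warps)
        for t in (37.0, 40.3, 44.0):
            assert np.abs(fit.evaluate(t) - vecs).max() < 1e-6

    def test_gompertz_growing_warps_recovered(self):
        amp = temporal.gompertz(CENTERS, 0.2, 1.8, 0.9, 40.5)
        base = np.zeros((5, 5, 5, 3))
        base[..., 1] = 1.0
        warps = [DisplacementField(base * a) for a in amp]
        fit = temporal.fit_gompertz_warps(CENTERS, warps)
        assert np.abs(fit.alpha[..., 1] - 0.2).max() < 1e-3
        assert np.abs(fit.gamma[..., 1] - 0.9).max() < 1e-3

    def test_affine_entries_fitted_within_range_rmse(self):
        scales = 1.0 + 0.15 / (1.0 + np.exp(-(CENTERS - 40.5) * 0.8))  # logistic-like
        mats = [np.diag([s, 1.0, 1 / s]) for s in scales]
        fit = temporal.fit_gompertz_affines(CENTERS, mats)
        recon = np.stack([fit.evaluate(t) for t in CENTERS])
        rmse = np.sqrt(((recon[:, 0, 0] - scales) ** 2).mean())
        assert rmse < 0.01 * np.ptp(scales)


class TestAtlasEvaluation:
    def _atlas(self, rng):
        shape = (4, 4, 4)
        series = {
            "chan": np.stack(
                [temporal.gompertz(c, 0.2, 0.9, 1.0, 40.5) * np.ones(shape) for c in CENTERS]
            )
        }
        params = temporal.fit_gompertz_series(CENTERS, series["chan"])
        return temporal.Atlas4D(
            {"chan": params}, {"chan": ("scalar", 0)}, None, None, shape, np.eye(4),
            (37.0, 44.0),
        )

    def test_out_of_range_rejected(self, rng):
        atlas = self._atlas(rng)
        with pytest.raises(ValueError):
            temporal.evaluate_atlas(atlas, 45.0)

    def test_window_center_matches_curve(self, rng):
        atlas = self._atlas(rng)
        maps, jac = temporal.evaluate_atlas(atlas, 40.5)
        assert jac is None
        expected = temporal.gompertz(40.5, 0.2, 0.9, 1.0, 40.5)
        assert np.abs(maps["chan"].values - expected).max() < 1e-6

    def test_midpoint_within_monotone_envelope(self, rng):
        atlas = self._atlas(rng)
        lo = temporal.evaluate_atlas(atlas, 40.0)[0]["chan"].values
        hi = temporal.evaluate_atlas(atlas, 40.5)[0]["chan"].values
        mid = temporal.evaluate_atlas(atlas, 40.25)[0]["chan"].values
        assert np.all(mid >= np.minimum(lo, hi) - 1e-12)
        assert np.all(mid <= np.maximum(lo, hi) + 1e-12)


class TestGrowthPeakOffset:
    def test_uniform_tau_at_reference_gives_empty(self):
        series = temporal.gompertz(CENTERS, 0.2, 0.9, 1.0, 40.5)[:, None, None, None] * np.ones((15, 2, 2, 2))
        params = temporal.fit_gompertz_series(CENTERS, series)
        mask = temporal.growth_peak_offset_map(params)
        assert mask.values.sum() == 0

    def test_offset_tau_gives_full(self):
        series = temporal.gompertz(CENTERS, 0.2, 0.9, 1.0, 40.8)[:, None, None, None] * np.ones((15, 2, 2, 2))
        params = temporal.fit_gompertz_series(CENTERS, series)
        mask = temporal.growth_peak_offset_map(params)
        assert mask.values.sum() == 8

    def test_mixed_field_matches_threshold_oracle(self, rng):
        tau = rng.uniform(39.5, 41.5, (5, 5, 8))
        series = temporal.gompertz(
            CENTERS[:, None, None, None], 0.2, 0.9, 1.0, tau[None]
        )
        params = temporal.fit_gompertz_series(CENTERS, series)
        mask = temporal.growth_peak_offset_map(params)
        oracle = (np.abs(params.tau - 40.5) >= 0.2).astype(float)
        assert np.array_equal(mask.values, oracle)
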