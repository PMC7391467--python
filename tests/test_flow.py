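"""Horizontal finite differences, Laplace-Beltrami operator and the flow."""

import math
import warnings

import numpy as np
import pytest

from gaborlift.bank import BankSpec, build_bank
from gaborlift.flow import (
    FlowConfig,
    FlowDiagnostics,
    FlowState,
    compute_metric,
    enhance,
    evolve_channel,
    horizontal_derivatives,
    laplace_beltrami,
    max_timestep,
    step,
    sub_riemannian_laplacian,
)
from gaborlift.transform import lift, reconstruct


def thetas_for(K):
    return 2.0 * np.pi * np.arange(K) / K


# ---------------------------------------------------------------------------
# independent dense oracle: pure-numpy assembly of the divergence form on a
# K=4 grid, where the spatial offsets (cos t, sin t) are integer so no
# interpolation library is involved at all
# ---------------------------------------------------------------------------


def _roll_shift(u, ex, ey, sign):
    """u(q + sign*(ex, ey)) on a periodic grid with integer offsets."""
    return np.roll(np.roll(u, -sign * ey, axis=0), -sign * ex, axis=1)


def dense_laplace_beltrami_oracle(u, c1, c2):
    """Naive loop assembly of the metric Laplacian on an (H, W, 4) grid.

    Builds the full 2x2 metric per point, inverts it with np.linalg.inv,
    and applies the same stencil definitions (staggered diagonal fluxes,
    central cross fluxes) with plain rolls.
    """
    H, W, K = u.shape
    assert K == 4
    dth = 2.0 * np.pi / K
    offsets = [(1, 0), (0, 1), (-1, 0), (0, -1)]  # (cos t, sin t) for t = 0, 90, 180, 270
    sc1, sc2 = math.sqrt(c1), math.sqrt(c2)

    plus = np.empty_like(u)
    minus = np.empty_like(u)
    for k, (ex, ey) in enumerate(offsets):
        plus[:, :, k] = _roll_shift(u[:, :, k], ex, ey, +1)
        minus[:, :, k] = _roll_shift(u[:, :, k], ex, ey, -1)
    up = np.roll(u, -1, axis=2)
    um = np.roll(u, 1, axis=2)
    w1 = sc1 * 0.5 * (plus - minus)
    w2 = sc2 * (up - um) / (2.0 * dth)

    sq = np.empty((H, W, K))
    a = np.empty((H, W, K, 2, 2))
    for i in range(H):
        for j in range(W):
            for k in range(K):
                wv = np.array([w1[i, j, k], w2[i, j, k]])
                g = np.eye(2) + np.outer(wv, wv)
                det = np.linalg.det(g)
                sq[i, j, k] = math.sqrt(det)
                a[i, j, k] = math.sqrt(det) * np.linalg.inv(g)

    out = np.empty_like(u)
    a11 = a[:, :, :, 0, 0]
    a12 = a[:, :, :, 0, 1]
    a22 = a[:, :, :, 1, 1]
    g1 = a12 * w2
    g2 = a12 * w1
    for k, (ex, ey) in enumerate(offsets):
        a11p = _roll_shift(a11[:, :, k], ex, ey, +1)
        a11m = _roll_shift(a11[:, :, k], ex, ey, -1)
        t1 = c1 * (
            0.5 * (a11p + a11[:, :, k]) * (plus[:, :, k] - u[:, :, k])
            - 0.5 * (a11[:, :, k] + a11m) * (u[:, :, k] - minus[:, :, k])
        )
        a22p = a22[:, :, (k + 1) % K]
        a22m = a22[:, :, (k - 1) % K]
        t2 = (c2 / dth**2) * (
            0.5 * (a22p + a22[:, :, k]) * (up[:, :, k] - u[:, :, k])
            - 0.5 * (a22[:, :, k] + a22m) * (u[:, :, k] - um[:, :, k])
        )
        cr1 = sc1 * 0.5 * (
            _roll_shift(g1[:, :, k], ex, ey, +1) - _roll_shift(g1[:, :, k], ex, ey, -1)
        )
        cr2 = sc2 * (g2[:, :, (k + 1) % K] - g2[:, :, (k - 1) % K]) / (2.0 * dth)
        out[:, :, k] = (t1 + t2 + cr1 + cr2) / sq[:, :, k]
    return out


class TestHorizontalDerivatives:
    def test_constant_field_has_zero_derivatives(self):
        u = np.full((12, 12, 8), 2.3)
        d = horizontal_derivatives(u, thetas_for(8))
        for f in (d.x1, d.x2, d.x1x1, d.x2x2):
            np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_x1_of_affine_field_is_cos_theta(self):
        """Linear interpolation is exact on affine fields: X1(x) = cos theta."""
        K = 8
        y, x = np.mgrid[0:16, 0:16].astype(float)
        u = np.repeat(x[:, :, None], K, axis=2)
        d = horizontal_derivatives(u, thetas_for(K), interpolation=1)
        interior = d.x1[4:-4, 4:-4, :]
        np.testing.assert_allclose(
            interior, np.broadcast_to(np.cos(thetas_for(K)), interior.shape), atol=1e-13
        )

    def test_x2x2_second_order_convergence(self):
        """X2X2 of sin(theta) converges to -sin(theta) at rate O(dtheta^2)."""
        errs = []
        for K in (8, 16):
            th = thetas_for(K)
            u = np.broadcast_to(np.sin(th), (6, 6, K)).copy()
            d = horizontal_derivatives(u, th)
            errs.append(np.max(np.abs(d.x2x2 - (-np.sin(th)))))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.1)

    def test_too_few_orientations_rejected(self):
        with pytest.raises(ValueError):
            horizontal_derivatives(np.zeros((8, 8, 2)), thetas_for(2))

    def test_unsupported_interpolation_rejected(self):
        with pytest.raises(ValueError):
            horizontal_derivatives(np.zeros((8, 8, 4)), thetas_for(4), interpolation=2)


class TestSubRiemannianLaplacian:
    def test_constant_is_in_kernel(self):
        u = np.full((10, 10, 8), 1.7)
        np.testing.assert_allclose(
            sub_riemannian_laplacian(u, thetas_for(8), 1.0, 0.25), 0.0, atol=1e-10
        )

    def test_quadratic_field(self):
        """X1X1 of x^2 equals 2 cos^2(theta) up to interpolation error."""
        K = 8
        y, x = np.mgrid[0:20, 0:20].astype(float)
        u = np.repeat((x**2)[:, :, None], K, axis=2)
        lap = sub_riemannian_laplacian(u, thetas_for(K), 1.0, 0.0, interpolation=3)
        interior = lap[6:-6, 6:-6, :]
        expected = 2.0 * np.cos(thetas_for(K)) ** 2
        np.testing.assert_allclose(
            interior, np.broadcast_to(expected, interior.shape), atol=5e-2
        )


class TestLaplaceBeltrami:
    def test_constant_fixed_point(self):
        u = np.full((10, 10, 8), 0.4)
        np.testing.assert_allclose(
            laplace_beltrami(u, thetas_for(8), 1.0, 0.0625), 0.0, atol=1e-10
        )

    def test_small_amplitude_limit_is_weighted_laplacian(self, rng):
        """L(eps u)/eps -> c1 X1X1 u + c2 X2X2 u as the metric flattens."""
        from scipy import ndimage

        base = ndimage.gaussian_filter(rng.standard_normal((16, 16, 8)), 2.0)
        th = thetas_for(8)
        c1, c2 = 1.0, 0.37
        eps = 1e-6
        lb = laplace_beltrami(eps * base, th, c1, c2, boundary="periodic") / eps
        d0 = sub_riemannian_laplacian(base, th, c1, c2, boundary="periodic")
        assert np.max(np.abs(lb - d0)) / np.max(np.abs(d0)) < 1e-4

    def test_matches_dense_oracle(self, rng):
        """Production operator equals the naive dense assembly on an 8x8x4 grid."""
        u = rng.standard_normal((8, 8, 4))
        got = laplace_beltrami(
            u, thetas_for(4), 1.0, 0.0625, interpolation=1, boundary="periodic"
        )
        expected = dense_laplace_beltrami_oracle(u, 1.0, 0.0625)
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestStep:
    def test_zero_operator_leaves_field_unchanged(self):
        u = np.full((8, 8, 4), 0.9)
        state = FlowState(u.copy(), thetas_for(4))
        new = step(state, FlowConfig(dt=0.1, iterations=1), 1.0, 0.0625)
        np.testing.assert_allclose(new.values, u, atol=1e-13)
        assert new.iteration == 1

    def test_divergence_raises_with_iteration(self, rng):
        state = FlowState(rng.standard_normal((8, 8, 4)), thetas_for(4), iteration=7)
        state.values[0, 0, 0] = np.inf
        from gaborlift.flow import FlowDivergenceError

        with pytest.raises(FlowDivergenceError, match="iteration 7"):
            step(state, FlowConfig(dt=0.1, iterations=1), 1.0, 0.0625)

    def test_max_norm_nonincreasing_with_frozen_identity_metric(self, rng):
        """With identity metric, linear interpolation and dt in the convex
        regime, the update is an averaging: max|u| never increases."""
        K = 16
        th = thetas_for(K)
        u = rng.standard_normal((16, 16, K))
        cfg = FlowConfig(dt=0.1, iterations=1, interpolation=1, boundary="periodic")
        c1, c2 = 1.0, 0.0625
        identity = compute_metric(
            np.zeros_like(u), np.zeros_like(u), c1, c2, th, 1, "periodic"
        )
        state = FlowState(u, th)
        peak = np.max(np.abs(u))
        for _ in range(50):
            state = step(state, cfg, c1, c2, metric=identity)
            new_peak = np.max(np.abs(state.values))
            assert new_peak <= peak + 1e-9
            peak = new_peak


class TestMaxTimestep:
    def test_reference_configuration(self):
        """K=16, c1=1, c2=(16/64)^2: the bound evaluates to 0.87."""
        assert max_timestep(16, 1.0, 0.0625) == pytest.approx(0.87, abs=5e-3)

    def test_decreasing_in_orientation_count(self):
        r = 16.0
        assert max_timestep(32, r, 1.0) < max_timestep(16, r, 1.0)

    def test_experimental_step_is_stable_for_all_protocols(self):
        from gaborlift.presets import PRESETS

        for preset in PRESETS.values():
            beta = preset.bank.K / preset.image_size
            assert preset.flow.dt <= max_timestep(preset.bank.K, 1.0, beta**2)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            max_timestep(0, 1.0, 1.0)
        with pytest.raises(ValueError):
            max_timestep(8, 1.0, 0.0)


class TestEvolveAndEnhance:
    def test_energy_decays_at_experimental_step(self, denoise_bank):
        """Diffusion contract: per-channel energy is non-increasing at dt=0.1."""
        from gaborlift.fixtures import make_pair

        _, noisy = make_pair()
        lifted = lift(noisy, denoise_bank)
        diag = FlowDiagnostics()
        evolve_channel(
            lifted.coeffs[:, :, :, 7], denoise_bank.thetas,
            FlowConfig(dt=0.1, iterations=10), 1.0, 0.0625, diag,
        )
        en = np.array(diag.energy)
        assert np.all(np.diff(en) <= 1e-6 * en[0])

    def test_zero_iterations_equals_round_trip(self, small_bank):
        from gaborlift.fixtures import bandlimited_image

        img = bandlimited_image(32)
        cfg = FlowConfig(dt=0.1, iterations=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = enhance(img, small_bank, cfg)
            ref = reconstruct(lift(img, small_bank), small_bank)
        np.testing.assert_array_equal(out, ref)

    def test_constant_image_is_near_fixed_point(self, small_bank):
        img = np.full((32, 32), 0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = enhance(img, small_bank, FlowConfig(dt=0.1, iterations=5))
            ref = enhance(img, small_bank, FlowConfig(dt=0.1, iterations=0))
        # the flow leaves every channel of a constant lift unchanged, so any
        # deviation equals the plain round-trip reconstruction error
        np.testing.assert_allclose(out, ref, atol=1e-8)

    def test_unstable_dt_rejected_upfront(self, small_bank):
        cfg = FlowConfig(dt=5.0, iterations=3)
        with pytest.raises(ValueError, match="stability bound"):
            enhance(np.zeros((32, 32)), small_bank, cfg)

    def test_metric_source_modulus_runs(self, small_bank):
        from gaborlift.fixtures import bandlimited_image

        img = bandlimited_image(32)
        cfg = FlowConfig(dt=0.1, iterations=2, metric_source="modulus", metric_period=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = enhance(img, small_bank, cfg)
        assert out.shape == img.shape
        assert np.all(np.isfinite(out))
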