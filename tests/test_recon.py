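import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mrgpet as m
from mrgpet import diffops
from mrgpet.projection import FWHM_TO_SIGMA


def smoothed_tv_value(u, spacing, alpha):
    """Independent smoothed-TV oracle: sum sqrt(alpha^2 + |grad u|^2)."""
    g = diffops.gradient(u, spacing)
    return float(np.sum(np.sqrt(alpha**2 + np.sum(g**2, axis=0))))


def smoothed_tv_gradient(u, spacing, alpha):
    """Independent smoothed-TV gradient: -div(grad u / sqrt(a^2 + |grad u|^2))."""
    g = diffops.gradient(u, spacing)
    root = np.sqrt(alpha**2 + np.sum(g**2, axis=0))
    return -diffops.divergence(g / root, spacing)


class TestDiffops:
    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_gradient_adjoint_identity(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.standard_normal((7, 9))
        p = rng.standard_normal((2, 7, 9))
        spacing = (1.3, 0.8)
        lhs = np.sum(diffops.gradient(u, spacing) * p)
        rhs = np.sum(u * diffops.gradient_adjoint(p, spacing))
        assert np.isclose(lhs, rhs, rtol=1e-12, atol=1e-12)


class TestNormalizedGradientField:
    def test_constant_prior_gives_zero_field(self):
        v = m.ImageGrid(np.full((10, 10), 3.0), (1.0, 1.0))
        xi = m.normalized_gradient_field(v, eta=0.5)
        assert np.all(xi.xi == 0)

    def test_known_gradient_magnitude(self):
        # ramp with |grad v| = 3 along one axis, eta = 4 -> |xi| = 0.6
        v = m.ImageGrid(np.outer(3.0 * np.arange(8), np.ones(8)), (1.0, 1.0))
        xi = m.normalized_gradient_field(v, eta=4.0)
        mag = np.sqrt(np.sum(xi.xi**2, axis=0))
        assert np.allclose(mag[:-1, :], 0.6)

    def test_magnitude_strictly_below_one(self):
        rng = np.random.default_rng(3)
        v = m.ImageGrid(10.0 * rng.random((12, 12)), (0.7, 1.1))
        xi = m.normalized_gradient_field(v, eta=1e-3)
        assert np.sqrt(np.sum(xi.xi**2, axis=0)).max() < 1.0

    def test_large_eta_suppresses_guidance(self):
        rng = np.random.default_rng(4)
        v = m.ImageGrid(rng.random((10, 10)), (1.0, 1.0))
        xi = m.normalized_gradient_field(v, eta=1e6)
        assert np.abs(xi.xi).max() < 1e-5

    def test_nonpositive_eta_rejected(self):
        v = m.ImageGrid(np.zeros((8, 8)), (1.0, 1.0))
        with pytest.raises(ValueError):
            m.normalized_gradient_field(v, eta=0.0)


class TestPlsPenalty:
    def test_constant_image_gives_alpha_per_voxel(self):
        u = m.ImageGrid(np.full((9, 11), 2.0), (1.0, 1.0))
        v = m.ImageGrid(np.arange(99, dtype=float).reshape(9, 11), (1.0, 1.0))
        xi = m.normalized_gradient_field(v, eta=1.0)
        assert m.pls_penalty(u, xi, alpha=0.1) == pytest.approx(0.1 * 99)

    def test_zero_field_reduces_to_smoothed_tv(self):
        rng = np.random.default_rng(0)
        u = m.ImageGrid(rng.random((10, 10)), (1.2, 0.9))
        vconst = m.ImageGrid(np.ones((10, 10)), (1.2, 0.9))
        xi0 = m.normalized_gradient_field(vconst, eta=0.3)
        tv = smoothed_tv_value(u.values, u.spacing_mm, 0.2)
        assert m.pls_penalty(u, xi0, 0.2) == pytest.approx(tv, rel=1e-12)

    def test_shared_edges_barely_penalized(self):
        """When u == v and eta -> 0, the integrand tends to alpha at edges:
        boundaries shared with the anatomical image cost almost nothing."""
        step = np.zeros((8, 8))
        step[:, 4:] = 5.0
        u = m.ImageGrid(step, (1.0, 1.0))
        alpha = 0.01
        xi = m.normalized_gradient_field(u, eta=1e-8)
        p = m.pls_penalty(u, xi, alpha)
        assert p == pytest.approx(alpha * 64, rel=1e-3)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_bounded_between_alpha_floor_and_smoothed_tv(self, seed):
        rng = np.random.default_rng(seed)
        u = m.ImageGrid(rng.random((8, 8)), (1.0, 1.0))
        v = m.ImageGrid(rng.random((8, 8)), (1.0, 1.0))
        alpha = float(rng.uniform(0.05, 0.5))
        xi = m.normalized_gradient_field(v, eta=float(rng.uniform(0.05, 1.0)))
        p = m.pls_penalty(u, xi, alpha)
        assert p >= 64 * alpha - 1e-9
        assert p <= smoothed_tv_value(u.values, u.spacing_mm, alpha) + 1e-9


class TestPlsGradient:
    def test_constant_image_is_stationary(self):
        u = m.ImageGrid(np.full((8, 8), 3.0), (1.0, 1.0))
        v = m.ImageGrid(np.random.default_rng(0).random((8, 8)), (1.0, 1.0))
        xi = m.normalized_gradient_field(v, eta=0.2)
        assert np.allclose(m.pls_gradient(u, xi, 0.3).values, 0.0)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(1)
        u = m.ImageGrid(rng.random((8, 8)), (1.1, 0.9))
        v = m.ImageGrid(rng.random((8, 8)), (1.1, 0.9))
        xi = m.normalized_gradient_field(v, eta=0.25)
        alpha = 0.2
        g = m.pls_gradient(u, xi, alpha).values
        h = 1e-5
        fd = np.zeros_like(g)
        for i in range(8):
            for j in range(8):
                up, um = u.copy(), u.copy()
                up.values[i, j] += h
                um.values[i, j] -= h
                fd[i, j] = (
                    m.pls_penalty(up, xi, alpha) - m.pls_penalty(um, xi, alpha)
                ) / (2 * h)
        assert np.linalg.norm(g - fd) / np.linalg.norm(g) < 1e-4

    def test_zero_field_matches_smoothed_tv_gradient(self):
        rng = np.random.default_rng(2)
        u = m.ImageGrid(rng.random((9, 9)), (1.0, 1.4))
        vconst = m.ImageGrid(np.zeros((9, 9)), (1.0, 1.4))
        xi0 = m.normalized_gradient_field(vconst, eta=1.0)
        want = smoothed_tv_gradient(u.values, u.spacing_mm, 0.15)
        got = m.pls_gradient(u, xi0, 0.15).values
        assert np.allclose(got, want, rtol=1e-12, atol=1e-12)


class TestOsem:
    def test_single_pixel_single_lor_closed_form(self):
        """1 pixel, 1 LOR, unit weight, y = 5, u0 = 1 -> u = 5 after one
        MLEM update (the classic closed-form sanity check)."""
        model = m.SystemModel(
            n_angles=1, n_radial_bins=1, bin_spacing_mm=1.0, psf_fwhm_mm=0.0
        )
        u0 = m.ImageGrid(np.ones((1, 1)), (1.0, 1.0))
        a = model.matrix((1, 1), (1.0, 1.0)).toarray()[0, 0]
        assert a == pytest.approx(1.0)
        y = m.Sinogram(np.array([[5.0]]))
        out = m.mlem(y, model, 1, u0=u0)[-1]
        assert out.values[0, 0] == pytest.approx(5.0, rel=1e-12)

    def test_exact_data_is_fixed_point(self, calibrated, small_phantom):
        act, _, _ = small_phantom
        model, ybar = calibrated
        out = m.osem(
            ybar, model, m.ReconConfig(n_subsets=4, n_iterations=1), u0=act.copy()
        )[-1]
        nz = act.values > 0
        assert np.allclose(out.values[nz], act.values[nz], rtol=1e-12)

    def test_single_subset_matches_independent_mlem(self, calibrated, small_phantom):
        """osem with n_subsets=1 equals a hand-rolled MLEM written directly
        from the multiplicative update formula."""
        act, _, _ = small_phantom
        model, ybar = calibrated
        y = m.add_poisson_noise(ybar, 21)
        got = m.osem(y, model, m.ReconConfig(n_subsets=1, n_iterations=3), grid=act)

        s = m.sensitivity_image(model, act).values
        fov = s > 1e-9 * s.max()
        total = y.values.sum()
        u = np.zeros(act.shape)
        u[fov] = total / s[fov].sum()
        for _ in range(3):
            ybar_i = m.forward_project(act.with_values(u), model).values
            ratio = np.divide(
                y.values, ybar_i, out=np.zeros_like(ybar_i), where=ybar_i > 0
            )
            back = m.back_project(m.Sinogram(ratio), model, act).values
            unew = np.zeros_like(u)
            unew[fov] = u[fov] * back[fov] / s[fov]
            u = unew
        assert np.allclose(got[-1].values, u, rtol=1e-10, atol=1e-12)

    def test_snapshots_one_per_iteration(self, calibrated, small_phantom):
        act, _, _ = small_phantom
        model, ybar = calibrated
        y = m.add_poisson_noise(ybar, 2)
        snaps = m.osem(y, model, m.ReconConfig(n_subsets=4, n_iterations=3), grid=act)
        assert len(snaps) == 3
        last_only = m.osem(
            y, model,
            m.ReconConfig(n_subsets=4, n_iterations=3, save_every_iteration=False),
            grid=act,
        )
        assert len(last_only) == 1
        assert np.array_equal(last_only[0].values, snaps[-1].values)

    def test_nonnegativity_preserved(self, calibrated, small_phantom):
        act, _, _ = small_phantom
        model, ybar = calibrated
        y = m.add_poisson_noise(ybar, 3)
        out = m.osem(y, model, m.ReconConfig(n_subsets=8, n_iterations=2), grid=act)
        assert np.all(out[-1].values >= 0)


class TestGaussianPostfilter:
    def test_zero_fwhm_is_identity(self, small_phantom):
        act, _, _ = small_phantom
        assert np.array_equal(m.gaussian_postfilter(act, 0.0).values, act.values)

    def test_fwhm_sigma_relation(self):
        # sigma = FWHM / (2 sqrt(2 ln 2)); at 3 mm FWHM this is 1.27398 mm
        assert 3.0 * FWHM_TO_SIGMA == pytest.approx(3.0 / 2.354820045, rel=1e-9)
        assert 3.0 * FWHM_TO_SIGMA == pytest.approx(1.27398, abs=5e-6)

    def test_flat_image_unchanged_and_sum_preserved(self, small_phantom):
        act, _, _ = small_phantom
        flat = act.with_values(np.full(act.shape, 1.7))
        out = m.gaussian_postfilter(flat, 3.0)
        assert np.allclose(out.values, 1.7, atol=1e-12)
        out2 = m.gaussian_postfilter(act, 3.0)
        assert np.isclose(out2.values.sum(), act.values.sum(), rtol=1e-10)

    def test_negative_fwhm_rejected(self, small_phantom):
        act, _, _ = small_phantom
        with pytest.raises(ValueError):
            m.gaussian_postfilter(act, -1.0)


class TestMrgReconstruct:
    def test_beta_zero_identical_to_osem(self, calibrated, small_phantom):
        act, prior, _ = small_phantom
        model, ybar = calibrated
        y = m.add_poisson_noise(ybar, 4)
        cfg = m.ReconConfig(n_subsets=4, n_iterations=2)
        pen = m.PenaltyParams(0.0, alpha=0.1, eta=0.1)
        a = m.mrg_reconstruct(y, model, prior, pen, cfg)
        b = m.osem(y, model, cfg, grid=act)
        for ia, ib in zip(a, b):
            assert np.array_equal(ia.values, ib.values)

    def test_constant_prior_equals_smoothed_tv_reconstruction(
        self, calibrated, small_phantom
    ):
        """With a flat prior, xi == 0 and the MR-guided loop must coincide
        with a penalized loop driven by an independent smoothed-TV gradient."""
        act, _, _ = small_phantom
        model, ybar = calibrated
        y = m.add_poisson_noise(ybar, 5)
        cfg = m.ReconConfig(n_subsets=4, n_iterations=2)
        flat_prior = act.with_values(np.ones(act.shape))
        alpha, beta, kappa = 0.05, 1.0, m.auto_weight_scale(model, act)
        pen = m.PenaltyParams(beta, alpha, eta=1.0, weight_scale=kappa)
        got = m.mrg_reconstruct(y, model, flat_prior, pen, cfg)[-1]

        # independent OSL loop with the smoothed-TV gradient
        nb = model.n_radial_bins
        s_all = m.sensitivity_image(model, act).values
        fov = s_all > 1e-9 * s_all.max()
        u = np.zeros(act.shape)
        u[fov] = y.values.sum() / s_all[fov].sum()
        from mrgpet.recon import _bit_reversed_order

        order = _bit_reversed_order(4)
        subsets = [np.arange(model.n_angles)[np.arange(model.n_angles) % 4 == k]
                   for k in range(4)]
        A = model.matrix(act.shape, act.spacing_mm)
        norm = model.norm_array().ravel()
        for _ in range(2):
            for k in order:
                rows = (subsets[k][:, None] * nb + np.arange(nb)[None, :]).ravel()
                Ak = A[rows]
                nk = norm[rows]
                yk = y.values.ravel()[rows]
                sk = (Ak.T @ nk).reshape(act.shape)
                ybar_k = nk * (Ak @ u.ravel())
                ratio = np.divide(
                    yk, ybar_k, out=np.zeros_like(ybar_k), where=ybar_k > 0
                )
                back = (Ak.T @ (nk * ratio)).reshape(act.shape)
                pgrad = smoothed_tv_gradient(u, act.spacing_mm, alpha)
                denom = sk + (beta * kappa / 4) * pgrad
                denom = np.maximum(denom, 1e-3 * sk)
                unew = np.zeros_like(u)
                msk = (sk > 0) & fov
                unew[msk] = u[msk] * back[msk] / denom[msk]
                u = unew
        assert np.allclose(got.values, u, rtol=1e-8, atol=1e-10)

    def test_prior_grid_mismatch_rejected(self, calibrated, small_phantom):
        act, _, _ = small_phantom
        model, ybar = calibrated
        y = m.add_poisson_noise(ybar, 6)
        bad_prior = m.ImageGrid(np.ones((32, 32)), (1.2, 1.2))
        with pytest.raises(ValueError, match="grid"):
            m.mrg_reconstruct(
                y, model, bad_prior, m.PenaltyParams(1.0, 0.1, 0.1),
                m.ReconConfig(n_subsets=2, n_iterations=1),
                u0=act.with_values(np.ones(act.shape)),
            )

    def test_penalized_objective_nonincreasing_single_subset(
        self, calibrated, small_phantom
    ):
        """One-step-late MAP-EM with one subset decreases the penalized
        objective monotonically on this problem (empirical contract)."""
        act, prior, _ = small_phantom
        model, ybar = calibrated
        y = m.add_poisson_noise(ybar, 7)
        alpha = m.default_alpha(4.0, act.spacing_mm)
        eta = m.default_eta(prior)
        kappa = m.auto_weight_scale(model, act)
        pen = m.PenaltyParams(1.0, alpha, eta, weight_scale=kappa)
        snaps = m.mrg_reconstruct(
            y, model, prior, pen, m.ReconConfig(n_subsets=1, n_iterations=10)
        )
        xi = m.normalized_gradient_field(prior, eta)
        objs = [m.objective_value(im, y, model, xi, pen) for im in snaps]
        diffs = np.diff(objs)
        assert np.all(diffs <= np.abs(objs[0]) * 1e-9)


class TestObjectiveValue:
    def test_zero_counts_beta_zero_equals_total_expectation(
        self, calibrated, small_phantom
    ):
        act, _, _ = small_phantom
        model, ybar = calibrated
        y0 = m.Sinogram(np.zeros(model.sino_shape))
        pen = m.PenaltyParams(0.0, 1.0, 1.0)
        got = m.objective_value(act, y0, model, None, pen)
        assert got == pytest.approx(ybar.values.sum(), rel=1e-12)

    def test_single_lor_unit_value(self):
        model = m.SystemModel(
            n_angles=1, n_radial_bins=1, bin_spacing_mm=1.0, psf_fwhm_mm=0.0
        )
        u = m.ImageGrid(np.ones((1, 1)), (1.0, 1.0))
        y = m.Sinogram(np.array([[1.0]]))
        got = m.objective_value(u, y, model, None, m.PenaltyParams(0.0, 1.0, 1.0))
        assert got == pytest.approx(1.0)  # 1 - 1*log(1)

    def test_linear_in_beta(self, small_phantom, calibrated):
        act, prior, _ = small_phantom
        model, ybar = calibrated
        y = m.add_poisson_noise(ybar, 8)
        xi = m.normalized_gradient_field(prior, eta=0.05)
        p1 = m.PenaltyParams(1.0, 0.1, 0.05)
        p2 = m.PenaltyParams(2.0, 0.1, 0.05)
        o1 = m.objective_value(act, y, model, xi, p1)
        o2 = m.objective_value(act, y, model, xi, p2)
        assert o2 - o1 == pytest.approx(m.pls_penalty(act, xi, 0.1), rel=1e-9)

    def test_infinite_objective_rejected(self):
        model = m.SystemModel(
            n_angles=1, n_radial_bins=1, bin_spacing_mm=1.0, psf_fwhm_mm=0.0
        )
        u = m.ImageGrid(np.zeros((1, 1)), (1.0, 1.0))
        y = m.Sinogram(np.array([[3.0]]))
        with pytest.raises(ValueError, match="infinite"):
            m.objective_value(u, y, model, None, m.PenaltyParams(0.0, 1.0, 1.0))
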