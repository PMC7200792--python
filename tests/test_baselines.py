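"""Classical baselines: Gerchberg-Saxton projections, the spectral TIE
solver and the RED penalty machinery."""

import numpy as np
import pytest

from physennet import (
    GSConfig, NetworkSpec, OptimizationConfig, PhantomSpec, PropagationSpec,
    REDConfig, TIEInput, forward_intensity, generate_phantom, gs_retrieve,
    make_denoiser, red_reconstruct, reconstruct, tie_solve,
)
from physennet.baselines import red_penalty
from tests.conftest import PITCH, WAVELENGTH

TINY_NET = NetworkSpec(n_scales=2, base_channels=4)


class TestGerchbergSaxton:
    def test_uniform_intensity_fixed_point(self, spec10mm):
        """A plane wave (flat phase) reproduces itself: zeros init is a
        fixed point of the projection cycle."""
        I = forward_intensity(np.zeros((16, 16)), spec10mm)
        phase = gs_retrieve(GSConfig(planes=[(I, 10e-3)], n_iterations=5), spec10mm)
        np.testing.assert_allclose(phase, 0.0, atol=1e-10)

    def test_error_reduction_monotone(self, phantom32, spec10mm):
        """Single-plane modulus mismatch is non-increasing (classic
        error-reduction behaviour on noise-free data)."""
        I = forward_intensity(phantom32, spec10mm)
        _, errors = gs_retrieve(
            GSConfig(planes=[(I, 10e-3)], n_iterations=50), spec10mm,
            return_errors=True)
        assert np.all(np.diff(errors) <= 1e-10)

    def test_multi_plane_recovers_smooth_phantom(self, phantom32, spec10mm):
        from physennet import mse
        planes = [(forward_intensity(phantom32,
                                     PropagationSpec(WAVELENGTH, PITCH, d)), d)
                  for d in (10e-3, 15e-3, 20e-3, 25e-3, 30e-3)]
        phase = gs_retrieve(GSConfig(planes=planes, n_iterations=100), spec10mm)
        assert mse(phase, phantom32) <= 0.03

    def test_zero_mean_output(self, phantom32, spec10mm):
        I = forward_intensity(phantom32, spec10mm)
        phase = gs_retrieve(GSConfig(planes=[(I, 10e-3)], n_iterations=3), spec10mm)
        assert phase.mean() == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_distances_rejected(self, spec10mm):
        I = np.ones((8, 8))
        with pytest.raises(ValueError, match="distinct"):
            gs_retrieve(GSConfig(planes=[(I, 0.01), (I, 0.01)]), spec10mm)

    def test_random_init_seeded(self, phantom32, spec10mm):
        I = forward_intensity(phantom32, spec10mm)
        cfg = GSConfig(planes=[(I, 10e-3)], n_iterations=3,
                       init_phase="random", seed=7)
        np.testing.assert_array_equal(gs_retrieve(cfg, spec10mm),
                                      gs_retrieve(cfg, spec10mm))


class TestTIE:
    def test_zero_axial_derivative_gives_flat_phase(self, spec10mm):
        I = np.ones((32, 32))
        phase = tie_solve(TIEInput(I, I, I, delta_z=1e-4), spec10mm)
        np.testing.assert_allclose(phase, 0.0, atol=1e-12)

    def test_linearity_in_intensity_derivative(self, spec10mm):
        rng = np.random.default_rng(0)
        I0 = np.ones((32, 32))
        dI = rng.standard_normal((32, 32)) * 0.01
        a = tie_solve(TIEInput(I0 - dI, I0, I0 + dI, 1e-4), spec10mm)
        b = tie_solve(TIEInput(I0 - 3 * dI, I0, I0 + 3 * dI, 1e-4), spec10mm)
        np.testing.assert_allclose(b, 3.0 * a, atol=1e-8 * np.abs(a).max())

    def test_recovers_quadratic_phase_curvature(self):
        """A weak defocus phase a*(x^2+y^2) under uniform illumination obeys
        the transport equation analytically; simulate the axial stack with
        the angular-spectrum model and recover the curvature by a quadratic
        fit on the central region."""
        n = 64
        spec = PropagationSpec(WAVELENGTH, PITCH, 0.0)
        x = (np.arange(n) - n / 2) * PITCH
        r2 = x[:, None] ** 2 + x[None, :] ** 2
        a = 2.0e6  # rad/m^2 -> ~0.26 rad peak-to-edge, weak-phase regime
        phi = a * r2
        dz = 2e-4
        Im = forward_intensity(phi, spec.with_distance(-dz))
        Ip = forward_intensity(phi, spec.with_distance(+dz))
        I0 = forward_intensity(phi, spec.with_distance(0.0))
        rec = tie_solve(TIEInput(Im, I0, Ip, dz), spec)
        # quadratic fit on the central quarter (away from the wrap seam)
        sl = slice(n // 2 - n // 8, n // 2 + n // 8)
        A = np.stack([r2[sl, sl].ravel(), np.ones(r2[sl, sl].size)]).T
        coef, *_ = np.linalg.lstsq(A, rec[sl, sl].ravel(), rcond=None)
        assert coef[0] == pytest.approx(a, rel=0.05)

    def test_shape_mismatch_rejected(self, spec10mm):
        with pytest.raises(ValueError, match="shape"):
            tie_solve(TIEInput(np.ones((8, 8)), np.ones((8, 8)),
                               np.ones((4, 4)), 1e-4), spec10mm)

    def test_invalid_delta_z(self):
        with pytest.raises(ValueError):
            TIEInput(np.ones((4, 4)), np.ones((4, 4)), np.ones((4, 4)), 0.0)


class TestRED:
    def test_identity_denoiser_zero_penalty(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 1, (8, 8))
        val, grad = red_penalty(phi, make_denoiser("identity"), lambda_red=0.7)
        assert val == 0.0
        np.testing.assert_array_equal(grad, 0.0)

    def test_gaussian_denoiser_gradient_matches_finite_differences(self):
        """For a linear symmetric denoiser the analytic RED gradient
        lambda*(phi - D(phi)) is the exact gradient of the penalty."""
        D = make_denoiser("gaussian", sigma=1.5)
        lam = 0.3
        rng = np.random.default_rng(1)
        phi = rng.uniform(0, 1, (8, 8))
        _, grad = red_penalty(phi, D, lam)
        eps = 1e-6
        for i, j in [(0, 0), (2, 5), (7, 7)]:
            p1, p2 = phi.copy(), phi.copy()
            p1[i, j] += eps
            p2[i, j] -= eps
            fd = (red_penalty(p1, D, lam)[0] - red_penalty(p2, D, lam)[0]) / (2 * eps)
            assert grad[i, j] == pytest.approx(fd, rel=1e-5)

    def test_lambda_zero_reduces_to_plain_reconstruction(self, spec10mm):
        ph = generate_phantom(PhantomSpec(size=16, n_features=2, seed=4))
        I = forward_intensity(ph, spec10mm)
        cfg = OptimizationConfig(epochs=30, seed=5)
        plain = reconstruct(I, spec10mm, TINY_NET, cfg)
        red = red_reconstruct(I, spec10mm, TINY_NET, REDConfig(lambda_red=0.0), cfg)
        np.testing.assert_array_equal(plain.phase, red)

    def test_tv_denoiser_available(self):
        D = make_denoiser("tv", weight=0.05)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (16, 16))
        y = D(x)
        assert y.shape == x.shape
        # TV smoothing reduces total variation
        tv = lambda z: np.abs(np.diff(z, axis=0)).sum() + np.abs(np.diff(z, axis=1)).sum()
        assert tv(y) < tv(x)

    def test_unknown_denoiser_rejected(self):
        with pytest.raises(ValueError, match="denoiser"):
            make_denoiser("bm3d")

    def test_stronger_lambda_moves_phase_toward_denoiser_fixed_points(self, spec10mm):
        """Sweeping the regularisation strength up shrinks the RED penalty
        of the final phase (the denoiser residual)."""
        ph = generate_phantom(PhantomSpec(size=16, n_features=2, seed=4))
        I = forward_intensity(ph, spec10mm)
        D = make_denoiser("gaussian", sigma=2.0)
        cfg = OptimizationConfig(epochs=150, seed=3)
        residuals = []
        for lam in (0.0, 1.0, 100.0):
            phase = red_reconstruct(I, spec10mm, TINY_NET,
                                    REDConfig(lambda_red=lam, denoiser=D), cfg)
            r = phase - D(phase)
            residuals.append(float(np.sum(phase * r)))
        assert residuals[2] < residuals[1] < residuals[0]
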