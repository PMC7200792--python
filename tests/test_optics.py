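"""Forward-model tests: the angular-spectrum propagator against an
independent DFT-matrix oracle, plus its physical invariants."""

import numpy as np
import pytest

from physennet import (
    PropagationSpec, forward_intensity, make_frequency_grid, phase_to_field,
    propagate, transfer_function,
)
from tests.conftest import PITCH, WAVELENGTH


def oracle_propagate(field: np.ndarray, spec: PropagationSpec,
                     distance: float) -> np.ndarray:
    """Brute-force propagation via explicit DFT matrices (no FFT).

    Builds the forward and inverse DFT as dense matrix products and applies
    the angular-spectrum transfer function between them; an O(n^3)-per-side
    summation completely independent of the FFT code path.
    """
    n = field.shape[0]
    j = np.arange(n)
    F = np.exp(-2j * np.pi * np.outer(j, j) / n)          # forward DFT matrix
    Finv = np.conj(F) / n                                  # inverse DFT matrix
    spectrum = F @ field @ F.T
    fx, fy = make_frequency_grid(n, spec.pitch)
    lam, k = spec.wavelength, 2 * np.pi / spec.wavelength
    radicand = 1.0 - (lam * fx) ** 2 - (lam * fy) ** 2
    G = np.where(radicand >= 0,
                 np.exp(1j * k * distance * np.sqrt(np.clip(radicand, 0, None))),
                 0.0)
    return Finv @ (spectrum * G) @ Finv.T


class TestFieldAndGrids:
    def test_zero_phase_gives_unit_field(self):
        f = phase_to_field(np.zeros((8, 8)))
        np.testing.assert_array_equal(f, np.ones((8, 8), complex))

    def test_half_pi_phase_gives_imaginary_unit(self):
        f = phase_to_field(np.full((4, 4), np.pi / 2))
        np.testing.assert_allclose(f, np.full((4, 4), 1j), atol=1e-15)

    def test_unit_modulus_for_any_phase(self):
        rng = np.random.default_rng(0)
        f = phase_to_field(rng.uniform(-50, 50, (16, 16)))
        np.testing.assert_allclose(np.abs(f), 1.0, rtol=1e-14)

    def test_nonfinite_phase_rejected(self):
        bad = np.zeros((4, 4))
        bad[1, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            phase_to_field(bad)

    def test_frequency_grid_single_sample(self):
        fx, fy = make_frequency_grid(1, 1.0)
        assert fx.ravel().tolist() == [0.0]

    def test_frequency_grid_matches_dft_definition(self):
        fx, _ = make_frequency_grid(4, 1.0)
        np.testing.assert_array_equal(fx.ravel(), [0.0, 0.25, -0.5, -0.25])

    def test_frequency_grid_nyquist(self):
        fx, fy = make_frequency_grid(16, PITCH)
        assert np.max(np.abs(fx)) == pytest.approx(1.0 / (2 * PITCH))
        assert fx[0, 0] == 0.0 and fy[0, 0] == 0.0

    def test_invalid_grid_size(self):
        with pytest.raises(ValueError):
            make_frequency_grid(0, 1.0)


class TestTransferFunction:
    def test_dc_term(self, spec10mm):
        fx, fy = np.zeros((1, 1)), np.zeros((1, 1))
        G = transfer_function(fx, fy, spec10mm)
        expected = np.exp(1j * spec10mm.wavenumber * spec10mm.distance)
        np.testing.assert_allclose(G[0, 0], expected, rtol=1e-14)

    def test_zero_distance_is_identity_on_propagating_band(self):
        spec = PropagationSpec(WAVELENGTH, PITCH, 0.0)
        fx, fy = make_frequency_grid(32, PITCH)
        G = transfer_function(fx, fy, spec)
        np.testing.assert_array_equal(G, np.ones((32, 32), complex))

    def test_evanescent_band_zeroed(self, spec10mm):
        f_ev = 1.5 / WAVELENGTH  # beyond the propagation cutoff 1/lambda
        G = transfer_function(np.array([[f_ev]]), np.array([[0.0]]), spec10mm)
        assert G[0, 0] == 0

    def test_unimodular_on_propagating_band(self, spec10mm):
        fx, fy = make_frequency_grid(64, PITCH)
        G = transfer_function(fx, fy, spec10mm)
        np.testing.assert_allclose(np.abs(G), 1.0, rtol=1e-14)


class TestPropagate:
    def test_zero_distance_identity(self, spec10mm):
        rng = np.random.default_rng(1)
        U = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        out = propagate(U, spec10mm, distance=0.0)
        np.testing.assert_allclose(out, U, atol=1e-14)

    def test_constant_field_picks_up_global_phase(self, spec10mm):
        U = np.full((16, 16), 2.0 + 0.0j)
        out = propagate(U, spec10mm)
        expected = U * np.exp(1j * spec10mm.wavenumber * spec10mm.distance)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    @pytest.mark.parametrize("n,distance", [(16, 10e-3), (32, 10e-3), (32, 180e-3)])
    def test_matches_dft_summation_oracle(self, n, distance):
        spec = PropagationSpec(WAVELENGTH, PITCH, distance)
        rng = np.random.default_rng(n)
        U = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        fast = propagate(U, spec)
        slow = oracle_propagate(U, spec, distance)
        err = np.linalg.norm(fast - slow) / np.linalg.norm(slow)
        assert err <= 1e-10

    def test_energy_conservation(self, spec10mm):
        rng = np.random.default_rng(2)
        U = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        out = propagate(U, spec10mm)  # 8 um pitch: no evanescent content on grid
        assert abs(np.sum(np.abs(out) ** 2) - np.sum(np.abs(U) ** 2)) \
            <= 1e-10 * np.sum(np.abs(U) ** 2)

    def test_round_trip(self, spec10mm):
        rng = np.random.default_rng(3)
        U = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        back = propagate(propagate(U, spec10mm, 10e-3), spec10mm, -10e-3)
        assert np.linalg.norm(back - U) / np.linalg.norm(U) <= 1e-10

    def test_semigroup(self, spec10mm):
        rng = np.random.default_rng(4)
        U = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        one_hop = propagate(U, spec10mm, 30e-3)
        two_hops = propagate(propagate(U, spec10mm, 10e-3), spec10mm, 20e-3)
        assert np.linalg.norm(one_hop - two_hops) / np.linalg.norm(one_hop) <= 1e-10

    def test_subwavelength_pitch_warns(self):
        spec = PropagationSpec(200e-9, 50e-9, 1e-6)  # pitch < lambda/2
        with pytest.warns(RuntimeWarning, match="evanescent"):
            propagate(np.ones((8, 8), complex), spec)


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=20, deadline=None)
@given(d1=st.floats(-0.05, 0.05), d2=st.floats(-0.05, 0.05))
def test_propagation_composes_over_any_signed_distances(d1, d2):
    """Semigroup property for arbitrary signed hops, including back-propagation."""
    spec = PropagationSpec(WAVELENGTH, PITCH, 0.0)
    rng = np.random.default_rng(11)
    U = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    once = propagate(U, spec, d1 + d2)
    twice = propagate(propagate(U, spec, d1), spec, d2)
    assert np.linalg.norm(once - twice) <= 1e-10 * np.linalg.norm(U)


class TestForwardIntensity:
    def test_flat_phase_gives_unit_intensity(self, spec10mm):
        I = forward_intensity(np.zeros((32, 32)), spec10mm)
        np.testing.assert_allclose(I, 1.0, rtol=1e-12)

    def test_global_phase_invisible(self, spec10mm):
        I = forward_intensity(np.full((32, 32), 1.3), spec10mm)
        np.testing.assert_allclose(I, 1.0, rtol=1e-12)

    def test_matches_oracle_on_phantom(self, phantom32, spec10mm):
        I = forward_intensity(phantom32, spec10mm)
        Ud = oracle_propagate(np.exp(1j * phantom32), spec10mm, spec10mm.distance)
        ref = np.abs(Ud) ** 2
        assert np.linalg.norm(I - ref) / np.linalg.norm(ref) <= 1e-10

    def test_nonnegative(self, phantom32):
        spec = PropagationSpec(WAVELENGTH, PITCH, 180e-3)
        assert np.all(forward_intensity(phantom32, spec) >= 0)

    def test_padded_model_reduces_wraparound_coupling(self, phantom32):
        # padding embeds the object in a transparent surround; the result
        # must stay a valid intensity of the same shape
        spec = PropagationSpec(WAVELENGTH, PITCH, 10e-3, pad_factor=2)
        I = forward_intensity(phantom32, spec)
        assert I.shape == phantom32.shape and np.all(I >= 0)


class TestSpecValidation:
    @pytest.mark.parametrize("kw", [
        dict(wavelength=-1e-9, pitch=PITCH),
        dict(wavelength=WAVELENGTH, pitch=0.0),
        dict(wavelength=WAVELENGTH, pitch=PITCH, pad_factor=0),
    ])
    def test_bad_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            PropagationSpec(distance=0.0, **kw)

    def test_wavenumber_derived(self, spec10mm):
        assert spec10mm.wavenumber == pytest.approx(2 * np.pi / WAVELENGTH)
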