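"""Unit and property tests for angular-spectrum propagation primitives."""

from __future__ import annotations

import cmath

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from holoscan.errors import InvalidParameterError, StructuralError
from holoscan.field_optics import (
    ComplexField,
    GridSpec,
    IlluminationGeometry,
    angular_spectrum_kernel,
    phase_rescale,
    propagate,
    tilt_carrier,
)


def _signed_freq(idx: int, n: int, pitch: float) -> float:
    """FFT frequency for lattice index, computed by hand (oracle helper)."""
    k = idx if idx < (n + 1) // 2 else idx - n
    return k / (n * pitch)


def _dft_propagate_oracle(
    values: np.ndarray, pitch: float, wavelength_nm: float, z_um: float, n_med=1.0
) -> np.ndarray:
    """Direct Rayleigh-Sommerfeld angular-spectrum summation, term by term.

    O(N^4) double loop over all lattice frequencies; deliberately avoids
    the FFT code path under test.
    """
    lam_um = wavelength_nm * 1e-3
    H, W = values.shape
    yy = np.arange(H)[:, None]
    xx = np.arange(W)[None, :]
    out = np.zeros((H, W), dtype=complex)
    cutoff_sq = (n_med / lam_um) ** 2
    for p in range(H):
        for q in range(W):
            coeff = np.sum(values * np.exp(-2j * np.pi * (p * yy / H + q * xx / W)))
            fy = _signed_freq(p, H, pitch)
            fx = _signed_freq(q, W, pitch)
            kz_sq = cutoff_sq - fx**2 - fy**2
            if kz_sq < 0:
                continue
            phase = cmath.exp(2j * np.pi * z_um * np.sqrt(kz_sq))
            out += coeff * phase * np.exp(2j * np.pi * (p * yy / H + q * xx / W))
    return out / (H * W)


class TestGridSpec:
    def test_invalid_pitch(self):
        with pytest.raises(InvalidParameterError):
            GridSpec(8, 8, 0.0)

    def test_too_small(self):
        with pytest.raises(InvalidParameterError):
            GridSpec(1, 8, 1.0)

    def test_freq_lattice_zero_first(self):
        g = GridSpec(8, 8, 2.0)
        assert g.freq_x()[0] == 0.0
        assert g.freq_y()[0] == 0.0


class TestComplexField:
    def test_shape_mismatch(self):
        with pytest.raises(StructuralError):
            ComplexField(GridSpec(4, 4, 1.0), np.ones((4, 5), complex))

    def test_nonfinite_rejected(self):
        bad = np.ones((4, 4), complex)
        bad[0, 0] = np.nan
        with pytest.raises(StructuralError):
            ComplexField(GridSpec(4, 4, 1.0), bad)


class TestAngularSpectrumKernel:
    def test_zero_distance_is_band_limit_indicator(self):
        # coarse wavelength so the lattice has evanescent corners
        g = GridSpec(32, 32, 1.85)
        k = angular_spectrum_kernel(g, 5300.0, 0.0)
        fx = g.freq_x()[None, :]
        fy = g.freq_y()[:, None]
        prop = fx**2 + fy**2 <= (1.0 / 5.3) ** 2
        assert np.all(k[prop] == 1.0)
        assert np.all(k[~prop] == 0.0)

    def test_dc_entry_closed_form(self):
        g = GridSpec(16, 16, 1.85)
        k = angular_spectrum_kernel(g, 530.0, 1000.0)
        expected = cmath.exp(2j * np.pi * 1000.0 / 0.530)
        assert k[0, 0] == pytest.approx(expected, abs=1e-9)

    def test_evanescent_count_matches_enumeration(self):
        # 32x32, pitch 1.85, lambda 530 nm: enumerate the lattice by hand
        for wavelength_nm in (530.0, 10000.0, 20000.0):
            g = GridSpec(32, 32, 1.85)
            cutoff_sq = (1.0 / (wavelength_nm * 1e-3)) ** 2
            expected = sum(
                1
                for p in range(32)
                for q in range(32)
                if _signed_freq(p, 32, 1.85) ** 2 + _signed_freq(q, 32, 1.85) ** 2
                > cutoff_sq
            )
            k = angular_spectrum_kernel(g, wavelength_nm, 250.0)
            assert int(np.sum(k == 0.0)) == expected
        # at 530 nm / 1.85 um pitch every lattice frequency propagates
        k530 = angular_spectrum_kernel(GridSpec(32, 32, 1.85), 530.0, 250.0)
        assert int(np.sum(k530 == 0.0)) == 0

    @given(
        z=st.floats(-2000, 2000),
        wl=st.floats(200, 20000),
        pitch=st.floats(0.2, 5.0),
    )
    @hyp_settings(max_examples=25, deadline=None)
    def test_kernel_magnitude_binary(self, z, wl, pitch):
        g = GridSpec(16, 16, pitch)
        k = angular_spectrum_kernel(g, wl, z)
        mags = np.abs(k)
        assert np.all((np.abs(mags - 1.0) < 1e-12) | (mags == 0.0))

    def test_invalid_wavelength(self):
        with pytest.raises(InvalidParameterError):
            angular_spectrum_kernel(GridSpec(8, 8, 1.0), -1.0, 100.0)


class TestPropagate:
    def test_matches_bruteforce_dft_oracle(self):
        g = GridSpec(16, 16, 1.85 / 4)
        values = np.zeros(g.shape, complex)
        values[5, 9] = 1.0  # single bright pixel
        field = ComplexField(g, values)
        out = propagate(field, 530.0, 200.0)
        oracle = _dft_propagate_oracle(values, g.pitch_um, 530.0, 200.0)
        assert np.max(np.abs(out.values - oracle)) < 1e-10

    def test_oracle_on_random_field(self):
        rng = np.random.default_rng(7)
        g = GridSpec(12, 16, 1.1)
        values = rng.normal(size=g.shape) + 1j * rng.normal(size=g.shape)
        out = propagate(ComplexField(g, values), 633.0, -150.0)
        oracle = _dft_propagate_oracle(values, g.pitch_um, 633.0, -150.0)
        assert np.max(np.abs(out.values - oracle)) < 1e-10

    def test_uniform_field_invariant(self):
        g = GridSpec(32, 32, 1.85)
        field = ComplexField(g, np.ones(g.shape, complex))
        out = propagate(field, 530.0, 750.0)
        np.testing.assert_allclose(np.abs(out.values), 1.0, atol=1e-12)
        # only a global phase: all values identical
        assert np.max(np.abs(out.values - out.values[0, 0])) < 1e-12

    def test_round_trip_band_limited(self):
        rng = np.random.default_rng(3)
        g = GridSpec(32, 32, 1.85 / 4)
        values = rng.normal(size=g.shape) + 1j * rng.normal(size=g.shape)
        field = ComplexField(g, values)
        # at this pitch / wavelength the whole lattice propagates -> input
        # is already band-limited
        fwd = propagate(field, 530.0, 640.0)
        back = propagate(fwd, 530.0, -640.0)
        assert np.max(np.abs(back.values - values)) < 1e-8

    def test_round_trip_is_band_limit_projection(self):
        rng = np.random.default_rng(4)
        g = GridSpec(24, 24, 1.85)
        wl = 8000.0  # coarse wavelength: evanescent corners exist
        values = rng.normal(size=g.shape) + 1j * rng.normal(size=g.shape)
        field = ComplexField(g, values)
        once = propagate(propagate(field, wl, 100.0), wl, -100.0)
        # idempotent after the first application
        twice = propagate(propagate(once, wl, 100.0), wl, -100.0)
        assert np.max(np.abs(twice.values - once.values)) < 1e-10
        # and equals explicit projection through the z=0 kernel
        proj = propagate(field, wl, 0.0)
        assert np.max(np.abs(once.values - proj.values)) < 1e-10

    @given(z=st.floats(-1500, 1500), seed=st.integers(0, 2**31))
    @hyp_settings(max_examples=15, deadline=None)
    def test_band_limited_energy_conserved(self, z, seed):
        rng = np.random.default_rng(seed)
        g = GridSpec(16, 16, 0.5)
        values = rng.normal(size=g.shape) + 1j * rng.normal(size=g.shape)
        field = ComplexField(g, propagate(ComplexField(g, values), 530.0, 0.0).values)
        out = propagate(field, 530.0, z)
        e_in = np.sum(np.abs(field.values) ** 2)
        e_out = np.sum(np.abs(out.values) ** 2)
        assert abs(e_out - e_in) <= 1e-9 * e_in


class TestTiltCarrier:
    def test_normal_incidence(self):
        g = GridSpec(16, 16, 1.85)
        out = tilt_carrier(IlluminationGeometry(), 530.0, g)
        np.testing.assert_allclose(out.values, 1.0, atol=1e-14)

    def test_carrier_frequencies_x(self):
        geom = IlluminationGeometry(theta_rad=np.pi / 6, phi_rad=0.0)
        fx, fy = geom.carrier_freqs(530.0)
        assert fx == pytest.approx(np.sin(np.pi / 6) / 0.530, rel=1e-12)
        assert fx == pytest.approx(0.9434, abs=1e-4)
        assert fy == pytest.approx(0.0, abs=1e-12)

    def test_carrier_frequencies_y(self):
        geom = IlluminationGeometry(theta_rad=np.pi / 6, phi_rad=np.pi / 2)
        fx, fy = geom.carrier_freqs(530.0)
        assert fx == pytest.approx(0.0, abs=1e-12)
        assert fy == pytest.approx(0.9434, abs=1e-4)

    def test_ramp_phase_gradient(self):
        g = GridSpec(8, 8, 2.0)
        geom = IlluminationGeometry(theta_rad=0.1, phi_rad=0.3)
        out = tilt_carrier(geom, 600.0, g)
        fx, fy = geom.carrier_freqs(600.0)
        np.testing.assert_allclose(np.abs(out.values), 1.0, atol=1e-12)
        # adjacent-pixel phase difference along x equals 2 pi fx pitch
        dphi = np.angle(out.values[0, 1] / out.values[0, 0])
        assert dphi == pytest.approx(2 * np.pi * fx * 2.0, rel=1e-9)

    def test_invalid_theta(self):
        with pytest.raises(InvalidParameterError):
            IlluminationGeometry(theta_rad=np.pi)


class TestPhaseRescale:
    def test_identity_when_equal(self):
        g = GridSpec(4, 4, 1.0)
        rng = np.random.default_rng(0)
        values = rng.normal(size=g.shape) + 1j * rng.normal(size=g.shape)
        field = ComplexField(g, values)
        out = phase_rescale(field, 530.0, 530.0)
        np.testing.assert_array_equal(out.values, values)

    def test_zero_phase_fixed_point(self):
        g = GridSpec(4, 4, 1.0)
        field = ComplexField(g, 2.5 * np.ones(g.shape, complex))
        out = phase_rescale(field, 530.0, 642.0)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-14)

    def test_stated_arithmetic(self):
        g = GridSpec(2, 2, 1.0)
        field = ComplexField(g, 3.0 * np.exp(1j * 0.5) * np.ones(g.shape))
        out = phase_rescale(field, 530.0, 536.0)
        expected_phase = 0.5 * 530.0 / 536.0
        np.testing.assert_allclose(np.angle(out.values), expected_phase, rtol=1e-12)
        np.testing.assert_allclose(np.abs(out.values), 3.0, rtol=1e-13)

    @given(seed=st.integers(0, 2**31), wl_to=st.floats(400, 700))
    @hyp_settings(max_examples=25, deadline=None)
    def test_magnitude_preserved(self, seed, wl_to):
        rng = np.random.default_rng(seed)
        g = GridSpec(8, 8, 1.0)
        values = rng.normal(size=g.shape) + 1j * rng.normal(size=g.shape)
        field = ComplexField(g, values)
        out = phase_rescale(field, 530.0, wl_to)
        np.testing.assert_allclose(np.abs(out.values), np.abs(values), rtol=1e-12)

    def test_composition_restores_unwrapped_phases(self):
        g = GridSpec(4, 4, 1.0)
        rng = np.random.default_rng(1)
        phases = rng.uniform(-3.0, 3.0, size=g.shape)  # safely inside (-pi, pi)
        field = ComplexField(g, np.exp(1j * phases))
        out = phase_rescale(phase_rescale(field, 530.0, 536.0), 536.0, 530.0)
        # 530 -> 536 shrinks phases, so no wrap boundary is crossed
        np.testing.assert_allclose(np.angle(out.values), phases, atol=1e-12)
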