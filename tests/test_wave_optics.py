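"""Angular-spectrum propagation: transfer function, identities, oracles."""

import numpy as np
import pytest

from dcod.metrics import nrms
from dcod.wave_optics import (
    ComplexField,
    Hologram,
    ObjectField,
    PropagationSettings,
    backpropagate,
    coherence_length,
    coherence_radius,
    field_of_view,
    hologram_intensity,
    propagate,
    transfer_function,
)

LAM = 532.2
Z = 300.0
PITCH = 1.12


def settings(z=Z, **kw) -> PropagationSettings:
    return PropagationSettings(wavelength_nm=LAM, distance_um=z, pitch_um=PITCH, **kw)


def band_limited_field(n: int, seed: int, cutoff_frac: float = 0.25) -> ComplexField:
    """Random field with spectrum confined well inside the propagating band."""
    rng = np.random.default_rng(seed)
    spec = np.zeros((n, n), dtype=complex)
    m = max(int(n * cutoff_frac), 2)
    block = rng.normal(size=(m, m)) + 1j * rng.normal(size=(m, m))
    spec[:m, :m] = block  # low frequencies only (fftshift-free corner block)
    values = np.fft.ifft2(spec)
    return ComplexField(values, PITCH, LAM)


class TestTransferFunction:
    def test_dc_term_is_plane_wave_phase(self):
        P = transfer_function((8, 8), settings())
        assert P[0, 0] == pytest.approx(np.exp(2j * np.pi * Z / (LAM * 1e-3)), abs=1e-12)

    def test_zero_distance_is_identity(self):
        P = transfer_function((16, 16), settings(z=0.0))
        np.testing.assert_allclose(P, np.ones((16, 16)), atol=1e-13)

    def test_matches_two_loop_evaluation(self):
        """Element-wise agreement with a direct nested-loop evaluation."""
        n = 8
        s = settings()
        P = transfer_function((n, n), s)
        lam = LAM * 1e-3
        freqs = np.fft.fftfreq(n, d=PITCH)
        for i in range(n):
            for j in range(n):
                rad = 1.0 - (lam * freqs[j]) ** 2 - (lam * freqs[i]) ** 2
                expect = np.exp(2j * np.pi * Z / lam * np.sqrt(rad)) if rad >= 0 else 0.0
                assert P[i, j] == pytest.approx(expect, abs=1e-12)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            PropagationSettings(wavelength_nm=-1.0, distance_um=Z, pitch_um=PITCH)
        with pytest.raises(ValueError):
            PropagationSettings(wavelength_nm=LAM, distance_um=Z, pitch_um=0.0)


class TestPropagate:
    def test_plane_wave_gains_global_phase(self):
        n = 32
        f = ComplexField(np.ones((n, n), dtype=complex), PITCH, LAM)
        out = propagate(f, settings())
        lam = LAM * 1e-3
        np.testing.assert_allclose(np.abs(out.values), 1.0, atol=1e-12)
        expected_phase = (2 * np.pi * Z / lam) % (2 * np.pi)
        np.testing.assert_allclose(out.phase, expected_phase, atol=1e-9)

    def test_forward_backward_round_trip(self):
        f = band_limited_field(32, seed=1)
        s = settings()
        back = propagate(propagate(f, s), s.reversed())
        assert np.max(np.abs(back.values - f.values)) < 1e-10

    def test_power_conservation(self):
        f = band_limited_field(32, seed=2)
        out = propagate(f, settings())
        assert out.power == pytest.approx(f.power, rel=1e-9)

    @pytest.mark.parametrize("z1,z2", [(100.0, 200.0), (250.0, -70.0)])
    def test_group_property(self, z1, z2):
        f = band_limited_field(32, seed=3)
        two_step = propagate(propagate(f, settings(z=z1)), settings(z=z2))
        one_step = propagate(f, settings(z=z1 + z2))
        assert np.max(np.abs(two_step.values - one_step.values)) < 1e-9

    def test_shape_and_metadata_mismatch_rejected(self):
        f = band_limited_field(16, seed=0)
        with pytest.raises(ValueError):
            propagate(f, PropagationSettings(LAM, Z, pitch_um=2.0))
        with pytest.raises(ValueError):
            propagate(f, PropagationSettings(wavelength_nm=600.0, distance_um=Z, pitch_um=PITCH))


class TestHologramIntensity:
    def test_free_space_gives_unit_intensity(self):
        n = 32
        obj = ObjectField(np.zeros((n, n)), np.ones((n, n)), PITCH)
        holo = hologram_intensity(obj, settings())
        np.testing.assert_allclose(holo.intensity, 1.0, atol=1e-10)

    def test_mean_intensity_preserved_for_band_limited_object(self):
        f = band_limited_field(32, seed=4)
        amp = 0.5 + 0.4 * np.real(f.values) / np.max(np.abs(np.real(f.values)))
        obj = ObjectField(np.zeros_like(amp), np.clip(amp, 0, 1), PITCH)
        holo = hologram_intensity(obj, settings())
        assert holo.intensity.mean() == pytest.approx(np.mean(obj.amplitude**2), rel=1e-6)


class TestBackpropagate:
    def test_free_space_hologram_recovers_unit_amplitude(self):
        n = 32
        holo = Hologram(np.ones((n, n)), settings())
        rec = backpropagate(holo, settings())
        np.testing.assert_allclose(rec.amplitude, 1.0, atol=1e-10)

    def test_is_exact_inverse_on_a_true_complex_field(self):
        f = band_limited_field(32, seed=5)
        fwd = propagate(f, settings())
        # backpropagate is propagate with the distance negated
        back = propagate(fwd, settings().reversed())
        assert np.max(np.abs(back.values - f.values)) < 1e-10

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            Hologram(-np.ones((8, 8)), settings())

    def test_intensity_round_trip_is_not_identity(self):
        """Detection discards phase: the twin image survives backpropagation."""
        n = 64
        phase = np.zeros((n, n))
        phase[28:36, 28:36] = 1.0
        obj = ObjectField(phase, np.ones((n, n)), PITCH)
        holo = hologram_intensity(obj, settings())
        rec = backpropagate(holo, settings())
        # a faithful inverse would restore unit amplitude; twin energy shows up
        twin_energy = float(np.sum((rec.amplitude - 1.0) ** 2))
        assert twin_energy > 1e-2


class TestDirectSummationOracles:
    """FFT-based propagation vs independent direct-summation diffraction."""

    def _oracle_field(self, source, kernel, z=Z):
        """Direct summation of the diffraction integral for a compact source."""
        n = source.shape[0]
        lam = LAM * 1e-3
        k = 2 * np.pi / lam
        coords = np.arange(n) * PITCH
        if kernel == "fresnel":
            pref = np.exp(1j * k * z) / (1j * lam * z) * PITCH**2
            chirp = np.exp(1j * k / (2 * z) * (coords[None, :] - coords[:, None]) ** 2)
            return pref * (chirp.T @ source @ chirp)
        # exact first Rayleigh-Sommerfeld solution
        pref = PITCH**2 / (2 * np.pi)
        out = np.zeros((n, n), dtype=complex)
        for iy in range(n):
            dy2 = (coords[iy] - coords) ** 2
            for ix in range(n):
                R = np.sqrt((coords[ix] - coords[None, :]) ** 2 + dy2[:, None] + z * z)
                kern = (z / R) * (1.0 / R - 1j * k) * np.exp(1j * k * R) / R
                out[iy, ix] = np.sum(source * kern)
        return pref * out

    def _as_hologram_of_unit_background_minus(self, perturbation):
        """|P(1 - D)|^2 via the padded angular spectrum route."""
        amp = np.clip(1.0 - np.real(perturbation), 0.0, 1.0)
        obj = ObjectField(np.zeros_like(amp), amp, PITCH)
        return hologram_intensity(obj, settings(pad_factor=2)).intensity

    def test_opaque_disc_matches_rayleigh_sommerfeld_summation(self):
        """Concentric fringes of a 6-px opaque disc vs the exact integral."""
        n = 128
        y, x = np.mgrid[0:n, 0:n]
        disc = ((y - n / 2) ** 2 + (x - n / 2) ** 2 <= 36).astype(float)
        H = self._as_hologram_of_unit_background_minus(disc)
        lam = LAM * 1e-3
        u_disc = self._oracle_field(disc.astype(complex), "rs")
        H_oracle = np.abs(np.exp(2j * np.pi * Z / lam) - u_disc) ** 2
        assert nrms(H, H_oracle) < 1e-2

    def test_smooth_object_matches_fresnel_summation(self):
        """Band-limited object: the paraxial kernel agrees too."""
        n = 128
        y, x = np.mgrid[0:n, 0:n]
        bump = np.exp(-(((y - n / 2) ** 2 + (x - n / 2) ** 2) / (2 * 3.0**2)))
        H = self._as_hologram_of_unit_background_minus(0.8 * bump)
        lam = LAM * 1e-3
        u = self._oracle_field(0.8 * bump.astype(complex), "fresnel")
        H_oracle = np.abs(np.exp(2j * np.pi * Z / lam) - u) ** 2
        assert nrms(H, H_oracle) < 1e-2


class TestInstrumentCharacteristics:
    def test_sensor_field_of_view(self):
        w, h = field_of_view((2480, 3296), 1.12)
        assert w == pytest.approx(3691.52)
        assert h == pytest.approx(2777.6)

    def test_temporal_coherence_length(self):
        assert coherence_length(532.3, 1.0) == pytest.approx(283.3, abs=0.05)

    def test_spatial_coherence_radius(self):
        assert coherence_radius(532.3, 10.0, 20.0) == pytest.approx(847.0, abs=0.5)
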