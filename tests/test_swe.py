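"""Shear wave elastography: displacement tracking and f-k estimation."""

import numpy as np
import pytest

from mpus import swe, synthetic
from mpus.swe import IQEnsemble
from mpus.synthetic import ShearGrid

SOUND_SPEED = 1540.0
DEMOD = 5e6


def _speckle(rng, n_axial=16, n_lateral=32):
    return (
        rng.normal(size=(n_axial, n_lateral)) + 1j * rng.normal(size=(n_axial, n_lateral))
    ) / np.sqrt(2)


def _shifted_ensemble(shift_m, n_frames=2, seed=0):
    """IQ ensemble whose frames carry a uniform axial displacement step."""
    rng = np.random.default_rng(seed)
    s0 = _speckle(rng)
    frames = [
        s0 * np.exp(1j * 4 * np.pi * DEMOD * k * shift_m / SOUND_SPEED)
        for k in range(n_frames)
    ]
    return IQEnsemble(np.stack(frames, axis=2), 20e6, DEMOD, 2000.0, 0.3)


class TestDisplacement:
    def test_identical_frames_give_zero(self):
        iq = _shifted_ensemble(0.0, n_frames=4)
        field = swe.estimate_displacement(iq)
        assert np.allclose(field.u, 0.0)
        assert not field.aliasing_warning

    def test_twentieth_wavelength_recovered_within_two_percent(self):
        lam = SOUND_SPEED / DEMOD
        shift = lam / 20
        field = swe.estimate_displacement(_shifted_ensemble(shift))
        recovered = field.u[:, :, 1].mean() * 1e-6
        assert recovered == pytest.approx(shift, rel=0.02)
        assert not field.aliasing_warning

    def test_quarter_wavelength_flags_aliasing(self):
        lam = SOUND_SPEED / DEMOD
        field = swe.estimate_displacement(_shifted_ensemble(lam / 4))
        assert field.aliasing_warning

    def test_input_validation(self):
        iq = _shifted_ensemble(0.0, n_frames=1)
        with pytest.raises(ValueError, match="2 slow-time frames"):
            swe.estimate_displacement(iq)
        with pytest.raises(ValueError, match="axial_kernel"):
            swe.estimate_displacement(_shifted_ensemble(0.0, n_frames=3), axial_kernel=2)


class TestFKTransform:
    @staticmethod
    def _plane_wave_field(k0, f0, n_x=64, n_t=64, dx_mm=0.3, dt=5e-4):
        x = np.arange(n_x) * dx_mm * 1e-3
        t = np.arange(n_t) * dt
        u = np.cos(k0 * x[:, None] - 2 * np.pi * f0 * t[None, :])
        return swe.DisplacementField(u=u[None], dx_mm=dx_mm, dt=dt)

    def test_real_sinusoid_has_conjugate_symmetric_peaks(self):
        dx, dt = 0.3e-3, 5e-4
        k0 = 2 * np.pi * 8 / (64 * dx)   # 8 cycles over the aperture
        f0 = 10 / (64 * dt)              # 10 cycles over the record
        spec = swe.fk_transform(self._plane_wave_field(k0, f0), 0)
        mag = spec.magnitude
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        # peak sits at (k0, -f0) or (-k0, f0); its mirror has equal magnitude
        mirror = mag[mag.shape[0] - i, mag.shape[1] - j]
        assert mirror == pytest.approx(mag[i, j], rel=1e-9)
        assert abs(abs(spec.k[i]) - k0) < 2 * np.pi / (64 * dx)
        assert abs(abs(spec.f[j]) - f0) < 1.0 / (64 * dt)

    def test_parseval(self):
        field = self._plane_wave_field(2000.0, 100.0)
        from scipy.signal.windows import tukey

        u = field.u[0] - field.u[0].mean()
        taper = np.outer(tukey(u.shape[0], 0.25), tukey(u.shape[1], 0.25))
        spec = swe.fk_transform(field, 0)
        field_energy = np.sum((u * taper) ** 2)
        spec_energy = np.sum(spec.magnitude**2) / u.size
        assert spec_energy == pytest.approx(field_energy, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        zero = swe.DisplacementField(u=np.zeros((1, 64, 64)), dx_mm=0.3, dt=5e-4)
        with pytest.raises(ValueError, match="all zero"):
            swe.fk_transform(zero, 0)
        tiny = swe.DisplacementField(u=np.ones((1, 4, 64)), dx_mm=0.3, dt=5e-4)
        with pytest.raises(ValueError, match="lateral"):
            swe.fk_transform(tiny, 0)


class TestSpeedAttenuation:
    def test_reference_liver_example_recovered(self):
        # control-liver-like setting: 1.52 m/s, 94.8 Np/m at 25 dB SNR
        iq, _ = synthetic.gen_shear_movie(1.52, 94.8, snr_db=25, seed=11)
        field = swe.estimate_displacement(iq)
        result = swe.shear_wave_analysis(field)
        assert result.speed == pytest.approx(1.52, rel=0.05)
        assert result.attenuation == pytest.approx(94.8, rel=0.10)
        assert result.r_squared > 0.9

    def test_halving_speed_doubles_wavenumber(self):
        grid = ShearGrid(n_lateral=240, n_frames=500)
        results = {}
        for speed in (2.0, 1.0):
            _, truth = synthetic.gen_shear_movie(
                speed, 100.0, grid=grid, snr_db=np.inf, seed=0
            )
            spec = swe.fk_transform(truth, 0)
            results[speed] = swe.estimate_speed_attenuation(spec)
        assert results[1.0].analysis_frequency == pytest.approx(
            results[2.0].analysis_frequency, rel=0.02
        )
        k1 = 2 * np.pi * results[1.0].analysis_frequency / results[1.0].speed
        k2 = 2 * np.pi * results[2.0].analysis_frequency / results[2.0].speed
        assert k1 == pytest.approx(2 * k2, rel=0.05)

    def test_amplitude_scale_invariance(self):
        _, truth = synthetic.gen_shear_movie(1.5, 100.0, snr_db=np.inf, seed=3)
        r1 = swe.estimate_speed_attenuation(swe.fk_transform(truth, 0))
        scaled = swe.DisplacementField(u=truth.u * 7.3, dx_mm=truth.dx_mm, dt=truth.dt)
        r2 = swe.estimate_speed_attenuation(swe.fk_transform(scaled, 0))
        assert r2.speed == pytest.approx(r1.speed, rel=1e-9)
        # attenuation involves an iterative fit; invariance holds to its
        # convergence tolerance
        assert r2.attenuation == pytest.approx(r1.attenuation, rel=1e-6)

    def test_undamped_wave_reports_resolution_floor(self):
        grid = ShearGrid(n_lateral=300, n_frames=520)
        _, truth = synthetic.gen_shear_movie(1.5, 0.0, grid=grid, snr_db=np.inf, seed=0)
        spec = swe.fk_transform(truth, 0)
        result = swe.estimate_speed_attenuation(spec)
        # anything below one wavenumber bin is unresolved aperture broadening
        one_bin = 2 * np.pi / (spec.n_lateral * spec.dx_m)
        assert 0.0 <= result.attenuation <= one_bin


class TestGenerator:
    def test_arrival_time_slope_matches_speed(self):
        speed = 1.52
        _, truth = synthetic.gen_shear_movie(speed, 94.8, snr_db=np.inf, seed=0)
        u = truth.u[0]
        arrived = np.abs(u) > 0
        first = np.argmax(arrived, axis=1).astype(float) * truth.dt
        x = np.arange(u.shape[0]) * truth.dx_mm * 1e-3
        slope = np.polyfit(x, first, 1)[0]
        assert slope == pytest.approx(1.0 / speed, rel=0.02)

    def test_envelope_decay_matches_attenuation(self):
        _, truth = synthetic.gen_shear_movie(1.5, 100.0, snr_db=np.inf, seed=0)
        u = truth.u[0]
        peak = np.abs(u).max(axis=1)
        x = np.arange(u.shape[0]) * truth.dx_mm * 1e-3
        # skip the trailing edge where the record may clip the last cycle
        n_fit = int(0.9 * x.size)
        slope = np.polyfit(x[:n_fit], np.log(peak[:n_fit]), 1)[0]
        assert slope == pytest.approx(-100.0, rel=0.01)

    def test_zero_attenuation_constant_envelope(self):
        # shear frequency incommensurate with the frame rate so the sampled
        # peak approaches the true envelope at every lateral position
        grid = ShearGrid(n_lateral=120, n_frames=600)
        _, truth = synthetic.gen_shear_movie(
            1.5, 0.0, shear_frequency=193.0, grid=grid, snr_db=np.inf, seed=0
        )
        peak = np.abs(truth.u[0]).max(axis=1)
        assert peak.min() == pytest.approx(peak.max(), rel=0.01)

    def test_iq_phase_demodulation_recovers_truth(self):
        iq, truth = synthetic.gen_shear_movie(1.5, 100.0, snr_db=np.inf, seed=5)
        # analytic demodulation against frame 0 (u = 0 there by construction)
        phase = np.angle(iq.data * np.conj(iq.data[:, :, :1]))
        u_rec = phase * SOUND_SPEED / (4 * np.pi * DEMOD) * 1e6
        assert np.allclose(u_rec[0], truth.u[0], atol=1e-6)

    def test_aliasing_amplitude_rejected(self):
        limit = 1e6 * SOUND_SPEED / (4 * DEMOD)
        with pytest.raises(ValueError, match="aliasing limit"):
            synthetic.gen_shear_movie(1.5, 100.0, amplitude_um=limit, seed=0)

    def test_grid_preconditions(self):
        with pytest.raises(ValueError, match="prf"):
            synthetic.gen_shear_movie(
                1.5, 100.0, shear_frequency=400.0,
                grid=ShearGrid(prf=2000.0, n_lateral=220, n_frames=300),
            )
        with pytest.raises(ValueError, match="lateral extent"):
            synthetic.gen_shear_movie(
                1.5, 20.0, grid=ShearGrid(n_lateral=100, n_frames=300)
            )
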