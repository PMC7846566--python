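"""Shear wave elastography: displacement tracking and f-k speed/attenuation.

An acoustic-radiation-force push launches a shear wave that propagates
laterally through the liver at a speed (SWS, m/s) set by tissue stiffness and
decays with an amplitude attenuation (SWA, Np/m) sensitive to viscosity and
fat content.  The processing implemented here follows the classical two-stage
chain:

1. ``estimate_displacement`` - axial tissue displacement from beamformed IQ
   ensembles via the phase of the lag-1 slow-time autocorrelation (Loupas-type
   estimator), cumulatively summed to displacement.
2. ``fk_transform`` / ``estimate_speed_attenuation`` - a 2-D Fourier transform
   of u(x, t) at a given depth; the dominant spectral ridge satisfies
   2*pi*f = k * c_s, so the wavenumber peak at the dominant temporal frequency
   gives the speed, while the Lorentzian half-width of the squared-magnitude
   wavenumber profile gives the attenuation (exact for an exponentially
   damped sinusoid, for which |U(k)|^2 ~ 1/((k - k0)^2 + alpha^2)).

The finite lateral aperture and taper broaden the wavenumber profile; the
taper's broadening is measured once on a synthetic undamped wave with the
same grid and removed in quadrature.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal.windows import tukey

from ._utils import check_finite

__all__ = [
    "IQEnsemble",
    "DisplacementField",
    "FKSpectrum",
    "ShearWaveResult",
    "estimate_displacement",
    "fk_transform",
    "estimate_speed_attenuation",
    "shear_wave_analysis",
]

TAPER_ALPHA = 0.25  # Tukey shape used in both f-k axes


@dataclass
class IQEnsemble:
    """Complex baseband ensemble, axial x lateral x slow-time."""

    data: np.ndarray             # complex
    axial_sampling: float        # Hz
    demod_frequency: float       # Hz
    prf: float                   # Hz, slow-time frame rate
    lateral_pitch_mm: float
    sound_speed: float = 1540.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3:
            raise ValueError("IQ data must be 3-D (axial x lateral x slow-time)")
        check_finite(self.data.view(float), "IQ data")


@dataclass
class DisplacementField:
    """Axial displacement movie u(z, x, t) in micrometers."""

    u: np.ndarray                # axial x lateral x slow-time, um
    dx_mm: float                 # lateral spacing
    dt: float                    # s, frame interval
    aliasing_warning: bool = False

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3:
            raise ValueError("displacement field must be 3-D")


@dataclass
class FKSpectrum:
    """Magnitude of the 2-D DFT of u(x, t) at one depth, physical axes."""

    magnitude: np.ndarray        # |U|, wavenumber x frequency
    k: np.ndarray                # rad/m, fftshifted
    f: np.ndarray                # Hz, fftshifted
    n_lateral: int = 0
    dx_m: float = 0.0


@dataclass
class ShearWaveResult:
    speed: float                 # m/s
    attenuation: float           # Np/m
    analysis_frequency: float    # Hz
    r_squared: float


def estimate_displacement(iq: IQEnsemble, axial_kernel: int = 8) -> DisplacementField:
    """Track axial displacement from IQ data (lag-1 autocorrelation phase).

    The frame-to-frame displacement at each pixel is
    d = c * angle(sum_z conj(s_t) s_{t+1}) / (4 pi f_demod), with the sum over
    an ``axial_kernel``-sample sliding window, and u is its cumulative sum
    over slow time (u = 0 at the first frame).  The estimate is unbiased for
    inter-frame shifts below one eighth of the demodulation wavelength; if
    any autocorrelation phase approaches +/-pi an aliasing warning is set on
    the returned field.
    """
    if axial_kernel < 4:
        raise ValueError("axial_kernel must be >= 4 samples")
    n_axial, _, n_t = iq.data.shape
    if n_t < 2:
        raise ValueError("need at least 2 slow-time frames")
    if n_axial < axial_kernel:
        raise ValueError("axial extent smaller than axial_kernel")
    r = np.conj(iq.data[:, :, :-1]) * iq.data[:, :, 1:]
    # sliding axial sum via cumulative sums
    csum = np.cumsum(r, axis=0)
    windowed = csum[axial_kernel - 1 :].copy()
    windowed[1:] -= csum[: n_axial - axial_kernel]
    phase = np.angle(windowed)
    aliasing = bool(np.max(np.abs(phase)) >= 0.95 * np.pi)
    d_m = iq.sound_speed * phase / (4.0 * np.pi * iq.demod_frequency)
    u_m = np.concatenate(
        [np.zeros_like(d_m[:, :, :1]), np.cumsum(d_m, axis=2)], axis=2
    )
    return DisplacementField(
        u=u_m * 1e6,
        dx_mm=iq.lateral_pitch_mm,
        dt=1.0 / iq.prf,
        aliasing_warning=aliasing,
    )


def fk_transform(field: DisplacementField, depth_row: int) -> FKSpectrum:
    """2-D DFT of the lateral x slow-time displacement at one depth row.

    The row is mean-removed and tapered with a separable Tukey(0.25) window
    before the transform; axes are returned in rad/m and Hz.  Parseval's
    identity between the tapered field and the spectrum holds to rounding.
    """
    u2 = field.u[depth_row]
    n_x, n_t = u2.shape
    if n_x < 8:
        raise ValueError("need at least 8 lateral samples")
    if n_t < 16:
        raise ValueError("need at least 16 slow-time samples")
    if not np.any(u2):
        raise ValueError("degenerate input: displacement field is all zero")
    u2 = u2 - u2.mean()
    taper = np.outer(tukey(n_x, TAPER_ALPHA), tukey(n_t, TAPER_ALPHA))
    spectrum = np.fft.fftshift(np.fft.fft2(u2 * taper))
    dx_m = field.dx_mm * 1e-3
    k = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(n_x, dx_m))
    f = np.fft.fftshift(np.fft.fftfreq(n_t, field.dt))
    return FKSpectrum(
        magnitude=np.abs(spectrum), k=k, f=f, n_lateral=n_x, dx_m=dx_m
    )


def _lorentzian(k: np.ndarray, amplitude: float, k0: float, gamma: float) -> np.ndarray:
    return amplitude / ((k - k0) ** 2 + gamma**2)


def _fit_lorentzian(
    k: np.ndarray, power: np.ndarray, i_peak: int
) -> tuple[float, float, float]:
    """Least-squares Lorentzian fit around a wavenumber power peak.

    Returns (k0, gamma, r_squared).  The fit window is the contiguous run of
    samples around the peak above 1% of the peak power (at least 7 samples).
    """
    n = power.size
    thresh = power[i_peak] / 100.0
    lo = i_peak
    while lo > 0 and power[lo - 1] > thresh:
        lo -= 1
    hi = i_peak
    while hi < n - 1 and power[hi + 1] > thresh:
        hi += 1
    lo = min(lo, max(i_peak - 3, 0))
    hi = max(hi, min(i_peak + 3, n - 1))
    kw, pw = k[lo : hi + 1], power[lo : hi + 1]

    dk = abs(k[1] - k[0])
    # initial half-width from the half-maximum crossings
    above = pw >= power[i_peak] / 2.0
    gamma0 = max(dk * (np.count_nonzero(above)) / 2.0, dk / 4.0)
    p0 = (power[i_peak] * gamma0**2, k[i_peak], gamma0)
    try:
        popt, _ = curve_fit(
            _lorentzian,
            kw,
            pw,
            p0=p0,
            bounds=([0.0, kw.min(), dk / 100.0], [np.inf, kw.max(), np.inf]),
            maxfev=5000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        resid = float(np.sum((pw - _lorentzian(kw, *p0)) ** 2))
        raise RuntimeError(
            f"Lorentzian fit did not converge (initial residual {resid:.3g})"
        ) from exc
    model = _lorentzian(kw, *popt)
    ss_res = float(np.sum((pw - model) ** 2))
    ss_tot = float(np.sum((pw - pw.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(popt[1]), float(abs(popt[2])), float(np.clip(r2, 0.0, 1.0))


@functools.lru_cache(maxsize=32)
def _taper_k_hwhm(n_lateral: int, n_slow: int, dx_um: int) -> float:
    """Effective wavenumber broadening of the taper/aperture, as seen by the
    Lorentzian fit.

    Measured once per grid by pushing an undamped plane wave (wavenumber at a
    worst-case half-bin offset) through the identical transform-and-fit path
    used on data; cached per (aperture, record length, pitch).
    """
    dx_m = dx_um * 1e-6
    x = np.arange(n_lateral) * dx_m
    t = np.arange(n_slow)
    dk = 2.0 * np.pi / (n_lateral * dx_m)
    k0 = (n_lateral // 4 + 0.5) * dk
    f0_cycles = max(n_slow // 8, 1)
    u = np.sin(2.0 * np.pi * f0_cycles * t[None, :] / n_slow - k0 * x[:, None])
    field = DisplacementField(u=u[None], dx_mm=dx_m * 1e3, dt=1.0)
    spectrum = fk_transform(field, 0)
    pos = spectrum.f > 0
    mag = spectrum.magnitude[:, pos]
    i_k, i_f = np.unravel_index(int(np.argmax(mag)), mag.shape)
    _, gamma, _ = _fit_lorentzian(spectrum.k, mag[:, i_f] ** 2, i_k)
    return gamma


def _parabolic_refine(k: np.ndarray, power: np.ndarray, i: int) -> float:
    """Sub-bin peak location via a 3-point parabola on log power."""
    if i == 0 or i == power.size - 1:
        return float(k[i])
    y0, y1, y2 = np.log(power[i - 1 : i + 2])
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(k[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(k[i] + delta * (k[1] - k[0]))


def estimate_speed_attenuation(spectrum: FKSpectrum) -> ShearWaveResult:
    """Shear wave speed and attenuation from an f-k magnitude spectrum.

    The analysis frequency f* is the temporal frequency of the global maximum
    on the positive-frequency half-plane; the speed is 2*pi*f* / |k_peak|
    with the wavenumber peak refined by parabolic interpolation.  The
    attenuation is the half-width at half-maximum of a Lorentzian fitted to
    the squared-magnitude wavenumber profile at f*, after removing the
    taper's broadening in quadrature.
    """
    pos = spectrum.f > 0
    if not pos.any():
        raise ValueError("spectrum has no positive-frequency content")
    mag = spectrum.magnitude[:, pos]
    f_pos = spectrum.f[pos]
    i_k, i_f = np.unravel_index(int(np.argmax(mag)), mag.shape)
    if i_k in (0, mag.shape[0] - 1):
        raise ValueError("unresolved wave: wavenumber peak at spectrum edge")
    f_star = float(f_pos[i_f])
    power = mag[:, i_f] ** 2
    k_peak = _parabolic_refine(spectrum.k, power, i_k)
    if k_peak == 0.0:
        raise ValueError("unresolved wave: zero wavenumber peak")
    speed = 2.0 * np.pi * f_star / abs(k_peak)

    k0_fit, gamma_fit, r2 = _fit_lorentzian(spectrum.k, power, i_k)
    gamma_taper = _taper_k_hwhm(
        spectrum.n_lateral, spectrum.magnitude.shape[1], int(round(spectrum.dx_m * 1e6))
    )
    attenuation = float(np.sqrt(max(gamma_fit**2 - gamma_taper**2, 0.0)))
    return ShearWaveResult(
        speed=float(speed),
        attenuation=attenuation,
        analysis_frequency=f_star,
        r_squared=r2,
    )


def shear_wave_analysis(
    field: DisplacementField, depth_rows: list[int] | None = None
) -> ShearWaveResult:
    """Median speed/attenuation over a band of depth rows (default: 5 central).

    A single push produces comparable waves over a depth band around the push
    focus; the per-row estimates are aggregated with the median for
    robustness to occasional poor rows.
    """
    n_axial = field.u.shape[0]
    if depth_rows is None:
        mid = n_axial // 2
        depth_rows = [r for r in range(mid - 2, mid + 3) if 0 <= r < n_axial]
    results = [
        estimate_speed_attenuation(fk_transform(field, r)) for r in depth_rows
    ]
    return ShearWaveResult(
        speed=float(np.median([r.speed for r in results])),
        attenuation=float(np.median([r.attenuation for r in results])),
        analysis_frequency=float(np.median([r.analysis_frequency for r in results])),
        r_squared=float(np.median([r.r_squared for r in results])),
    )
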