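"""H-scan ultrasound reconstruction.

H-scan tissue characterization matches backscattered radiofrequency (RF)
echoes against Gaussian-weighted Hermite (GH) functions of different order.
Low-order kernels (GH2) peak at lower frequencies and respond to echoes from
relatively large scattering structures; high-order kernels (GH8) peak higher
and respond to echoes from small, sub-wavelength scatterer aggregates.  The
two matched-filter envelopes are assigned to red (R, GH2) and blue (B, GH8)
channels and the per-pixel ratio B/(R+B) colorizes relative scatterer size:
values above 0.5 indicate spectral content above the pulse center (smaller
scatterers, "bluer"), values below 0.5 the opposite.

The processing chain implemented here: depth-gain attenuation correction of
the RF frame, parallel convolution with GH2 and GH8 kernels, normalization of
each branch by the kernel signal energy sqrt(E_n), zero-phase bandpass
filtering (default 5-18 MHz), Hilbert envelope detection, and ROI averaging
of both the B-scan envelope and the B/(R+B) intensity map.  The B-scan image
is the envelope of the original, unfiltered RF.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, fftconvolve, hilbert, sosfiltfilt
from scipy.special import eval_hermite

from ._utils import check_finite

__all__ = [
    "RFFrame",
    "GHKernel",
    "HScanImage",
    "attenuation_correct",
    "make_gh_kernel",
    "gh_time_scale_for_center",
    "hscan_reconstruct",
    "roi_metrics",
]

SOUND_SPEED_TISSUE = 1540.0  # m/s, soft-tissue convention


@dataclass
class RFFrame:
    """Beamformed RF echo frame, axial (rows) x lateral (columns).

    ``depth_step_cm`` is the depth increment per axial sample (sample 0 sits
    at depth 0); for pulse-echo data it is sound_speed / (2 * sampling_rate).
    """

    samples: np.ndarray          # real, axial x lateral, a.u.
    sampling_rate: float         # Hz
    center_frequency: float      # Hz
    line_pitch_mm: float = 0.1
    sound_speed: float = SOUND_SPEED_TISSUE
    attenuation_corrected: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("RF samples must be 2-D (axial x lateral)")
        check_finite(self.samples, "RF samples")
        if self.sampling_rate <= 0 or self.center_frequency <= 0:
            raise ValueError("sampling_rate and center_frequency must be positive")

    @property
    def depth_step_cm(self) -> float:
        return 100.0 * self.sound_speed / (2.0 * self.sampling_rate)

    @property
    def depths_cm(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) * self.depth_step_cm


@dataclass
class GHKernel:
    """Sampled Gaussian-weighted Hermite function GH_n(t/sigma).

    GH_n(t) = H_n(t/sigma) * exp(-t^2 / (2 sigma^2)) with H_n the physicists'
    Hermite polynomial.  ``energy`` is E_n = integral of GH_n^2 dt; matched
    filter outputs are normalized by sqrt(E_n) so that different orders are
    comparable.  ``peak_frequency`` grows with order at fixed time scale.
    """

    order: int
    time_scale: float            # sigma, s
    sampling_rate: float         # Hz
    taps: np.ndarray = field(repr=False)
    energy: float = 0.0
    peak_frequency: float = 0.0


@dataclass
class HScanImage:
    """Co-registered B-scan envelope, R/B channel envelopes and B/(R+B) map.

    ``valid_mask`` is False where edge effects (within one kernel half-length
    of the frame top/bottom) or a vanishing R+B denominator make the
    intensity map undefined.
    """

    bscan_envelope: np.ndarray
    red_channel: np.ndarray
    blue_channel: np.ndarray
    intensity_map: np.ndarray
    valid_mask: np.ndarray


def attenuation_correct(frame: RFFrame, coeff: float) -> RFFrame:
    """Apply bulk depth-gain compensation of ``coeff`` dB/cm/MHz.

    Each sample at depth z is multiplied by 10^(coeff * f_c[MHz] * 2z[cm]/20),
    i.e. the two-way amplitude attenuation at the transmit center frequency is
    undone with a single global scaling coefficient (0.3 dB/cm/MHz in the
    liver protocol this package models).
    """
    if coeff < 0:
        raise ValueError("attenuation coefficient must be >= 0")
    if frame.attenuation_corrected:
        raise ValueError("frame is already attenuation-corrected")
    fc_mhz = frame.center_frequency / 1e6
    gain_db = coeff * fc_mhz * 2.0 * frame.depths_cm
    gain = 10.0 ** (gain_db / 20.0)
    corrected = frame.samples * gain[:, None]
    return replace(frame, samples=corrected, attenuation_corrected=True)


def _gh_taps(order: int, time_scale: float, sampling_rate: float) -> np.ndarray:
    half = int(np.ceil(6.0 * time_scale * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    return eval_hermite(order, t / time_scale) * np.exp(-(t**2) / (2.0 * time_scale**2))


def make_gh_kernel(order: int, time_scale: float, sampling_rate: float) -> GHKernel:
    """Build a GH_n matched-filter kernel sampled at ``sampling_rate``.

    Tap support is +/- 6 sigma.  Rejects under-resolved kernels
    (sampling_rate < 4x the kernel's spectral peak).
    """
    if not (0 <= int(order) <= 12) or order != int(order):
        raise ValueError("order must be an integer in 0..12")
    order = int(order)
    if time_scale <= 0 or sampling_rate <= 0:
        raise ValueError("time_scale and sampling_rate must be positive")
    taps = _gh_taps(order, time_scale, sampling_rate)
    dt = 1.0 / sampling_rate
    energy = float(np.sum(taps**2) * dt)
    # spectral peak on a finely zero-padded grid
    nfft = 16 * 2 ** int(np.ceil(np.log2(taps.size)))
    spec = np.abs(np.fft.rfft(taps, nfft))
    freqs = np.fft.rfftfreq(nfft, dt)
    peak_frequency = float(freqs[int(np.argmax(spec))])
    if order > 0 and sampling_rate < 4.0 * peak_frequency:
        raise ValueError(
            f"under-resolved kernel: sampling_rate {sampling_rate:.3g} Hz < "
            f"4 x peak frequency {peak_frequency:.3g} Hz"
        )
    return GHKernel(
        order=order,
        time_scale=time_scale,
        sampling_rate=sampling_rate,
        taps=taps,
        energy=energy,
        peak_frequency=peak_frequency,
    )


def gh_time_scale_for_center(
    center_frequency: float,
    low_order: int = 2,
    high_order: int = 8,
    sampling_rate: float | None = None,
) -> float:
    """Shared kernel time scale placing the two GH spectral peaks around f_c.

    The GH_n spectral peak scales as 1/sigma, so a single sigma is chosen such
    that the geometric mean of the GH_low and GH_high peak frequencies equals
    the transducer center frequency.
    """
    if center_frequency <= 0:
        raise ValueError("center_frequency must be positive")
    # peak frequencies at sigma = 1 s, measured once on a fine grid
    peaks = []
    for order in (low_order, high_order):
        taps = _gh_taps(order, 1.0, 64.0)
        nfft = 1 << 18
        spec = np.abs(np.fft.rfft(taps, nfft))
        freqs = np.fft.rfftfreq(nfft, 1.0 / 64.0)
        peaks.append(freqs[int(np.argmax(spec))])
    geomean_at_unit_sigma = float(np.sqrt(peaks[0] * peaks[1]))
    return geomean_at_unit_sigma / center_frequency


def _bandpass_sos(band: tuple[float, float], sampling_rate: float):
    low, high = band
    nyq = sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist ({nyq:.3g})")
    return butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")


def hscan_reconstruct(
    frame: RFFrame,
    low_kernel: GHKernel,
    high_kernel: GHKernel,
    band: tuple[float, float] = (5e6, 18e6),
) -> HScanImage:
    """Reconstruct the B-scan and H-scan channel images from an RF frame.

    Per RF line: convolve with each GH kernel, divide by sqrt(E_n), zero-phase
    bandpass to ``band``, and take the Hilbert envelope; the GH2 branch is the
    red channel, the GH8 branch the blue channel.  The B-scan envelope comes
    from the original unfiltered RF.  intensity_map = B / (R + B).
    """
    if not frame.attenuation_corrected:
        raise ValueError(
            "frame must be attenuation-corrected first (attenuation_correct; "
            "use coeff=0 for data that needs no compensation)"
        )
    if low_kernel.order == high_kernel.order:
        raise ValueError("low and high kernels must have different orders")
    if low_kernel.order > high_kernel.order:
        low_kernel, high_kernel = high_kernel, low_kernel
    sos = _bandpass_sos(band, frame.sampling_rate)
    rf = frame.samples

    channels = []
    for kernel in (low_kernel, high_kernel):
        out = fftconvolve(rf, kernel.taps[:, None], mode="same")
        out /= np.sqrt(kernel.energy)
        out = sosfiltfilt(sos, out, axis=0)
        channels.append(np.abs(hilbert(out, axis=0)))
    red, blue = channels

    bscan = np.abs(hilbert(rf, axis=0))

    denom = red + blue
    # pixels with negligible channel energy (40 dB below the frame maximum)
    # carry no spectral information and are flagged undefined
    defined = denom > 1e-2 * max(float(denom.max()), 1e-300)
    intensity = np.full_like(denom, np.nan)
    np.divide(blue, denom, out=intensity, where=defined)

    valid = defined.copy()
    half = max(low_kernel.taps.size, high_kernel.taps.size) // 2
    edge = min(half, rf.shape[0])
    valid[:edge, :] = False
    if edge > 0:
        valid[-edge:, :] = False
    return HScanImage(
        bscan_envelope=bscan,
        red_channel=red,
        blue_channel=blue,
        intensity_map=intensity,
        valid_mask=valid,
    )


def roi_metrics(
    image: HScanImage, roi: tuple[int, int, int, int]
) -> tuple[float, float]:
    """Mean B-scan envelope and mean B/(R+B) intensity over a rectangular ROI.

    ``roi`` is (col0, row0, col1, row1) in image pixels with exclusive upper
    bounds (lateral = columns, axial = rows).  The intensity mean is taken
    over ROI pixels where the map is defined and unaffected by edge effects.
    """
    col0, row0, col1, row1 = roi
    n_rows, n_cols = image.bscan_envelope.shape
    if not (0 <= col0 < col1 <= n_cols and 0 <= row0 < row1 <= n_rows):
        raise ValueError(f"ROI {roi} outside image bounds {(n_cols, n_rows)}")
    if (col1 - col0) * (row1 - row0) < 100:
        raise ValueError("ROI area must be at least 100 pixels")
    sl = (slice(row0, row1), slice(col0, col1))
    bscan_intensity = float(np.mean(image.bscan_envelope[sl]))
    valid = image.valid_mask[sl]
    if not valid.any():
        raise ValueError("ROI contains no defined H-scan intensity pixels")
    hscan_intensity = float(np.mean(image.intensity_map[sl][valid]))
    return bscan_intensity, hscan_intensity
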