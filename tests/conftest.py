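import numpy as np
import pytest

from mpus import hscan
from mpus.synthetic import PulseSpec

SAMPLING = 100e6


@pytest.fixture(scope="session")
def pulse():
    return PulseSpec()


@pytest.fixture(scope="session")
def gh_pair():
    """GH2/GH8 kernel pair tuned so the spectral-peak geometric mean is 15 MHz."""
    sigma = hscan.gh_time_scale_for_center(15e6)
    low = hscan.make_gh_kernel(2, sigma, SAMPLING)
    high = hscan.make_gh_kernel(8, sigma, SAMPLING)
    return low, high


def single_echo_frame(echo_frequency, pulse, n=4096, n_lines=8):
    """RF frame with one Gaussian-enveloped echo per line at the frame center."""
    t = np.arange(n) / pulse.sampling_rate
    t0 = t[n // 2]
    st = pulse.envelope_sigma_s
    line = np.exp(-((t - t0) ** 2) / (2 * st**2)) * np.cos(
        2 * np.pi * echo_frequency * (t - t0)
    )
    return hscan.RFFrame(
        np.tile(line[:, None], (1, n_lines)),
        pulse.sampling_rate,
        pulse.center_frequency,
        attenuation_corrected=True,
    )


def binned_log_power_slope(frame, z_lo=0.3, z_hi=1.7, n_bins=14):
    """Depth slope (dB/cm) of the mean envelope power, averaged in depth bins."""
    from scipy.signal import hilbert

    env2 = (np.abs(hilbert(frame.samples, axis=0)) ** 2).mean(axis=1)
    z = frame.depths_cm
    bins = np.linspace(z_lo, z_hi, n_bins + 1)
    idx = np.digitize(z, bins)
    zb, pb = [], []
    for b in range(1, n_bins + 1):
        sel = idx == b
        if sel.any():
            zb.append(z[sel].mean())
            pb.append(env2[sel].mean())
    return float(np.polyfit(zb, 10 * np.log10(pb), 1)[0])
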