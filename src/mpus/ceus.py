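"""Contrast-enhanced ultrasound perfusion analysis.

After a bolus injection of a microbubble contrast agent, the image intensity
in a region of interest (ROI) rises during wash-in and decays during
wash-out.  The first-pass bolus is modelled with the standard lognormal
time-intensity curve

    I(t) = A * exp(-(ln(t - t0) - mu)^2 / (2 sigma^2)) / (t - t0),  t > t0,

whose peak and maximum wash-in slope have closed forms (derived below), so
that the two perfusion surrogates used here - peak enhancement (PE, blood
volume surrogate) and wash-in rate (WIR, flow surrogate) - are exact model
functionals rather than sample statistics.  Liver-parenchyma values are
normalized by the inferior vena cava (IVC) values (PE-nLP, WIR-nLP), which
cancels system gain and injected dose.

Closed forms used throughout (tau = t - t0, y = (ln tau - mu)/sigma^2):
  * peak at y = -1, i.e. tau_pk = exp(mu - sigma^2), peak value
    A * exp(sigma^2/2 - mu);
  * the rising inflection solves (1+y)^2 + (1+y) - 1/sigma^2 = 0 with the
    negative root 1 + y = -q, q = (1 + sqrt(1 + 4/sigma^2)) / 2, giving the
    maximum wash-in slope A * q * exp(-sigma^2 (q+1)^2 / 2) / tau_*^2 at
    tau_* = exp(mu - sigma^2 (q+1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._utils import check_finite

__all__ = [
    "CEUSSeries",
    "TIC",
    "PerfusionParams",
    "lognormal_bolus",
    "bolus_peak",
    "bolus_max_washin_slope",
    "bolus_params_for",
    "extract_tic",
    "fit_tic",
    "normalize_perfusion",
    "max_intensity_projection",
]

BASELINE_WINDOW_S = 1.0   # pre-injection window for baseline statistics
ARRIVAL_N_SD = 3.0        # bolus arrival threshold: baseline mean + 3 SD


@dataclass
class CEUSSeries:
    """Contrast-mode frame stack (rows x cols x time) with named ROI masks."""

    frames: np.ndarray
    frame_times: np.ndarray     # s, strictly increasing
    rois: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (rows x cols x time)")
        if self.frame_times.size != self.frames.shape[2]:
            raise ValueError("frame_times length must match the time axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        check_finite(self.frames, "frames")
        for name, mask in self.rois.items():
            if mask.shape != self.frames.shape[:2]:
                raise ValueError(f"ROI '{name}' shape does not match frames")


@dataclass
class TIC:
    """Baseline-subtracted ROI mean-intensity time course."""

    times: np.ndarray
    intensities: np.ndarray
    roi_name: str
    baseline: float
    arrival_index: int = 0


@dataclass
class PerfusionParams:
    pe: float                    # a.u., baseline-subtracted peak enhancement
    wir: float                   # a.u./s, maximum wash-in slope
    t_peak: float                # s
    fit_rmse: float
    roi_name: str = ""
    pe_nlp: float | None = None  # liver PE / IVC PE
    wir_nlp: float | None = None
    fallback: bool = False       # model-free estimates used


# ---------------------------------------------------------------------------
# lognormal bolus model
# ---------------------------------------------------------------------------

def lognormal_bolus(
    t: np.ndarray, t0: float, mu: float, sigma: float, amplitude: float
) -> np.ndarray:
    """Evaluate the lognormal bolus curve; zero at and before ``t0``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    tau = t - t0
    pos = tau > 0
    lt = np.log(tau[pos])
    out[pos] = amplitude * np.exp(-((lt - mu) ** 2) / (2.0 * sigma**2)) / tau[pos]
    return out


def bolus_peak(mu: float, sigma: float) -> tuple[float, float]:
    """(tau_peak, peak value per unit amplitude) of the lognormal bolus."""
    tau_pk = np.exp(mu - sigma**2)
    return float(tau_pk), float(np.exp(sigma**2 / 2.0 - mu))


def bolus_max_washin_slope(mu: float, sigma: float) -> tuple[float, float]:
    """(tau at the rising inflection, max slope per unit amplitude)."""
    q = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 / sigma**2))
    tau_star = np.exp(mu - sigma**2 * (q + 1.0))
    slope = q * np.exp(-(sigma**2) * (q + 1.0) ** 2 / 2.0) / tau_star**2
    # equivalently: slope = g(tau*) * q / tau*
    return float(tau_star), float(slope)


def bolus_params_for(pe: float, wir: float, sigma: float) -> tuple[float, float]:
    """(mu, amplitude) giving exactly peak ``pe`` and max wash-in slope ``wir``.

    Both PE and WIR scale linearly with amplitude, and WIR/PE scales as
    exp(-mu); the pair is therefore uniquely solvable for a fixed shape
    parameter sigma.
    """
    if pe <= 0 or wir <= 0:
        raise ValueError("PE and WIR must be positive")
    _, slope_unit_mu0 = bolus_max_washin_slope(0.0, sigma)
    # slope per unit A at general mu is slope_unit_mu0 * exp(-2 mu)
    # peak per unit A is exp(sigma^2/2 - mu)
    # => WIR/PE = slope_unit_mu0 * exp(-mu - sigma^2/2)
    mu = float(np.log(slope_unit_mu0 * pe / wir) - sigma**2 / 2.0)
    amplitude = float(pe / np.exp(sigma**2 / 2.0 - mu))
    return mu, amplitude


# ---------------------------------------------------------------------------
# TIC extraction and fitting
# ---------------------------------------------------------------------------

def _arrival_index(times: np.ndarray, intensities: np.ndarray) -> tuple[int, float]:
    window = times <= times[0] + BASELINE_WINDOW_S
    if not window.any():
        raise ValueError("no pre-arrival frames for baseline estimation")
    base = intensities[window]
    mu, sd = float(base.mean()), float(base.std())
    thresh = mu + ARRIVAL_N_SD * max(sd, 1e-12)
    above = np.nonzero(intensities > thresh)[0]
    if above.size == 0:
        # no enhancement detected; treat the whole record as baseline
        return intensities.size, mu
    idx = int(above[0])
    if idx == 0:
        raise ValueError("no pre-arrival frames: enhancement starts at frame 0")
    return idx, float(intensities[:idx].mean())


def extract_tic(series: CEUSSeries, roi_name: str) -> TIC:
    """Mean intensity under a named ROI mask vs time, baseline-subtracted.

    Bolus arrival is the first frame whose ROI mean exceeds the mean of a
    1 s pre-injection window by 3 SD; the baseline is the mean over all
    pre-arrival frames.
    """
    if roi_name not in series.rois:
        raise KeyError(
            f"ROI '{roi_name}' not found; available: {sorted(series.rois)}"
        )
    mask = series.rois[roi_name].astype(bool)
    if not mask.any():
        raise ValueError(f"ROI '{roi_name}' is empty")
    trace = series.frames[mask].mean(axis=0)
    arrival, baseline = _arrival_index(series.frame_times, trace)
    return TIC(
        times=series.frame_times.copy(),
        intensities=trace - baseline,
        roi_name=roi_name,
        baseline=baseline,
        arrival_index=min(arrival, trace.size - 1),
    )


def _smooth(y: np.ndarray, window: int = 5) -> np.ndarray:
    window = min(window | 1, y.size if y.size % 2 else y.size - 1)
    if window < 3:
        return y
    kernel = np.ones(window) / window
    pad = np.pad(y, window // 2, mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def fit_tic(tic: TIC, sigma0: float = 0.4) -> PerfusionParams:
    """Fit the lognormal bolus to the wash-in phase and derive PE and WIR.

    Only samples from bolus arrival through the first post-peak sample are
    fitted (wash-in restriction, which suppresses recirculation).  PE is the
    fitted curve's analytic maximum, WIR the analytic maximum of its first
    derivative on the wash-in interval.  If the fit fails to converge, leaves
    a relative RMSE above 15%, or the record never washes out after its
    maximum (a plateau is outside the first-pass bolus regime), model-free
    estimates are substituted (max of the smoothed curve, max
    finite-difference slope) and flagged.
    """
    t, y = tic.times, tic.intensities
    i0 = tic.arrival_index
    smoothed = _smooth(y)
    # peak located on a heavily smoothed curve (~1 s window): noise on the
    # flat top must not truncate the wash-in window before the true peak
    dt_frame = float(np.median(np.diff(t)))
    peak_window = max(5, int(round(1.0 / dt_frame)))
    i_peak = int(np.argmax(_smooth(y, peak_window)))
    if i_peak >= y.size - 1:
        raise ValueError("monotone curve: no peak inside the record")
    if i_peak - i0 < 4 or np.count_nonzero(y[i0 : i_peak + 1] > 0) < 5:
        raise ValueError("wash-in too short: need a rise of >= 5 samples")
    hi = min(i_peak + 2, y.size)  # through the first post-peak sample
    tw, yw = t[i0:hi], y[i0:hi]

    fallback = False
    pe = wir = t_peak = rmse = np.nan
    try:
        t_arr = t[max(i0 - 1, 0)]
        peak_amp = float(smoothed[i_peak])
        mu0 = float(np.log(max(t[i_peak] - t_arr, 2 * (t[1] - t[0]))) + sigma0**2)
        a0 = peak_amp / np.exp(sigma0**2 / 2.0 - mu0)
        span = t[-1] - t[0]
        # the bolus onset cannot precede the start of the record
        popt, _ = curve_fit(
            lognormal_bolus,
            tw,
            yw,
            p0=(max(t_arr - 0.01 * span, t[0] + 0.01 * span), mu0, sigma0, a0),
            bounds=(
                [t[0], -10.0, 0.02, 0.0],
                [tw[-1], 10.0, 3.0, np.inf],
            ),
            maxfev=10000,
        )
        t0_f, mu_f, sigma_f, a_f = popt
        tau_pk, peak_unit = bolus_peak(mu_f, sigma_f)
        _, slope_unit = bolus_max_washin_slope(mu_f, sigma_f)
        pe = a_f * peak_unit
        wir = a_f * slope_unit
        t_peak = t0_f + tau_pk
        rmse = float(np.sqrt(np.mean((lognormal_bolus(tw, *popt) - yw) ** 2)))
        # a record that never washes out after its maximum (plateau rather
        # than first-pass bolus) is outside the model's regime
        no_washout = float(smoothed[i_peak:].min()) >= 0.9 * float(smoothed[i_peak])
        if no_washout or rmse > 0.15 * max(pe, 1e-12):
            fallback = True
    except RuntimeError:
        fallback = True

    if fallback:
        pe = float(np.max(smoothed))
        sl = slice(max(i0 - 1, 0), i_peak + 1)
        slopes = np.diff(smoothed[sl]) / np.diff(t[sl])
        wir = float(np.max(slopes)) if slopes.size else 0.0
        t_peak = float(t[i_peak])
        rmse = float("nan")
    return PerfusionParams(
        pe=float(max(pe, 0.0)),
        wir=float(max(wir, 0.0)),
        t_peak=float(t_peak),
        fit_rmse=rmse,
        roi_name=tic.roi_name,
        fallback=fallback,
    )


def normalize_perfusion(
    liver: PerfusionParams, ivc: PerfusionParams
) -> PerfusionParams:
    """Normalize liver PE/WIR by the IVC reference (PE-nLP, WIR-nLP)."""
    if not (ivc.pe > 0 and ivc.wir > 0):
        raise ValueError("invalid IVC reference: PE and WIR must be positive")
    out = PerfusionParams(**vars(liver))
    out.pe_nlp = liver.pe / ivc.pe
    out.wir_nlp = liver.wir / ivc.wir
    return out


def max_intensity_projection(series: CEUSSeries) -> np.ndarray:
    """Per-pixel maximum over time of baseline-subtracted frames.

    The per-pixel baseline is the mean over the pre-injection window (first
    second of the record).
    """
    if series.frames.shape[2] < 2:
        raise ValueError("need at least 2 frames")
    window = series.frame_times <= series.frame_times[0] + BASELINE_WINDOW_S
    baseline = series.frames[:, :, window].mean(axis=2)
    return (series.frames - baseline[:, :, None]).max(axis=2)
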