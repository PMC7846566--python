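"""Synthetic generators for every pipeline input, with known ground truth.

The in vivo study this package models (control vs MCD-diet rats imaged at 0,
2 and 6 weeks) deposited no raw data, so each measurement stage is validated
by parameter recovery on synthetic inputs instead:

* ``gen_rf_phantom`` - RF speckle frames whose per-region echo spectral
  content and depth attenuation are controlled (H-scan oracle).
* ``gen_shear_movie`` - IQ ensembles carrying an exponentially damped,
  laterally propagating shear wave with exact speed/attenuation truth.
* ``gen_ceus_series`` - contrast frame stacks whose ROI time-intensity
  curves are lognormal boluses with analytically exact PE and WIR.
* ``gen_histology`` - H&E-like images of pink parenchyma with non-overlapping
  white fat vacuoles at a known area fraction.
* ``gen_feature_table`` - per-subject six-feature tables drawn from Gaussian
  cohort distributions (normal / low-fat / high-fat).

Every generator is deterministic for a fixed seed and returns (or attaches)
its ground truth, so no estimator output is ever its own reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.draw import ellipse as draw_ellipse

from .ceus import CEUSSeries, bolus_params_for, bolus_peak, lognormal_bolus
from .histology import HistologyImage
from .hscan import RFFrame
from .swe import DisplacementField, IQEnsemble

__all__ = [
    "PulseSpec",
    "ScattererRegionSpec",
    "CohortSpec",
    "ShearGrid",
    "default_shear_grid",
    "gen_rf_phantom",
    "gen_shear_movie",
    "gen_ceus_series",
    "gen_histology",
    "gen_feature_table",
    "FEATURE_COLUMNS",
    "default_cohorts",
    "effect_size_cohorts",
]

FEATURE_COLUMNS = ["sws", "swa", "bscan", "hscan", "pe_nlp", "wir_nlp"]
_HSCAN_IDX = FEATURE_COLUMNS.index("hscan")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSpec:
    """Transmit pulse: Gaussian envelope, -6 dB fractional bandwidth."""

    center_frequency: float = 15e6       # Hz
    fractional_bandwidth: float = 0.6    # -6 dB, dimensionless
    sampling_rate: float = 100e6         # Hz

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional_bandwidth must be in (0, 2)")
        if self.sampling_rate < 4 * self.center_frequency:
            raise ValueError("sampling_rate must be >= 4 x center_frequency")

    @property
    def envelope_sigma_s(self) -> float:
        # -6 dB (half-amplitude) full width of a Gaussian spectrum:
        # 2 * sigma_f * sqrt(2 ln 2) = fbw * fc
        sigma_f = self.fractional_bandwidth * self.center_frequency / (
            2.0 * np.sqrt(2.0 * np.log(2.0))
        )
        return 1.0 / (2.0 * np.pi * sigma_f)


@dataclass(frozen=True)
class ScattererRegionSpec:
    """Depth band with its own scatterer density and echo spectral shift.

    ``echo_spectral_shift`` multiplies the pulse center frequency of echoes
    from this region: > 1 emulates finer scatterers (spectral content above
    the transmit center), < 1 coarser ones.
    """

    depth_range_cm: tuple[float, float]
    scatterer_density: float = 2000.0    # scatterers / mm^2, developed speckle
    echo_spectral_shift: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.depth_range_cm
        if not (0 <= lo < hi):
            raise ValueError("depth_range_cm must be ordered and non-negative")
        if self.scatterer_density <= 0:
            raise ValueError("scatterer_density must be positive")
        if self.echo_spectral_shift <= 0:
            raise ValueError("echo_spectral_shift must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Gaussian feature distribution of one cohort.

    Feature order: (sws m/s, swa Np/m, bscan a.u., hscan dimensionless,
    pe_nlp, wir_nlp).  ``timepoints_weeks``, when given, assigns a study week
    to each row; otherwise normal cohorts of 39 rows follow the study design
    (21 at week 0, 9 at week 2, 9 at week 6), other labels default to their
    study week (low_fat: 2, high_fat: 6).
    """

    label: str
    n_subjects: int
    feature_means: tuple[float, ...]
    feature_sds: tuple[float, ...]
    timepoints_weeks: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.label not in {"normal", "low_fat", "high_fat"}:
            raise ValueError("label must be normal, low_fat or high_fat")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if len(self.feature_means) != 6 or len(self.feature_sds) != 6:
            raise ValueError("feature_means and feature_sds must have 6 entries")
        if any(sd <= 0 for sd in self.feature_sds):
            raise ValueError("all feature SDs must be positive")
        if not 0 < self.feature_means[_HSCAN_IDX] < 1:
            raise ValueError("H-scan intensity mean must lie in (0, 1)")
        if self.timepoints_weeks is not None and len(self.timepoints_weeks) != self.n_subjects:
            raise ValueError("timepoints_weeks must have one entry per subject")


# ---------------------------------------------------------------------------
# RF phantom
# ---------------------------------------------------------------------------

def gen_rf_phantom(
    pulse: PulseSpec,
    regions: list[ScattererRegionSpec],
    attenuation_coeff: float,
    n_lines: int,
    seed: int,
    line_pitch_mm: float = 0.1,
    sound_speed: float = 1540.0,
) -> RFFrame:
    """Speckle RF frame from randomly placed Gaussian-enveloped echoes.

    Each scatterer contributes a Gaussian-enveloped sinusoid at the pulse
    center frequency times its region's spectral shift, with two-way
    amplitude attenuation 10^(-coeff * f_echo[MHz] * 2z[cm] / 20).  Regions
    must tile a contiguous depth span.
    """
    if attenuation_coeff < 0:
        raise ValueError("attenuation_coeff must be >= 0")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    regions = sorted(regions, key=lambda r: r.depth_range_cm[0])
    for a, b in zip(regions, regions[1:]):
        if not np.isclose(a.depth_range_cm[1], b.depth_range_cm[0]):
            raise ValueError(
                f"regions must be contiguous: {a.depth_range_cm} then {b.depth_range_cm}"
            )
    rng = np.random.default_rng(seed)
    fs = pulse.sampling_rate
    sigma_t = pulse.envelope_sigma_s
    z_max_m = regions[-1].depth_range_cm[1] * 1e-2
    t_max = 2.0 * z_max_m / sound_speed + 8.0 * sigma_t
    n_samples = int(np.ceil(t_max * fs))
    rf = np.zeros((n_samples, n_lines))
    half_w = int(np.ceil(6.0 * sigma_t * fs))
    tt = np.arange(-half_w, half_w + 1) / fs

    # per region: deposit an attenuated impulse train on the sample grid,
    # then convolve once with the region's echo waveform (scatterer depths
    # are quantized to the RF sample grid, < 1/4 period at 15 MHz / 100 MHz)
    for region in regions:
        lo_cm, hi_cm = region.depth_range_cm
        f_echo = pulse.center_frequency * region.echo_spectral_shift
        mean_count = region.scatterer_density * (hi_cm - lo_cm) * 10.0 * line_pitch_mm
        impulses = np.zeros_like(rf)
        for line in range(n_lines):
            count = rng.poisson(mean_count)
            depths_cm = rng.uniform(lo_cm, hi_cm, size=count)
            amps = rng.normal(0.0, 1.0, size=count)
            amps *= 10.0 ** (
                -attenuation_coeff * (f_echo / 1e6) * 2.0 * depths_cm / 20.0
            )
            idx = np.round(2.0 * depths_cm * 1e-2 / sound_speed * fs).astype(int)
            keep = (idx >= 0) & (idx < n_samples)
            np.add.at(impulses[:, line], idx[keep], amps[keep])
        waveform = np.exp(-(tt**2) / (2 * sigma_t**2)) * np.cos(2 * np.pi * f_echo * tt)
        rf += fftconvolve(impulses, waveform[:, None], mode="same")
    return RFFrame(
        samples=rf,
        sampling_rate=fs,
        center_frequency=pulse.center_frequency,
        line_pitch_mm=line_pitch_mm,
        sound_speed=sound_speed,
    )


# ---------------------------------------------------------------------------
# shear wave movie
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShearGrid:
    """Lateral / slow-time / axial sampling of a shear-wave acquisition."""

    lateral_pitch_mm: float = 0.3
    n_lateral: int = 200
    prf: float = 2000.0          # Hz
    n_frames: int = 400
    n_axial: int = 16
    axial_sampling: float = 20e6


def default_shear_grid(
    speed: float, attenuation: float, shear_frequency: float = 200.0
) -> ShearGrid:
    """Grid sized so the wave decays ~e^-6 across the aperture and the slow
    time window covers the transit plus 12 wave periods."""
    if attenuation > 0:
        extent_m = min(max(0.04, 6.0 / attenuation), 0.12)
    else:
        extent_m = 0.06
    pitch_mm = 0.3
    n_lateral = int(np.ceil(extent_m / (pitch_mm * 1e-3)))
    prf = max(2000.0, 10.0 * shear_frequency)
    duration = extent_m / speed + 12.0 / shear_frequency
    return ShearGrid(
        lateral_pitch_mm=pitch_mm,
        n_lateral=n_lateral,
        prf=prf,
        n_frames=int(np.ceil(duration * prf)),
    )


def gen_shear_movie(
    speed: float,
    attenuation: float,
    shear_frequency: float = 200.0,
    grid: ShearGrid | None = None,
    demod_frequency: float = 5e6,
    snr_db: float = 25.0,
    seed: int = 0,
    amplitude_um: float = 10.0,
    sound_speed: float = 1540.0,
) -> tuple[IQEnsemble, DisplacementField]:
    """Damped plane shear wave embedded in an IQ speckle ensemble.

    Ground truth displacement (micrometers):
        u(x, t) = A exp(-attenuation * x) sin(2 pi f_s (t - x/speed))
    for t >= x/speed and zero before the wavefront arrives.  The IQ ensemble
    carries u as an axial phase modulation 4 pi f_demod u / c of a fixed
    complex speckle pattern, plus circular Gaussian noise at ``snr_db``
    relative to unit speckle power.  Returns (IQ ensemble, truth field);
    the truth field has a single axial row.
    """
    if speed <= 0 or attenuation < 0:
        raise ValueError("speed must be positive and attenuation >= 0")
    if grid is None:
        grid = default_shear_grid(speed, attenuation, shear_frequency)
    if grid.prf < 8.0 * shear_frequency:
        raise ValueError("grid must resolve the shear frequency (prf >= 8 f_s)")
    dx_m = grid.lateral_pitch_mm * 1e-3
    extent_m = grid.n_lateral * dx_m
    if attenuation > 0 and extent_m < 3.0 / attenuation:
        raise ValueError(
            f"lateral extent {extent_m:.3g} m too short: need >= 3/attenuation "
            f"= {3.0 / attenuation:.3g} m"
        )
    alias_limit_um = 1e6 * sound_speed / (4.0 * demod_frequency)
    if amplitude_um >= alias_limit_um:
        raise ValueError(
            f"displacement amplitude {amplitude_um:.3g} um would wrap the IQ "
            f"phase; aliasing limit is {alias_limit_um:.3g} um"
        )

    rng = np.random.default_rng(seed)
    x = np.arange(grid.n_lateral) * dx_m
    t = np.arange(grid.n_frames) / grid.prf
    phase_arg = t[None, :] - x[:, None] / speed
    u_um = (
        amplitude_um
        * np.exp(-attenuation * x)[:, None]
        * np.sin(2.0 * np.pi * shear_frequency * phase_arg)
        * (phase_arg >= 0)
    )
    truth = DisplacementField(u=u_um[None, :, :], dx_mm=grid.lateral_pitch_mm, dt=1.0 / grid.prf)

    speckle = (
        rng.normal(size=(grid.n_axial, grid.n_lateral))
        + 1j * rng.normal(size=(grid.n_axial, grid.n_lateral))
    ) / np.sqrt(2.0)
    mod_phase = 4.0 * np.pi * demod_frequency * (u_um * 1e-6) / sound_speed
    data = speckle[:, :, None] * np.exp(1j * mod_phase[None, :, :])
    if np.isfinite(snr_db):
        noise_sd = np.sqrt(0.5 * 10.0 ** (-snr_db / 10.0))
        data = data + noise_sd * (
            rng.normal(size=data.shape) + 1j * rng.normal(size=data.shape)
        )
    iq = IQEnsemble(
        data=data,
        axial_sampling=grid.axial_sampling,
        demod_frequency=demod_frequency,
        prf=grid.prf,
        lateral_pitch_mm=grid.lateral_pitch_mm,
        sound_speed=sound_speed,
    )
    return iq, truth


# ---------------------------------------------------------------------------
# CEUS series
# ---------------------------------------------------------------------------

def _roi_layout(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    ivc = (rr - rows // 4) ** 2 + (cc - cols // 4) ** 2 <= (rows // 10) ** 2
    aorta = (rr - rows // 4) ** 2 + (cc - 3 * cols // 4) ** 2 <= (rows // 12) ** 2
    liver = (rr >= rows // 2) & (rr < rows - 2) & (cc >= 2) & (cc < cols - 2)
    liver &= ~(ivc | aorta)
    return {"liver": liver, "ivc": ivc, "aorta": aorta}


def gen_ceus_series(
    liver_truth: tuple[float, float],
    ivc_truth: tuple[float, float],
    frame_rate: float = 20.0,
    duration: float = 30.0,
    snr_db: float = 20.0,
    seed: int = 0,
    frame_shape: tuple[int, int] = (64, 64),
    liver_sigma: float = 0.45,
    ivc_sigma: float = 0.25,
) -> tuple[CEUSSeries, dict]:
    """Bolus CEUS frame stack with lognormal ROI kinetics.

    ``liver_truth`` and ``ivc_truth`` are (PE [a.u.], WIR [a.u./s]) pairs; the
    analytic maximum of each clean ROI curve equals its PE and the analytic
    maximum wash-in slope equals its WIR.  The IVC enhances before the liver
    parenchyma.  ``snr_db`` is the SNR of the ROI-mean trace (per-pixel noise
    is scaled by sqrt(ROI size)); ``snr_db=inf`` disables noise.

    Returns (series, truth) where truth maps each ROI to its PE, WIR, peak
    time and clean curve.
    """
    for name, (pe, wir) in (("liver", liver_truth), ("ivc", ivc_truth)):
        if pe <= 0 or wir <= 0:
            raise ValueError(f"{name} PE and WIR must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * frame_rate))
    times = np.arange(n_frames) / frame_rate
    rois = _roi_layout(frame_shape)

    ivc_t0 = 3.0
    mu_i, a_i = bolus_params_for(*ivc_truth, ivc_sigma)
    mu_l, a_l = bolus_params_for(*liver_truth, liver_sigma)
    tau_pk_i, _ = bolus_peak(mu_i, ivc_sigma)
    tau_pk_l, _ = bolus_peak(mu_l, liver_sigma)
    # liver onset after the IVC, and late enough that its peak follows too
    liver_t0 = max(ivc_t0 + 2.0, ivc_t0 + tau_pk_i - tau_pk_l + 1.0)
    if liver_t0 + tau_pk_l + 2.0 > duration:
        raise ValueError(
            f"duration {duration:.3g} s too short for full liver wash-in "
            f"(peak at {liver_t0 + tau_pk_l:.3g} s)"
        )

    curves = {
        "ivc": lognormal_bolus(times, ivc_t0, mu_i, ivc_sigma, a_i),
        "liver": lognormal_bolus(times, liver_t0, mu_l, liver_sigma, a_l),
    }
    # aorta: arterial vessel, slightly after the IVC with similar kinetics
    curves["aorta"] = lognormal_bolus(times, ivc_t0 + 0.5, mu_i, ivc_sigma, 0.8 * a_i)

    frames = np.zeros(frame_shape + (n_frames,))
    noise_ref = {"liver": liver_truth[0], "ivc": ivc_truth[0], "aorta": ivc_truth[0]}
    for name, mask in rois.items():
        n_px = int(mask.sum())
        frames[mask] = curves[name][None, :]
        if np.isfinite(snr_db):
            sd_roi = noise_ref[name] / 10.0 ** (snr_db / 20.0)
            frames[mask] += rng.normal(
                0.0, sd_roi * np.sqrt(n_px), size=(n_px, n_frames)
            )
    background = ~(rois["liver"] | rois["ivc"] | rois["aorta"])
    if np.isfinite(snr_db):
        sd_bg = 0.02 * liver_truth[0]
        frames[background] = rng.normal(
            0.0, sd_bg, size=(int(background.sum()), n_frames)
        )

    series = CEUSSeries(frames=frames, frame_times=times, rois=rois)
    truth = {
        "liver": {
            "pe": liver_truth[0], "wir": liver_truth[1],
            "t_peak": liver_t0 + tau_pk_l, "curve": curves["liver"],
        },
        "ivc": {
            "pe": ivc_truth[0], "wir": ivc_truth[1],
            "t_peak": ivc_t0 + tau_pk_i, "curve": curves["ivc"],
        },
        "pe_nlp": liver_truth[0] / ivc_truth[0],
        "wir_nlp": liver_truth[1] / ivc_truth[1],
    }
    return series, truth


# ---------------------------------------------------------------------------
# histology
# ---------------------------------------------------------------------------

_TISSUE_RGB = np.array([210.0, 160.0, 190.0])   # eosin pink
_FAT_RGB = np.array([250.0, 249.0, 251.0])      # unstained vacuole
_NUCLEUS_RGB = np.array([120.0, 90.0, 160.0])   # hematoxylin purple


def gen_histology(
    fat_fraction_true: float,
    vacuole_radius_um: tuple[float, float] = (15.0, 4.0),
    image_size: tuple[int, int] = (512, 512),
    pixel_size: float = 1.0,
    seed: int = 0,
    max_attempts: int = 50000,
) -> HistologyImage:
    """H&E-like image with non-overlapping white vacuoles at a known fraction.

    Ellipses are placed by rejection sampling until the white-area fraction
    is within 0.2 percentage points of ``fat_fraction_true`` (the last
    vacuole is shrunk to land inside the tolerance); the realized fraction
    and vacuole count are recorded on the returned image.
    """
    if not 0 <= fat_fraction_true <= 60:
        raise ValueError("fat_fraction_true must be in [0, 60] percent")
    mean_r_px = vacuole_radius_um[0] / pixel_size
    if mean_r_px < 2:
        raise ValueError("vacuole radius must be at least 2 pixels")
    rng = np.random.default_rng(seed)
    rows, cols = image_size
    total_px = rows * cols
    target_px = fat_fraction_true / 100.0 * total_px
    tol_px = 0.2 / 100.0 * total_px

    fat = np.zeros((rows, cols), dtype=bool)
    blocked = np.zeros_like(fat)
    fat_px = 0
    n_vac = 0
    attempts = 0
    while target_px - fat_px > tol_px:
        r_px = float(np.clip(rng.normal(mean_r_px, vacuole_radius_um[1] / pixel_size), 2.0, min(rows, cols) / 4))
        aspect = rng.uniform(0.6, 1.0)
        remaining = target_px - fat_px
        if np.pi * r_px**2 * aspect > remaining:
            r_px = max(np.sqrt(remaining / (np.pi * aspect)), 2.0)
        rot = rng.uniform(0, np.pi)
        cy = rng.uniform(r_px, rows - r_px)
        cx = rng.uniform(r_px, cols - r_px)
        rr, cc = draw_ellipse(cy, cx, r_px, r_px * aspect, shape=(rows, cols), rotation=rot)
        if blocked[rr, cc].any():
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not reach fat fraction {fat_fraction_true}% without "
                    f"overlap after {max_attempts} attempts"
                )
            continue
        fat[rr, cc] = True
        fat_px += rr.size
        n_vac += 1
        rb, cb = draw_ellipse(
            cy, cx, r_px + 2, r_px * aspect + 2, shape=(rows, cols), rotation=rot
        )
        blocked[rb, cb] = True

    img = np.empty((rows, cols, 3))
    img[:] = _TISSUE_RGB
    img += rng.normal(0.0, 5.0, size=img.shape)
    # sparse hematoxylin-stained nuclei in the parenchyma
    nuclei = rng.random((rows, cols)) < 0.01
    img[nuclei & ~fat] = _NUCLEUS_RGB + rng.normal(0.0, 8.0, size=(int((nuclei & ~fat).sum()), 3))
    img[fat] = _FAT_RGB + rng.normal(0.0, 1.5, size=(fat_px, 3))
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    realized = 100.0 * fat_px / total_px
    return HistologyImage(
        pixels=pixels,
        pixel_size=pixel_size,
        true_fat_fraction=realized,
        n_vacuoles_true=n_vac,
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def default_cohorts(
    n_normal: int = 39, n_low: int = 12, n_high: int = 12
) -> list[CohortSpec]:
    """Study-mirroring cohort specs (21 rats: 9 control, 12 MCD; weeks 0/2/6).

    The source study reports group values only as boxplots, so these means
    and SDs are this package's own plausible settings: steatosis lowers the
    shear wave speed and the normalized perfusion parameters, and raises the
    attenuation, echogenicity and H-scan (blue-shift) intensity.
    """
    return [
        CohortSpec(
            "normal", n_normal,
            feature_means=(1.50, 95.0, 55.0, 0.45, 0.65, 0.55),
            feature_sds=(0.06, 6.0, 4.0, 0.025, 0.06, 0.06),
        ),
        CohortSpec(
            "low_fat", n_low,
            feature_means=(1.43, 105.0, 62.0, 0.50, 0.54, 0.44),
            feature_sds=(0.06, 6.0, 4.0, 0.025, 0.06, 0.06),
        ),
        CohortSpec(
            "high_fat", n_high,
            feature_means=(1.36, 114.0, 70.0, 0.56, 0.42, 0.33),
            feature_sds=(0.06, 6.0, 4.0, 0.025, 0.06, 0.06),
        ),
    ]


def effect_size_cohorts(
    steps_sd: tuple[float, ...] = (3.0,) * 6,
    n_per_cohort: tuple[int, ...] = (39, 12),
) -> list[CohortSpec]:
    """Cohorts whose adjacent means differ by ``steps_sd`` pooled SDs per
    feature, with within-cohort SDs fixed.

    Separations are specified in SD units; the H-scan feature keeps its
    natural (0, 1) scale (SD 0.03) while the others use unit SDs, which is
    equivalent under Z-scoring.
    """
    labels = ["normal", "low_fat", "high_fat"][: len(n_per_cohort)]
    if len(n_per_cohort) == 2:
        labels = ["normal", "high_fat"]
    sds = [1.0] * 6
    sds[_HSCAN_IDX] = 0.03
    base = [0.0] * 6
    base[_HSCAN_IDX] = 0.2
    cohorts = []
    for i, (label, n) in enumerate(zip(labels, n_per_cohort)):
        means = tuple(
            b + i * step * sd for b, step, sd in zip(base, steps_sd, sds)
        )
        cohorts.append(
            CohortSpec(label, n, feature_means=means, feature_sds=tuple(sds))
        )
    return cohorts


def _default_weeks(label: str, n: int) -> list[int]:
    if label == "normal":
        if n == 39:
            return [0] * 21 + [2] * 9 + [6] * 9
        return [0] * n
    return [2 if label == "low_fat" else 6] * n


def gen_feature_table(cohorts: list[CohortSpec], seed: int) -> pd.DataFrame:
    """Draw one six-feature row per subject from its cohort's Gaussian.

    Columns: subject, timepoint, cohort, sws, swa, bscan, hscan, pe_nlp,
    wir_nlp.  The default study-mirroring configuration yields 63 rows with
    cohort counts (39, 12, 12).
    """
    labels = [c.label for c in cohorts]
    if len(set(labels)) != len(labels):
        raise ValueError("cohort labels must be distinct")
    rng = np.random.default_rng(seed)
    records = []
    for cohort in cohorts:
        weeks = (
            list(cohort.timepoints_weeks)
            if cohort.timepoints_weeks is not None
            else _default_weeks(cohort.label, cohort.n_subjects)
        )
        draws = rng.normal(
            np.asarray(cohort.feature_means),
            np.asarray(cohort.feature_sds),
            size=(cohort.n_subjects, 6),
        )
        for i in range(cohort.n_subjects):
            rec = {
                "subject": f"{cohort.label[:2].upper()}{i + 1:03d}",
                "timepoint": weeks[i],
                "cohort": cohort.label,
            }
            rec.update(dict(zip(FEATURE_COLUMNS, draws[i])))
            records.append(rec)
    return pd.DataFrame.from_records(records)
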