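"""End-to-end study analogue: generate, measure, test, classify, report.

``run_study`` emulates the full longitudinal experiment: two animal groups
(control and MCD-diet) imaged at weeks 0, 2 and 6.  For every
subject-timepoint it synthesizes raw data with group- and week-dependent
ground truth, runs the four measurement stages (H-scan, shear wave
elastography, CEUS perfusion, and optionally week-6 histology), assembles
the six-feature table, and finishes with per-feature Mann-Whitney group
comparisons and the two- and three-category SVM classification.

All per-stage random seeds are derived by hashing (master seed, subject,
week, stage), so any subject can be regenerated in isolation and the whole
study is bit-reproducible from the master seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ceus, classify, histology, hscan, swe, synthetic
from ._utils import derive_seed
from .io import save_feature_table
from .synthetic import FEATURE_COLUMNS, PulseSpec, ScattererRegionSpec

__all__ = ["StudyConfig", "run_study"]

# group- and week-dependent ground truth of the study analogue; values follow
# the directions steatosis is known to move each parameter (speed down,
# attenuation up, echogenicity and H-scan blue shift up, perfusion down)
SWE_TRUTH = {  # (group, week) -> (speed m/s, attenuation Np/m)
    ("control", 0): (1.42, 96.0), ("control", 2): (1.47, 95.0), ("control", 6): (1.52, 94.8),
    ("mcd", 0): (1.42, 96.0), ("mcd", 2): (1.445, 99.0), ("mcd", 6): (1.36, 113.9),
}
HSCAN_SHIFT = {  # echo spectral shift of the liver parenchyma
    ("control", 0): 1.0, ("control", 2): 1.0, ("control", 6): 1.0,
    ("mcd", 0): 1.0, ("mcd", 2): 1.05, ("mcd", 6): 1.25,
}
BSCAN_GAIN = {  # echogenicity scaling of the RF amplitude
    ("control", 0): 1.0, ("control", 2): 1.05, ("control", 6): 1.10,
    ("mcd", 0): 1.0, ("mcd", 2): 1.18, ("mcd", 6): 1.80,
}
PERFUSION_TRUTH = {  # (liver PE, liver WIR, IVC PE, IVC WIR) a.u.
    ("control", 0): (13.0, 4.4, 20.0, 8.0),
    ("control", 2): (13.4, 4.6, 20.0, 8.0),
    ("control", 6): (14.0, 4.8, 20.0, 8.0),
    ("mcd", 0): (13.0, 4.4, 20.0, 8.0),
    ("mcd", 2): (12.4, 4.2, 20.0, 8.0),
    ("mcd", 6): (8.4, 2.6, 20.0, 8.0),
}
FAT_FRACTION_TRUTH = {"control": (0.4, 0.1), "mcd": (39.4, 1.3)}  # mean, SD %


@dataclass
class StudyConfig:
    """Design, generator and analysis settings of one synthetic study."""

    n_control: int = 9
    n_mcd: int = 12
    timepoints: tuple[int, ...] = (0, 2, 6)
    master_seed: int = 0
    output_dir: str = "study_out"
    subject_jitter: float = 0.02      # biological variability, fractional SD
    attenuation_coeff: float = 0.3    # dB/cm/MHz, generation and correction
    band_hz: tuple[float, float] = (5e6, 18e6)
    rf_lines: int = 48
    swe_snr_db: float = 25.0
    ceus_snr_db: float = 25.0
    ceus_frame_rate: float = 10.0
    split: float = 0.8
    include_histology: bool = True
    histology_size: int = 256
    make_plots: bool = False

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["timepoints"] = list(self.timepoints)
        data["band_hz"] = list(self.band_hz)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["timepoints"] = tuple(data["timepoints"])
        data["band_hz"] = tuple(data["band_hz"])
        return cls(**data)


def _jitter(rng: np.random.Generator, value: float, frac: float) -> float:
    return float(value * (1.0 + rng.normal(0.0, frac)))


def _measure_hscan(config: StudyConfig, group: str, week: int, subject: str) -> tuple[float, float]:
    seed = derive_seed(config.master_seed, subject, week, "hscan")
    rng = np.random.default_rng(derive_seed(config.master_seed, subject, week, "hscan_bio"))
    shift = _jitter(rng, HSCAN_SHIFT[(group, week)], config.subject_jitter)
    gain = _jitter(rng, BSCAN_GAIN[(group, week)], config.subject_jitter)
    pulse = PulseSpec()
    region = ScattererRegionSpec(depth_range_cm=(0.5, 2.0), echo_spectral_shift=shift)
    frame = synthetic.gen_rf_phantom(
        pulse, [region], config.attenuation_coeff, config.rf_lines, seed
    )
    frame.samples *= gain
    corrected = hscan.attenuation_correct(frame, config.attenuation_coeff)
    sigma = hscan.gh_time_scale_for_center(pulse.center_frequency)
    low = hscan.make_gh_kernel(2, sigma, pulse.sampling_rate)
    high = hscan.make_gh_kernel(8, sigma, pulse.sampling_rate)
    image = hscan.hscan_reconstruct(corrected, low, high, config.band_hz)
    # ROI: central depth band, full width
    step = frame.depth_step_cm
    r0, r1 = int(0.7 / step), int(1.8 / step)
    return hscan.roi_metrics(image, (0, r0, config.rf_lines, r1))


def _measure_swe(config: StudyConfig, group: str, week: int, subject: str) -> tuple[float, float]:
    seed = derive_seed(config.master_seed, subject, week, "swe")
    rng = np.random.default_rng(derive_seed(config.master_seed, subject, week, "swe_bio"))
    speed, att = SWE_TRUTH[(group, week)]
    speed = _jitter(rng, speed, config.subject_jitter)
    att = _jitter(rng, att, config.subject_jitter)
    iq, _ = synthetic.gen_shear_movie(
        speed, att, snr_db=config.swe_snr_db, seed=seed
    )
    field = swe.estimate_displacement(iq)
    result = swe.shear_wave_analysis(field)
    return result.speed, result.attenuation


def _measure_ceus(config: StudyConfig, group: str, week: int, subject: str) -> tuple[float, float]:
    seed = derive_seed(config.master_seed, subject, week, "ceus")
    rng = np.random.default_rng(derive_seed(config.master_seed, subject, week, "ceus_bio"))
    lpe, lwir, ipe, iwir = PERFUSION_TRUTH[(group, week)]
    lpe = _jitter(rng, lpe, config.subject_jitter)
    lwir = _jitter(rng, lwir, config.subject_jitter)
    series, _ = synthetic.gen_ceus_series(
        (lpe, lwir), (ipe, iwir),
        frame_rate=config.ceus_frame_rate,
        snr_db=config.ceus_snr_db,
        seed=seed,
        frame_shape=(32, 32),
    )
    liver = ceus.fit_tic(ceus.extract_tic(series, "liver"))
    ivc = ceus.fit_tic(ceus.extract_tic(series, "ivc"))
    normalized = ceus.normalize_perfusion(liver, ivc)
    return float(normalized.pe_nlp), float(normalized.wir_nlp)


def _measure_histology(config: StudyConfig, group: str, subject: str) -> dict:
    seed = derive_seed(config.master_seed, subject, "histology")
    rng = np.random.default_rng(derive_seed(config.master_seed, subject, "histology_bio"))
    mean, sd = FAT_FRACTION_TRUTH[group]
    truth = float(np.clip(rng.normal(mean, sd), 0.0, 60.0))
    image = synthetic.gen_histology(
        truth, image_size=(config.histology_size, config.histology_size), seed=seed
    )
    result = histology.segment_fat(image)
    return {
        "subject": subject,
        "group": group,
        "true_fat_fraction": image.true_fat_fraction,
        "measured_fat_fraction": result.fat_fraction,
        "n_vacuoles": result.n_vacuoles,
    }


def _cohort_of(group: str, week: int) -> str:
    if group == "control" or week == 0:
        return "normal"
    return "low_fat" if week == 2 else "high_fat"


def run_study(config: StudyConfig) -> dict:
    """Run the full synthetic study and write its report to the output dir.

    Writes ``features.csv`` (always, partial on failure), ``report.json``
    and, optionally, diagnostic PNGs.  Returns the report as a dict with the
    feature table under "features".
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = [("control", f"C{i + 1:02d}") for i in range(config.n_control)]
    subjects += [("mcd", f"M{i + 1:02d}") for i in range(config.n_mcd)]

    rows: list[dict] = []
    timings: dict[str, float] = {"hscan": 0.0, "swe": 0.0, "ceus": 0.0, "histology": 0.0}
    try:
        for group, subject in subjects:
            for week in config.timepoints:
                stage = "hscan"
                try:
                    t0 = time.perf_counter()
                    bscan_i, hscan_i = _measure_hscan(config, group, week, subject)
                    timings["hscan"] += time.perf_counter() - t0
                    stage = "swe"
                    t0 = time.perf_counter()
                    sws, swa = _measure_swe(config, group, week, subject)
                    timings["swe"] += time.perf_counter() - t0
                    stage = "ceus"
                    t0 = time.perf_counter()
                    pe_nlp, wir_nlp = _measure_ceus(config, group, week, subject)
                    timings["ceus"] += time.perf_counter() - t0
                except Exception as exc:
                    raise RuntimeError(
                        f"stage '{stage}' failed for subject {subject} week {week}: {exc}"
                    ) from exc
                rows.append({
                    "subject": subject,
                    "timepoint": week,
                    "cohort": _cohort_of(group, week),
                    "group": group,
                    "sws": sws, "swa": swa,
                    "bscan": bscan_i, "hscan": hscan_i,
                    "pe_nlp": pe_nlp, "wir_nlp": wir_nlp,
                })
    finally:
        if rows:  # partial outputs are retained on failure
            save_feature_table(out / "features.csv", pd.DataFrame(rows))

    features = pd.DataFrame(rows)

    # per-feature, per-week control vs MCD comparisons
    mw: dict[str, dict[str, dict]] = {}
    for week in config.timepoints:
        at_week = features[features["timepoint"] == week]
        mw[f"week_{week}"] = {}
        for col in FEATURE_COLUMNS:
            res = classify.mann_whitney_u(
                at_week.loc[at_week["group"] == "control", col],
                at_week.loc[at_week["group"] == "mcd", col],
            )
            mw[f"week_{week}"][col] = {
                "u": res.u, "p": res.p, "significant": res.significant,
            }

    cls_seed = derive_seed(config.master_seed, "classification")
    reports = {
        "two_category_raw": classify.svm_train_eval(
            features, "two_category", "raw_features", config.split, cls_seed
        ),
        "three_category_first_3_pcs": classify.svm_train_eval(
            features, "three_category", "first_3_pcs", config.split, cls_seed
        ),
        "three_category_all_pcs": classify.svm_train_eval(
            features, "three_category", "all_pcs", config.split, cls_seed
        ),
    }

    standardized, _ = classify.zscore(features)
    pca = classify.pca_contributions(standardized, n_components=3)

    histo = []
    if config.include_histology:
        t0 = time.perf_counter()
        for group, subject in subjects:
            histo.append(_measure_histology(config, group, subject))
        timings["histology"] = time.perf_counter() - t0

    report = {
        "config": {**asdict(config)},
        "n_rows": len(features),
        "cohort_counts": features["cohort"].value_counts().to_dict(),
        "mann_whitney": mw,
        "classification": {k: asdict(v) for k, v in reports.items()},
        "pca_contributions_pct": pca.contributions.round(3).to_dict(),
        "histology": histo,
        "stage_seconds": {k: round(v, 2) for k, v in timings.items()},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))

    if config.make_plots:
        _write_plots(features, out)

    report["features"] = features
    return report


def _write_plots(features: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, col in zip(axes.ravel(), FEATURE_COLUMNS):
        data = [
            features.loc[
                (features["group"] == g) & (features["timepoint"] == w), col
            ]
            for w in sorted(features["timepoint"].unique())
            for g in ("control", "mcd")
        ]
        ax.boxplot(data)
        ax.set_title(col)
        ax.set_xticklabels(
            [f"{g[0]}{w}" for w in sorted(features["timepoint"].unique())
             for g in ("control", "mcd")],
            fontsize=7,
        )
    fig.tight_layout()
    fig.savefig(out / "feature_boxplots.png", dpi=120)
    plt.close(fig)
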