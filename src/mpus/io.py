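"""HDF5 / TIFF / CSV persistence for the pipeline's data containers.

Arrays go to an HDF5 container with one group per object and acquisition
metadata stored as attributes; histology images go to TIFF; feature tables
to CSV with the canonical header
``subject,timepoint,cohort,sws,swa,bscan,hscan,pe_nlp,wir_nlp``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .ceus import CEUSSeries
from .histology import HistologyImage
from .hscan import RFFrame
from .swe import DisplacementField, IQEnsemble
from .synthetic import FEATURE_COLUMNS

__all__ = [
    "save_rf_frame", "load_rf_frame",
    "save_iq_ensemble", "load_iq_ensemble",
    "save_displacement_field", "load_displacement_field",
    "save_ceus_series", "load_ceus_series",
    "save_histology", "load_histology",
    "save_feature_table", "load_feature_table",
]

TABLE_COLUMNS = ["subject", "timepoint", "cohort"] + FEATURE_COLUMNS


def _group(path, name: str, mode: str):
    f = h5py.File(path, mode)
    if mode == "a" and name in f:
        del f[name]
    return f


def save_rf_frame(path, frame: RFFrame, name: str = "rf") -> None:
    with _group(path, name, "a") as f:
        g = f.create_group(name)
        g.create_dataset("samples", data=frame.samples)
        g.attrs.update(
            sampling_rate=frame.sampling_rate,
            center_frequency=frame.center_frequency,
            line_pitch_mm=frame.line_pitch_mm,
            sound_speed=frame.sound_speed,
            attenuation_corrected=frame.attenuation_corrected,
        )


def load_rf_frame(path, name: str = "rf") -> RFFrame:
    with h5py.File(path, "r") as f:
        g = f[name]
        return RFFrame(
            samples=g["samples"][()],
            sampling_rate=float(g.attrs["sampling_rate"]),
            center_frequency=float(g.attrs["center_frequency"]),
            line_pitch_mm=float(g.attrs["line_pitch_mm"]),
            sound_speed=float(g.attrs["sound_speed"]),
            attenuation_corrected=bool(g.attrs["attenuation_corrected"]),
        )


def save_iq_ensemble(path, iq: IQEnsemble, name: str = "iq") -> None:
    with _group(path, name, "a") as f:
        g = f.create_group(name)
        g.create_dataset("data", data=iq.data)
        g.attrs.update(
            axial_sampling=iq.axial_sampling,
            demod_frequency=iq.demod_frequency,
            prf=iq.prf,
            lateral_pitch_mm=iq.lateral_pitch_mm,
            sound_speed=iq.sound_speed,
        )


def load_iq_ensemble(path, name: str = "iq") -> IQEnsemble:
    with h5py.File(path, "r") as f:
        g = f[name]
        return IQEnsemble(
            data=g["data"][()],
            axial_sampling=float(g.attrs["axial_sampling"]),
            demod_frequency=float(g.attrs["demod_frequency"]),
            prf=float(g.attrs["prf"]),
            lateral_pitch_mm=float(g.attrs["lateral_pitch_mm"]),
            sound_speed=float(g.attrs["sound_speed"]),
        )


def save_displacement_field(path, field: DisplacementField, name: str = "displacement") -> None:
    with _group(path, name, "a") as f:
        g = f.create_group(name)
        g.create_dataset("u", data=field.u)
        g.attrs.update(
            dx_mm=field.dx_mm, dt=field.dt, aliasing_warning=field.aliasing_warning
        )


def load_displacement_field(path, name: str = "displacement") -> DisplacementField:
    with h5py.File(path, "r") as f:
        g = f[name]
        return DisplacementField(
            u=g["u"][()],
            dx_mm=float(g.attrs["dx_mm"]),
            dt=float(g.attrs["dt"]),
            aliasing_warning=bool(g.attrs["aliasing_warning"]),
        )


def save_ceus_series(path, series: CEUSSeries, name: str = "ceus") -> None:
    with _group(path, name, "a") as f:
        g = f.create_group(name)
        g.create_dataset("frames", data=series.frames)
        g.create_dataset("frame_times", data=series.frame_times)
        rg = g.create_group("rois")
        for roi_name, mask in series.rois.items():
            rg.create_dataset(roi_name, data=mask.astype(bool))


def load_ceus_series(path, name: str = "ceus") -> CEUSSeries:
    with h5py.File(path, "r") as f:
        g = f[name]
        rois = {k: g["rois"][k][()].astype(bool) for k in g["rois"]}
        return CEUSSeries(
            frames=g["frames"][()], frame_times=g["frame_times"][()], rois=rois
        )


def save_histology(path, image: HistologyImage) -> None:
    tifffile.imwrite(
        path,
        image.pixels,
        resolution=(1e4 / image.pixel_size, 1e4 / image.pixel_size),
        metadata={"pixel_size_um": image.pixel_size},
    )


def load_histology(path, pixel_size: float) -> HistologyImage:
    return HistologyImage(pixels=tifffile.imread(path), pixel_size=pixel_size)


def save_feature_table(path, table: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    table[TABLE_COLUMNS].to_csv(path, index=False)


def load_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{Path(path).name} missing columns: {missing}")
    return table
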