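"""Readers and writers for the pipeline's on-disk dialects.

Image series travel as separate 4-D magnitude and phase NIfTI volumes
(phase in radians) with a JSON sidecar carrying TE/TR/B0/pixel spacing, or
as a raw complex64 binary with the same sidecar.  Probe logs are 2-column
delimited text (time_s, temp_C), header optional.  Calibration tables are
CSV with columns fa_deg, b1rms_uT, energy_J, tmax_C; a measured table for
a copper wire in agar gel at 1.5 T ships with the package.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .model import CalibrationSet, EqOneParams, HeatingWindow, IsothermGrid
from .series import ComplexImageSeries, TemperatureSeries

__all__ = [
    "MissingMetadataError",
    "load_wire_calibration",
    "read_calibration_table",
    "read_probe_log",
    "write_series_nifti",
    "read_series_nifti",
    "write_series_raw",
    "read_series_raw",
    "write_temperature_nifti",
    "write_map_nifti",
    "save_calibration_json",
    "load_calibration_json",
    "isotherm_to_csv",
]

SIDECAR_REQUIRED = ("te_s", "tr_s", "b0_t", "pixel_spacing_mm")


class MissingMetadataError(KeyError):
    """A required acquisition-metadata field is absent from the sidecar."""


def load_wire_calibration() -> pd.DataFrame:
    """Shipped calibration table: flip angle, B1+rms, energy, peak rise."""
    with resources.files("thermowire.data").joinpath(
        "copper_wire_calibration.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def read_calibration_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"fa_deg", "b1rms_uT", "energy_J", "tmax_C"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration table missing columns: {sorted(missing)}")
    return df


def read_probe_log(path) -> tuple[np.ndarray, np.ndarray]:
    """Probe temperature log: (time_s, temp_C) columns, header optional."""
    arr = np.genfromtxt(path, delimiter=None, names=None, skip_header=0)
    if arr.ndim == 1:  # header line produced NaNs; retry skipping it
        arr = np.genfromtxt(path, skip_header=1)
    if np.isnan(arr[0]).any():
        arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"probe log {path} must have 2 columns (time_s, temp_C)")
    return arr[:, 0].astype(float), arr[:, 1].astype(float)


def _sidecar_from_series(series: ComplexImageSeries) -> dict:
    return {
        "te_s": series.te,
        "tr_s": series.tr,
        "b0_t": series.b0,
        "pixel_spacing_mm": list(series.pixel_spacing),
        "times_s": series.times.tolist(),
    }


def _series_meta(sidecar_path) -> dict:
    meta = json.loads(Path(sidecar_path).read_text())
    for key in SIDECAR_REQUIRED:
        if key not in meta:
            raise MissingMetadataError(
                f"sidecar {sidecar_path} is missing required field '{key}'"
            )
    return meta


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    # NIfTI stores x,y,z,t; our arrays are [dyn, slice, row, col]
    return nib.Nifti1Image(np.transpose(data, (3, 2, 1, 0)), affine=np.eye(4))


def _from_nifti(img: nib.Nifti1Image) -> np.ndarray:
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr[..., None]
    return np.transpose(arr, (3, 2, 1, 0))


def write_series_nifti(series: ComplexImageSeries, mag_path, phase_path, sidecar_path) -> None:
    nib.save(_nifti(np.abs(series.data).astype(np.float32)), str(mag_path))
    nib.save(_nifti(np.angle(series.data).astype(np.float32)), str(phase_path))
    Path(sidecar_path).write_text(json.dumps(_sidecar_from_series(series), indent=1))


def read_series_nifti(mag_path, phase_path, sidecar_path) -> ComplexImageSeries:
    meta = _series_meta(sidecar_path)
    mag = _from_nifti(nib.load(str(mag_path))).astype(float)
    phase = _from_nifti(nib.load(str(phase_path))).astype(float)
    if mag.shape != phase.shape:
        raise ValueError("magnitude and phase volumes have different shapes")
    times = np.asarray(
        meta.get("times_s", np.arange(mag.shape[0]) * meta["tr_s"]), dtype=float
    )
    return ComplexImageSeries(
        data=mag * np.exp(1j * phase),
        times=times,
        pixel_spacing=tuple(meta["pixel_spacing_mm"]),
        te=meta["te_s"],
        b0=meta["b0_t"],
        tr=meta["tr_s"],
    )


def write_series_raw(series: ComplexImageSeries, data_path, sidecar_path) -> None:
    """Raw complex64 binary (C order, [dyn, slice, row, col]) + JSON sidecar."""
    series.data.astype(np.complex64).tofile(str(data_path))
    meta = _sidecar_from_series(series)
    meta["shape"] = list(series.data.shape)
    meta["dtype"] = "complex64"
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def read_series_raw(data_path, sidecar_path) -> ComplexImageSeries:
    meta = _series_meta(sidecar_path)
    if "shape" not in meta:
        raise MissingMetadataError(f"sidecar {sidecar_path} is missing 'shape'")
    data = np.fromfile(str(data_path), dtype=meta.get("dtype", "complex64"))
    data = data.reshape(meta["shape"])
    times = np.asarray(
        meta.get("times_s", np.arange(data.shape[0]) * meta["tr_s"]), dtype=float
    )
    return ComplexImageSeries(
        data=data.astype(np.complex128),
        times=times,
        pixel_spacing=tuple(meta["pixel_spacing_mm"]),
        te=meta["te_s"],
        b0=meta["b0_t"],
        tr=meta["tr_s"],
    )


def write_temperature_nifti(dT: TemperatureSeries, path) -> None:
    nib.save(_nifti(dT.dT.astype(np.float32)), str(path))


def write_map_nifti(img: np.ndarray, path) -> None:
    """3-D (slice, row, col) map, e.g. μ_T or σ_T."""
    nib.save(
        nib.Nifti1Image(np.transpose(img, (2, 1, 0)).astype(np.float32), np.eye(4)),
        str(path),
    )


def save_calibration_json(calib: CalibrationSet, path) -> None:
    payload = {
        "fits": [
            {
                "p0_w": f.p0,
                "alpha": f.alpha,
                "tau_s": f.tau,
                "alpha_se": None if np.isnan(f.alpha_se) else f.alpha_se,
                "tau_se": None if np.isnan(f.tau_se) else f.tau_se,
                "rmse_c": None if np.isnan(f.rmse) else f.rmse,
                "low_signal": f.low_signal,
            }
            for f in calib.fitted
        ],
        "alpha_poly_desc": None
        if calib.alpha_poly is None
        else list(map(float, calib.alpha_poly)),
        "tau_poly_desc": None
        if calib.tau_poly is None
        else list(map(float, calib.tau_poly)),
        "power_range_w": None
        if calib.power_range is None
        else list(calib.power_range),
        "window_s": None
        if calib.window is None
        else [calib.window.t0, calib.window.t1],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_calibration_json(path) -> CalibrationSet:
    payload = json.loads(Path(path).read_text())
    fits = [
        EqOneParams(
            alpha=f["alpha"],
            tau=f["tau_s"],
            p0=f["p0_w"],
            alpha_se=np.nan if f.get("alpha_se") is None else f["alpha_se"],
            tau_se=np.nan if f.get("tau_se") is None else f["tau_se"],
            rmse=np.nan if f.get("rmse_c") is None else f["rmse_c"],
            low_signal=f.get("low_signal", False),
        )
        for f in payload.get("fits", [])
    ]
    window = (
        HeatingWindow(*payload["window_s"]) if payload.get("window_s") else None
    )
    return CalibrationSet(
        fitted=fits,
        alpha_poly=None
        if payload.get("alpha_poly_desc") is None
        else np.asarray(payload["alpha_poly_desc"], dtype=float),
        tau_poly=None
        if payload.get("tau_poly_desc") is None
        else np.asarray(payload["tau_poly_desc"], dtype=float),
        power_range=None
        if payload.get("power_range_w") is None
        else tuple(payload["power_range_w"]),
        window=window,
    )


def isotherm_to_csv(grid: IsothermGrid, matrix_path, axes_path) -> None:
    """Peak-rise matrix as CSV (rows = powers) + JSON axes."""
    pd.DataFrame(
        grid.tmax,
        index=pd.Index(grid.powers, name="power_w"),
        columns=[f"{d:g}" for d in grid.durations],
    ).to_csv(matrix_path)
    Path(axes_path).write_text(
        json.dumps(
            {
                "powers_w": list(map(float, grid.powers)),
                "durations_s": list(map(float, grid.durations)),
            },
            indent=1,
        )
    )
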