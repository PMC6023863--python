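"""Tabular and config file formats.

Composition series: CSV with header ``time_min,xA,xB,xC,xD``.
Thermal series:     CSV with header ``time_s,x_start,x_other``.
Spectra:            CSV with first column ``wavelength_nm``, one column per time.
Matrices (4x4):     CSV with an A-D header row and index column.
Conditions/manifests/diagnostics: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .photokin import CompositionSeries, PhotoConditions, QuantumYieldMatrix
from .markov import TransitionMatrix
from .spectra import SpectraSeries
from .states import ISOMERS, as_isomer

__all__ = [
    "write_composition_csv", "read_composition_csv",
    "write_matrix_csv", "read_matrix_csv",
    "write_thermal_csv", "read_thermal_csv",
    "write_spectra_csv", "read_spectra_csv",
    "write_conditions_json", "read_conditions_json",
    "write_manifest", "read_manifest",
    "write_json",
]

_COMP_COLS = ["time_min", "xA", "xB", "xC", "xD"]
_FLOAT_FMT = "%.12g"


def write_composition_csv(series: CompositionSeries, path) -> None:
    df = pd.DataFrame(
        np.column_stack([series.times_min, series.fractions]), columns=_COMP_COLS
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_composition_csv(path, start=None, label=None) -> CompositionSeries:
    df = pd.read_csv(path)
    if list(df.columns) != _COMP_COLS:
        raise FormatError(
            f"{path}: expected header {','.join(_COMP_COLS)}, got {','.join(df.columns)}"
        )
    return CompositionSeries.normalized(
        df["time_min"].to_numpy(),
        df[["xA", "xB", "xC", "xD"]].to_numpy(),
        start=as_isomer(start) if start else None,
        label=label or str(path),
    )


def write_matrix_csv(matrix, path) -> None:
    arr = matrix.M if isinstance(matrix, TransitionMatrix) else (
        matrix.phi if isinstance(matrix, QuantumYieldMatrix) else np.asarray(matrix, float)
    )
    labels = [i.value for i in ISOMERS]
    pd.DataFrame(arr, index=labels, columns=labels).to_csv(path, float_format=_FLOAT_FMT)


def read_matrix_csv(path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    labels = [i.value for i in ISOMERS]
    if list(df.columns) != labels or list(df.index) != labels:
        raise FormatError(f"{path}: expected A-D row/column labels")
    return df.to_numpy(dtype=float)


def write_thermal_csv(times_s, x_start, path) -> None:
    x = np.asarray(x_start, float)
    df = pd.DataFrame({"time_s": np.asarray(times_s, float), "x_start": x, "x_other": 1.0 - x})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_thermal_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "x_start", "x_other"]:
        raise FormatError(f"{path}: expected header time_s,x_start,x_other")
    return df["time_s"].to_numpy(), df["x_start"].to_numpy()


def write_spectra_csv(series: SpectraSeries, path) -> None:
    data = {"wavelength_nm": series.wavelengths_nm}
    for label, row in zip(series.times, series.absorbance):
        data[str(label)] = row
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra_csv(path) -> SpectraSeries:
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm" or df.shape[1] < 2:
        raise FormatError(f"{path}: expected wavelength_nm plus one column per time")
    return SpectraSeries(
        df["wavelength_nm"].to_numpy(),
        df.iloc[:, 1:].to_numpy(dtype=float).T,
        times=tuple(df.columns[1:]),
    )


def write_conditions_json(cond: PhotoConditions, path) -> None:
    write_json(cond.to_dict(), path)


def read_conditions_json(path) -> PhotoConditions:
    with open(path) as fh:
        try:
            return PhotoConditions.from_dict(json.load(fh))
        except (KeyError, TypeError) as exc:
            raise FormatError(f"{path}: malformed conditions file ({exc})") from exc


def write_manifest(entries: list[dict], path, **extra) -> None:
    """Manifest naming each series file, its starting isomer, and label."""
    write_json({"series": entries, **extra}, path)


def read_manifest(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if "series" not in doc or not isinstance(doc["series"], list):
        raise FormatError(f"{path}: manifest must contain a 'series' list")
    return doc


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
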