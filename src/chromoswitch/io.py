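"""CSV dialects and strict, lossless table IO.

All files are plain UTF-8 CSV with '.' decimal, a mandatory header and
exactly the documented columns:

* spectra:          ``wavelength_nm,eps_E,eps_Z``      (wavelength sorted)
* response trace:   ``time_s,fz,effect,segment_id``    (time sorted)
* dose–response:    ``conc_M,response,replicate``
* action spectrum:  ``wavelength_nm,bioactivity,conc_M``

Malformed files raise :class:`CsvFormatError` with a descriptive message.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pharm import DoseResponseSet
from .photochem import IsomerSpectrumPair
from .simulate import ActionSpectrumSet, ResponseTrace

__all__ = [
    "CsvFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_trace_csv",
    "write_trace_csv",
    "read_doseresp_csv",
    "write_doseresp_csv",
    "read_actionspec_csv",
    "write_actionspec_csv",
]

SPECTRA_COLUMNS = ("wavelength_nm", "eps_E", "eps_Z")
TRACE_COLUMNS = ("time_s", "fz", "effect", "segment_id")
DOSERESP_COLUMNS = ("conc_M", "response", "replicate")
ACTIONSPEC_COLUMNS = ("wavelength_nm", "bioactivity", "conc_M")


class CsvFormatError(ValueError):
    """Raised for missing/extra columns, non-numeric cells or bad ordering."""


def _read_table(path, columns: tuple[str, ...], sorted_col: str | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise CsvFormatError(f"{path}: empty file (header required)") from None
    got = tuple(frame.columns)
    if set(got) != set(columns):
        raise CsvFormatError(
            f"{path}: expected columns {list(columns)}, got {list(got)}"
        )
    frame = frame[list(columns)]
    if len(frame) == 0:
        raise CsvFormatError(f"{path}: table has a header but no rows")
    for col in columns:
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            bad = frame[col][values.isna()].iloc[0]
            raise CsvFormatError(f"{path}: non-numeric value {bad!r} in column {col!r}")
        frame[col] = values
    if sorted_col is not None:
        v = frame[sorted_col].to_numpy(float)
        if np.any(np.diff(v) < 0):
            raise CsvFormatError(f"{path}: column {sorted_col!r} must be sorted ascending")
    return frame


def _write_table(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_spectra_csv(path) -> IsomerSpectrumPair:
    frame = _read_table(path, SPECTRA_COLUMNS, sorted_col="wavelength_nm")
    return IsomerSpectrumPair(
        wavelengths=frame["wavelength_nm"].to_numpy(float),
        eps_E=frame["eps_E"].to_numpy(float),
        eps_Z=frame["eps_Z"].to_numpy(float),
    )


def write_spectra_csv(spectra: IsomerSpectrumPair, path) -> None:
    _write_table(
        pd.DataFrame(
            {
                "wavelength_nm": spectra.wavelengths,
                "eps_E": spectra.eps_E,
                "eps_Z": spectra.eps_Z,
            }
        ),
        path,
    )


def read_trace_csv(path) -> ResponseTrace:
    frame = _read_table(path, TRACE_COLUMNS, sorted_col="time_s")
    return ResponseTrace.from_frame(frame)


def write_trace_csv(trace: ResponseTrace, path) -> None:
    _write_table(trace.to_frame(), path)


def read_doseresp_csv(path) -> DoseResponseSet:
    frame = _read_table(path, DOSERESP_COLUMNS)
    frame["replicate"] = frame["replicate"].astype(int)
    return DoseResponseSet(table=frame)


def write_doseresp_csv(data: DoseResponseSet, path) -> None:
    _write_table(data.table[list(DOSERESP_COLUMNS)], path)


def read_actionspec_csv(path) -> ActionSpectrumSet:
    frame = _read_table(path, ACTIONSPEC_COLUMNS)
    return ActionSpectrumSet(table=frame)


def write_actionspec_csv(data: ActionSpectrumSet, path) -> None:
    _write_table(data.table[list(ACTIONSPEC_COLUMNS)], path)
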