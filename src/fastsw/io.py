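"""Delimited-text signal and segment files.

One dialect for everything: UTF-8 comma-separated text with a header row.
Quaternion streams use columns ``t,qw,qx,qy,qz``; generic D-channel signals
use ``t,v1,...,vD``.  Floats are written with 17 significant digits, so a
write-read round trip is bitwise exact.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import TimestampOrderError
from .signal import SegmentSeries, Signal

__all__ = [
    "read_signal",
    "write_signal",
    "read_segments",
    "write_segments",
]

log = logging.getLogger("fastsw")

_QUAT_COLUMNS = ["t", "qw", "qx", "qy", "qz"]


def _columns_for(ndim: int) -> list[str]:
    if ndim == 4:
        return _QUAT_COLUMNS
    return ["t"] + [f"v{d}" for d in range(1, ndim + 1)]


def _read_table(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:
        raise ValueError(f"{path}: malformed delimited text ({exc})") from exc
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need a timestamp column plus at least one value column")
    if frame.columns[0] != "t":
        raise ValueError(f"{path}: first column must be 't', got {frame.columns[0]!r}")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric cell in column {col!r} at line {row}")
        if numeric.isna().any():
            row = int(np.argmax(numeric.isna().to_numpy())) + 2
            raise ValueError(f"{path}: missing cell in column {col!r} at line {row}")
        frame[col] = numeric
    return frame


def _check_monotone(path, t: np.ndarray) -> None:
    if len(t) > 1:
        diffs = np.diff(t)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 3  # header + one-based + offset row
            raise TimestampOrderError(
                f"{path}: timestamps not strictly increasing at line {row}"
            )


def read_signal(path, quaternion: bool | None = None, renormalize: bool = False) -> Signal:
    """Read a signal file.

    ``quaternion=True`` insists on exactly four value columns.  When the file
    is (or is declared) a quaternion stream and any row's norm is off unity
    by more than 1e-6, a warning is issued; with ``renormalize=True`` the
    rows are rescaled to unit norm instead.
    """
    frame = _read_table(path)
    t = frame["t"].to_numpy(dtype=float)
    values = frame.iloc[:, 1:].to_numpy(dtype=float)
    _check_monotone(path, t)
    if quaternion is True and values.shape[1] != 4:
        raise ValueError(
            f"{path}: expected a quaternion file with 4 value columns, found {values.shape[1]}"
        )
    is_quat = values.shape[1] == 4 if quaternion is None else quaternion
    if is_quat:
        norms = np.linalg.norm(values, axis=1)
        off = np.abs(norms - 1.0) > 1e-6
        if off.any():
            if renormalize:
                values = values / norms[:, None]
                log.info("%s: renormalized %d off-unit quaternion rows", path, int(off.sum()))
            else:
                warnings.warn(
                    f"{path}: {int(off.sum())} rows deviate from unit norm by more than 1e-6",
                    stacklevel=2,
                )
    return Signal(t, values)


def write_signal(path, signal: Signal) -> None:
    """Write a signal as delimited text (exact round trip)."""
    frame = pd.DataFrame(
        np.column_stack([signal.timestamps, signal.values]),
        columns=_columns_for(signal.values.shape[1]),
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def write_segments(path, series: SegmentSeries) -> None:
    """Write a segment-point series; the source length rides in a comment header."""
    ndim = series.values.shape[1] if len(series) else 4
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# source_length={series.source_length}\n")
        fh.write(",".join(_columns_for(ndim)) + "\n")
        for i in range(len(series)):
            row = [series.timestamps[i], *series.values[i]]
            fh.write(",".join(format(x, ".17g") for x in row) + "\n")


def read_segments(path) -> SegmentSeries:
    """Read a segment-point series written by :func:`write_segments`."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    source_length = 0
    skip = 0
    if first.startswith("#"):
        skip = 1
        try:
            source_length = int(first.strip().split("=", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed header comment {first!r}") from exc
    frame = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if frame.shape[1] < 2 or frame.columns[0] != "t":
        raise ValueError(f"{path}: not a segment file (missing 't' column)")
    t = frame["t"].to_numpy(dtype=float)
    values = frame.iloc[:, 1:].to_numpy(dtype=float)
    _check_monotone(path, t)
    return SegmentSeries(
        timestamps=t,
        values=values,
        source_length=source_length if source_length else len(t),
    )
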