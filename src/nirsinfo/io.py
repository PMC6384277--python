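"""Reading and writing of multichannel recordings and skin-blood-flow traces.

Recordings are plain delimited text (comma or tab, auto-detected from the
header line): one header row naming the channels, an optional leading time
column, one row per sample.  Values are arbitrary device units; the sample
index is authoritative and the sampling rate is supplied by the caller or
the study configuration.
"""

from __future__ import annotations

import dataclasses
import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SBFTrace",
    "RecordingError",
    "read_recording",
    "write_recording",
    "read_sbf",
    "write_sbf",
]

#: column names treated as a time axis and excluded from the data matrix
TIME_COLUMNS = ("time", "t", "seconds", "sec", "time_s")


class RecordingError(ValueError):
    """Raised for malformed recording files or invalid recording invariants."""


@dataclass
class Recording:
    """A multichannel time series with a designated resting prefix.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Sample matrix, rows are time points.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per column, e.g. ``["Left1", "Left3", "Right1", "Right3"]``.
    rest_len : int
        Number of leading samples recorded at rest (used for baseline
        normalisation and for fitting the PCA spatial filter).
    source_detector_cm : list of float, optional
        Per-channel optode separation in cm.
    meta : dict
        Free-form provenance (applied preprocessing steps etc.); not part of
        equality comparisons.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = None
    rest_len: int = 0
    source_detector_cm: list[float] | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise RecordingError("data must be a 2-D samples x channels matrix")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise RecordingError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
        if self.fs <= 0:
            raise RecordingError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise RecordingError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if not 0 <= self.rest_len < self.n_samples:
            raise RecordingError(
                f"rest_len={self.rest_len} outside [0, {self.n_samples})"
            )
        if self.source_detector_cm is not None and len(
            self.source_detector_cm
        ) != self.n_channels:
            raise RecordingError("source_detector_cm length must match channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def rest(self) -> np.ndarray:
        """The resting prefix, shape (rest_len, n_channels)."""
        return self.data[: self.rest_len]

    @property
    def task(self) -> np.ndarray:
        """The task portion (everything after the resting prefix)."""
        return self.data[self.rest_len :]

    def replace(self, **kw) -> "Recording":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kw)


@dataclass
class SBFTrace:
    """A scalar skin-blood-flow time series sampled alongside a Recording."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            bad = int(np.argwhere(~np.isfinite(self.values))[0])
            raise RecordingError(f"non-finite SBF value at row {bad}")
        if self.fs <= 0:
            raise RecordingError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.values)


def _detect_sep(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def _read_table(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such recording file: {path}")
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise RecordingError(f"{path}: empty file")
        sep = _detect_sep(header)
        body = header + fh.read()
    df = pd.read_csv(_io.StringIO(body), sep=sep)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.index[coerced.isna() & df[col].notna()]
            row = int(bad[0]) if len(bad) else int(df[col].index[df[col].isna()][0])
            raise RecordingError(
                f"{path}: non-numeric cell at row {row + 2}, column '{col}'"
            )
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().values)))
        raise RecordingError(
            f"{path}: missing/NaN cell at row {int(r) + 2}, "
            f"column '{df.columns[int(c)]}'"
        )
    return df


def _strip_time(df: pd.DataFrame) -> pd.DataFrame:
    if df.columns[0].strip().lower() in TIME_COLUMNS:
        return df.iloc[:, 1:]
    return df


def read_recording(path, rest_len: int, fs: float) -> Recording:
    """Read a delimited-text recording.

    The first column is dropped if its header names a time axis; remaining
    columns become channels in file order.
    """
    df = _strip_time(_read_table(path))
    if df.shape[1] == 0:
        raise RecordingError(f"{path}: no channel columns")
    return Recording(
        data=df.to_numpy(dtype=float),
        fs=fs,
        channel_labels=[str(c) for c in df.columns],
        rest_len=rest_len,
    )


def write_recording(rec: Recording, path, sep: str = ",") -> None:
    """Write a recording as delimited text with a leading time column.

    Values are written with 17 significant digits so that a read/write cycle
    round-trips to better than 1e-12 relative error.
    """
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(rec.data, columns=rec.channel_labels)
    df.insert(0, "time", t)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_sbf(path, fs: float) -> SBFTrace:
    """Read a single-column skin-blood-flow trace (time column optional)."""
    df = _strip_time(_read_table(path))
    if df.shape[1] != 1:
        raise RecordingError(
            f"{path}: SBF trace must have exactly one value column, "
            f"got {df.shape[1]}"
        )
    return SBFTrace(values=df.iloc[:, 0].to_numpy(dtype=float), fs=fs)


def write_sbf(trace: SBFTrace, path, sep: str = ",") -> None:
    t = np.arange(len(trace)) / trace.fs
    df = pd.DataFrame({"time": t, "sbf": trace.values})
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
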