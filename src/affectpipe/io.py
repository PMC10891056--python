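"""Mind-Monitor-style CSV input/output.

Two dialects are supported and auto-detected from the header:

* **raw** — columns ``TimeStamp, RAW_TP9, RAW_AF7, RAW_AF8, RAW_TP10``
  carrying raw samples; parsed into a :class:`~affectpipe.core.RawRecording`.
* **bandpower** — 20 columns ``Delta_TP9 … Gamma_TP10`` (5 bands x 4
  channels) carrying per-row band powers as exported by the app; parsed into
  a list of :class:`~affectpipe.core.EpochBandPowers`.  App exports are
  log-scaled (Bels); ``bandpower_scale="bels"`` (the default) exponentiates
  with ``10**x`` on read, ``"linear"`` leaves values untouched.

Unknown extra columns (gyroscope, contact quality, markers, ...) are ignored
with a logged warning; empty cells become NaN, never zeros.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BAND_NAMES,
    CHANNELS,
    DataError,
    DialectError,
    EpochBandPowers,
    FormatError,
    RawRecording,
    logger,
)

RAW_COLUMNS = tuple(f"RAW_{ch}" for ch in CHANNELS)
BANDPOWER_COLUMNS = tuple(
    f"{band.capitalize()}_{ch}" for band in BAND_NAMES for ch in CHANNELS
)
TIMESTAMP_COLUMN = "TimeStamp"

#: Columns a Mind-Monitor export may carry that we recognise but do not use.
_KNOWN_OPTIONAL_PREFIXES = (
    "Accelerometer", "Gyro", "HeadBandOn", "HSI", "Battery", "Elements", "Marker",
)


def _is_known(col: str) -> bool:
    if col == TIMESTAMP_COLUMN or col in RAW_COLUMNS or col in BANDPOWER_COLUMNS:
        return True
    return any(col.startswith(p) for p in _KNOWN_OPTIONAL_PREFIXES)


def _parse_timestamps(raw: pd.Series) -> np.ndarray:
    """Timestamps as epoch seconds; accepts numeric seconds or ISO strings."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if not numeric.isna().any():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(raw, errors="coerce", format="mixed")
    if parsed.isna().any():
        raise FormatError("timestamps are neither numeric seconds nor parseable datetimes")
    return parsed.astype("int64").to_numpy() / 1e9


def read_csv(
    path,
    *,
    participant_id: str = "",
    stage: str = "A",
    fs: float | None = None,
    bandpower_scale: str = "bels",
):
    """Read a Mind-Monitor-style CSV.

    Returns a :class:`RawRecording` (raw dialect) or a list of
    :class:`EpochBandPowers` (bandpower dialect).  ``fs`` overrides the rate
    inferred from the median timestamp spacing.

    Raises
    ------
    DialectError
        If the header matches no supported dialect; the message names the
        first unmatched column.
    FormatError
        If timestamps are not strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)

    unknown = [c for c in cols if not _is_known(c)]
    has_raw = all(c in cols for c in RAW_COLUMNS)
    has_bp = all(c in cols for c in BANDPOWER_COLUMNS)
    if not (has_raw or has_bp):
        first = unknown[0] if unknown else cols[0]
        raise DialectError(
            f"header matches no supported dialect; first unmatched column: {first!r}"
        )
    if unknown:
        logger.warning("%s: ignoring %d unrecognised column(s), e.g. %r",
                       path.name, len(unknown), unknown[0])
    if TIMESTAMP_COLUMN not in cols:
        raise DialectError(f"missing required column {TIMESTAMP_COLUMN!r}")

    ts = _parse_timestamps(df[TIMESTAMP_COLUMN])
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise FormatError("timestamps must be strictly increasing")
    if fs is None:
        if len(ts) < 2:
            raise DataError("cannot infer fs from fewer than two samples; pass fs=")
        fs = 1.0 / float(np.median(np.diff(ts)))

    def numeric(col: str) -> np.ndarray:
        # empty cells -> NaN (missing marker); never fabricate zeros.
        # numpy's str->float conversion is correctly rounded, so values
        # written with the shortest repr round-trip bit-exactly.
        raw = df[col].to_numpy(dtype=str)
        return np.where(raw == "", "nan", raw).astype(np.float64)

    if has_raw:
        samples = np.vstack([numeric(c) for c in RAW_COLUMNS])
        return RawRecording(participant_id, stage, fs, ts, samples)

    powers = np.stack(
        [[numeric(f"{b.capitalize()}_{ch}") for ch in CHANNELS] for b in BAND_NAMES]
    )  # (5, 4, n)
    if bandpower_scale == "bels":
        powers = np.power(10.0, powers)
    elif bandpower_scale != "linear":
        raise DataError(f"bandpower_scale must be 'bels' or 'linear', got {bandpower_scale!r}")
    return [
        EpochBandPowers(participant_id, stage, i, powers[:, :, i], fs)
        for i in range(powers.shape[2])
    ]


def _fmt_sample(v: float) -> str:
    if math.isnan(v):
        return ""
    return repr(float(v))


def write_csv(recording: RawRecording, path) -> Path:
    """Write a raw-dialect CSV: header plus one row per sample.

    Timestamps are written at millisecond precision; samples with the
    shortest round-tripping decimal representation; missing samples as empty
    fields.  One read/write cycle is idempotent (byte-identical files).
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow([TIMESTAMP_COLUMN, *RAW_COLUMNS])
        for i in range(recording.n_samples):
            w.writerow(
                [f"{recording.timestamps[i]:.3f}"]
                + [_fmt_sample(recording.samples[ch, i]) for ch in range(len(CHANNELS))]
            )
    return path
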