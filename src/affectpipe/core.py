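"""Shared containers, band definitions and error types for the affect pipeline.

The pipeline operates on 4-channel Muse-style recordings (electrodes TP9,
AF7, AF8, TP10; AF7/AF8 are the left/right frontal sites used for the
asymmetry metrics).  Missing samples are represented as NaN in memory and as
empty fields on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("affectpipe")

#: Channel order used everywhere: index 0..3.
CHANNELS: tuple[str, ...] = ("TP9", "AF7", "AF8", "TP10")

#: Left / right frontal electrodes (indices into CHANNELS).
FRONTAL_LEFT = "AF7"
FRONTAL_RIGHT = "AF8"
FRONTAL_LEFT_IDX = CHANNELS.index(FRONTAL_LEFT)
FRONTAL_RIGHT_IDX = CHANNELS.index(FRONTAL_RIGHT)

STAGES: tuple[str, ...] = ("A", "B", "C")


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class AffectPipeError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(AffectPipeError, ValueError):
    """Invalid parameter combination (e.g. band edge above Nyquist)."""


class DataError(AffectPipeError, ValueError):
    """Input data violates a precondition (e.g. fully-missing channel)."""


class DialectError(DataError):
    """CSV header does not match any supported Mind-Monitor dialect."""


class FormatError(DataError):
    """CSV content is malformed (e.g. non-monotone timestamps)."""


class OrderingError(AffectPipeError, RuntimeError):
    """Pipeline stages called out of order (e.g. filtering before imputation)."""


class ConvergenceError(AffectPipeError, RuntimeError):
    """Iterative decomposition failed to converge."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


# --------------------------------------------------------------------------
# Frequency bands
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high})"
            )


#: The five canonical EEG bands (Hz); non-overlapping, ordered, with small
#: gaps at 7.5-8, 13-14 and 29-30 Hz kept as defined (no renormalisation).
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 7.5),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 14.0, 29.0),
    BandSpec("gamma", 30.0, 45.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
ALPHA_IDX = BAND_NAMES.index("alpha")
BETA_IDX = BAND_NAMES.index("beta")


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Timestamped 4-channel EEG samples; NaN marks a missing sample.

    Parameters
    ----------
    participant_id : str
    stage : str
        One of ``"A"``, ``"B"``, ``"C"`` (free-form accepted).
    fs : float
        Sampling rate, samples/s.
    timestamps : ndarray, shape (n,)
        Seconds; strictly increasing.
    samples : ndarray, shape (4, n)
        Channel order TP9, AF7, AF8, TP10.
    """

    participant_id: str
    stage: str
    fs: float
    timestamps: np.ndarray
    samples: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DataError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(CHANNELS):
            raise DataError(
                f"samples must be 4 x n (channels {CHANNELS}), got {self.samples.shape}"
            )
        n = self.samples.shape[1]
        if n < 1:
            raise DataError("recording must contain at least one sample")
        if self.timestamps.shape != (n,):
            raise DataError("timestamps length must match number of samples")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise FormatError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def has_missing(self) -> bool:
        return bool(np.isnan(self.samples).any())

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.participant_id,
            self.stage,
            self.fs,
            self.timestamps.copy(),
            self.samples.copy(),
        )


@dataclass
class EpochedRecording:
    """Contiguous, non-overlapping fixed-length epochs of a cleaned recording."""

    participant_id: str
    stage: str
    fs: float
    epoch_len: float
    epochs: np.ndarray          # (n_epochs, 4, samples_per_epoch)
    start_times: np.ndarray     # (n_epochs,) seconds

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.start_times = np.asarray(self.start_times, dtype=float)
        if self.epochs.ndim != 3 or self.epochs.shape[1] != len(CHANNELS):
            raise DataError(f"epochs must be (n, 4, m), got {self.epochs.shape}")
        if np.isnan(self.epochs).any():
            raise DataError("epochs must not contain missing samples")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class EpochBandPowers:
    """Band-power matrix for one 1-s (by default) epoch.

    ``power[i, j]`` is the power of band ``BAND_NAMES[i]`` on channel
    ``CHANNELS[j]``; all entries are nonnegative.
    """

    participant_id: str
    stage: str
    epoch_index: int
    power: np.ndarray           # (5, 4)
    fs: float

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(BAND_NAMES), len(CHANNELS)):
            raise DataError(
                f"power must be {len(BAND_NAMES)} x {len(CHANNELS)}, got {self.power.shape}"
            )

    def get(self, band: str, channel: str) -> float:
        return float(self.power[BAND_NAMES.index(band), CHANNELS.index(channel)])


@dataclass
class ParticipantMeta:
    """Cohort metadata for one participant."""

    id: str
    gender: str                 # "female" | "male"
    university: str             # "state" | "private"
    stage_order: str            # permutation of "ABC"
    tool_preference: str        # "3D" | "2D-digital" | "2D-manual"

    def __post_init__(self):
        if sorted(self.stage_order) != ["A", "B", "C"]:
            raise DataError(f"stage_order must be a permutation of ABC, got {self.stage_order!r}")


GENDERS: tuple[str, ...] = ("female", "male")
UNIVERSITIES: tuple[str, ...] = ("state", "private")
TOOL_PREFERENCES: tuple[str, ...] = ("3D", "2D-digital", "2D-manual")
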