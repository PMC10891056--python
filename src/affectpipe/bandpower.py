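"""Welch power spectral density and canonical band-power extraction.

For the default 1 s epochs at 256 samples/s the Welch estimate degenerates
to a single Hamming-windowed periodogram (segment length = one epoch); this
matches the per-second feature cadence of the analysis.  Longer epochs get
genuine segment averaging (segment length capped at one second, 50%
overlap).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import (
    BAND_NAMES,
    BandSpec,
    CANONICAL_BANDS,
    CHANNELS,
    ConfigurationError,
    EpochBandPowers,
    EpochedRecording,
)


def welch_psd(
    samples: np.ndarray,
    fs: float,
    segment_len: int | None = None,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of a single-channel epoch.

    ``segment_len`` defaults to ``min(len(samples), fs)`` samples with a
    Hamming window and 50% overlap.  Returns ``(frequencies, psd)`` with the
    PSD in power per Hz, nonnegative on a 0..fs/2 grid.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ConfigurationError("welch_psd expects a 1-D array")
    if segment_len is None:
        segment_len = min(len(samples), int(round(fs)))
    if segment_len > len(samples):
        raise ConfigurationError(
            f"segment_len {segment_len} exceeds epoch length {len(samples)}"
        )
    if not 0 <= overlap < 1:
        raise ConfigurationError(f"overlap must be in [0, 1), got {overlap}")
    f, psd = signal.welch(
        samples,
        fs=fs,
        window="hamming",
        nperseg=segment_len,
        noverlap=int(overlap * segment_len),
    )
    return f, psd


def band_power(frequencies: np.ndarray, psd: np.ndarray, band: BandSpec) -> float:
    """Integrate the PSD over ``band`` (trapezoidal rule).

    Interior grid points are selected half-open ``[low, high)``; the PSD is
    linearly interpolated at the exact band edges so the integral runs from
    ``low`` to ``high`` (a flat PSD of height h over an L-Hz band yields
    exactly L*h).  The canonical bands are disjoint, so no spectral mass is
    counted twice.
    """
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(psd, dtype=float)
    if band.low >= f[-1] or band.high <= f[0]:
        raise ConfigurationError(
            f"band [{band.low}, {band.high}) has no overlap with the grid "
            f"[{f[0]}, {f[-1]}]"
        )
    lo = max(band.low, float(f[0]))
    hi = min(band.high, float(f[-1]))
    inner = f[(f > lo) & (f < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, f, p)
    return float(max(np.trapezoid(vals, grid), 0.0))


def extract_band_powers(
    epoched: EpochedRecording,
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS,
    segment_len: int | None = None,
    overlap: float = 0.5,
) -> list[EpochBandPowers]:
    """Per-epoch band x channel power matrices (one 5 x 4 matrix per epoch)."""
    out: list[EpochBandPowers] = []
    for ei in range(epoched.n_epochs):
        power = np.zeros((len(bands), len(CHANNELS)))
        for ci in range(len(CHANNELS)):
            f, psd = welch_psd(epoched.epochs[ei, ci], epoched.fs, segment_len, overlap)
            for bi, band in enumerate(bands):
                power[bi, ci] = band_power(f, psd, band)
        out.append(
            EpochBandPowers(epoched.participant_id, epoched.stage, ei, power, epoched.fs)
        )
    return out


def band_powers_frame(bps: list[EpochBandPowers]):
    """Long-format DataFrame: participant_id, stage, epoch, band, channel, power."""
    import pandas as pd

    rows = []
    for bp in bps:
        for bi, band in enumerate(BAND_NAMES):
            for ci, ch in enumerate(CHANNELS):
                rows.append(
                    (bp.participant_id, bp.stage, bp.epoch_index, band, ch, bp.power[bi, ci])
                )
    return pd.DataFrame(
        rows, columns=["participant_id", "stage", "epoch", "band", "channel", "power"]
    )
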