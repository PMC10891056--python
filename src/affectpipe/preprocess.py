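"""Cleaning of raw recordings: imputation, bandpass filtering, ICA, epoching.

The enforced order is impute -> filter -> ICA -> epoch: the filter and the
decomposition require gap-free signals, so calling them on a recording that
still carries missing markers raises :class:`~affectpipe.core.OrderingError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core import (
    CHANNELS,
    ConfigurationError,
    ConvergenceError,
    DataError,
    EpochedRecording,
    FRONTAL_LEFT_IDX,
    FRONTAL_RIGHT_IDX,
    OrderingError,
    RawRecording,
    logger,
)


def impute_missing(recording: RawRecording, window: int = 129) -> RawRecording:
    """Replace missing samples by a centered moving average of valid neighbours.

    Each missing sample becomes the mean of the non-missing samples inside a
    centered window of ``window`` samples (~0.5 s at 256 samples/s by
    default).  Windows containing no valid sample fall back to the mean of
    the nearest valid neighbour on each side.  Non-missing samples are left
    untouched, so the operation is idempotent.

    Raises
    ------
    DataError
        If a channel has no valid sample at all (names the channel).
    """
    if window < 1:
        raise ConfigurationError(f"window must be >= 1, got {window}")
    out = recording.copy()
    hw = window // 2
    n = out.n_samples
    for ci, ch in enumerate(CHANNELS):
        x = out.samples[ci]
        valid = ~np.isnan(x)
        if not valid.any():
            raise DataError(f"channel {ch} is entirely missing")
        if valid.all():
            continue
        vals = np.where(valid, x, 0.0)
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        ccnt = np.concatenate([[0], np.cumsum(valid.astype(int))])
        valid_idx = np.flatnonzero(valid)
        for i in np.flatnonzero(~valid):
            lo, hi = max(0, i - hw), min(n, i + hw + 1)
            cnt = ccnt[hi] - ccnt[lo]
            if cnt > 0:
                x[i] = (csum[hi] - csum[lo]) / cnt
            else:
                # nearest valid neighbour(s) on each side
                pos = np.searchsorted(valid_idx, i)
                neigh = []
                if pos > 0:
                    neigh.append(x[valid_idx[pos - 1]])
                if pos < len(valid_idx):
                    neigh.append(x[valid_idx[pos]])
                x[i] = float(np.mean(neigh))
    return out


def bandpass_filter(
    recording: RawRecording, low: float = 0.5, high: float = 50.0
) -> RawRecording:
    """Zero-phase 4th-order Butterworth bandpass (applied forward-backward).

    Defaults to the 0.5-50 Hz analysis band.  Missing markers must be
    imputed first (raises :class:`OrderingError` otherwise); ``high`` at or
    above the Nyquist frequency raises :class:`ConfigurationError`.
    """
    if not 0 < low < high:
        raise ConfigurationError(f"need 0 < low < high, got ({low}, {high})")
    if high >= recording.fs / 2:
        raise ConfigurationError(
            f"high={high} Hz must be below Nyquist ({recording.fs / 2} Hz)"
        )
    if recording.has_missing():
        raise OrderingError("recording has missing samples; impute before filtering")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    out = recording.copy()
    out.samples = signal.sosfiltfilt(sos, out.samples, axis=1)
    return out


@dataclass
class ICAReport:
    """Which independent components were removed, and why."""

    flagged: list[int] = field(default_factory=list)
    criteria: dict[int, list[str]] = field(default_factory=dict)
    kurtosis: dict[int, float] = field(default_factory=dict)
    low_freq_fraction: dict[int, float] = field(default_factory=dict)


def remove_artifacts_ica(
    recording: RawRecording,
    kurtosis_threshold: float = 5.0,
    seed: int = 0,
    *,
    low_freq_fraction: float = 0.6,
    max_iter: int = 1000,
    tol: float = 1e-3,
) -> tuple[RawRecording, ICAReport]:
    """fastICA artifact removal on the four channels.

    The recording is decomposed into four independent components; a
    component is flagged when its excess kurtosis exceeds
    ``kurtosis_threshold`` (blink pulses are strongly super-Gaussian) or
    when more than ``low_freq_fraction`` of its power lies below 4 Hz while
    its mixing weights are frontal-dominant (ocular topography).  Flagged
    components are zeroed and the signal back-projected.  The flagged set is
    reproducible from ``seed``.
    """
    if recording.has_missing():
        raise OrderingError("recording has missing samples; impute before ICA")
    if recording.duration < 10.0:
        raise DataError(f"need >= 10 s for a stable decomposition, got {recording.duration:.1f} s")

    X = recording.samples.T  # (n, 4)
    ica = FastICA(
        n_components=len(CHANNELS),
        random_state=seed,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise ConvergenceError(
                f"fastICA did not converge within {max_iter} iterations", n_iter=max_iter
            )

    A = ica.mixing_  # (4, 4)
    report = ICAReport()
    frontal = (FRONTAL_LEFT_IDX, FRONTAL_RIGHT_IDX)
    temporal = tuple(i for i in range(len(CHANNELS)) if i not in frontal)
    for j in range(S.shape[1]):
        hit: list[str] = []
        k = float(stats.kurtosis(S[:, j]))  # excess kurtosis
        f, psd = signal.welch(S[:, j], fs=recording.fs,
                              nperseg=min(len(S), int(recording.fs) * 4))
        total = np.trapezoid(psd, f)
        lowfrac = float(np.trapezoid(psd[f <= 4.0], f[f <= 4.0]) / total) if total > 0 else 0.0
        report.kurtosis[j] = k
        report.low_freq_fraction[j] = lowfrac
        if k > kurtosis_threshold:
            hit.append("kurtosis")
        frontal_dominant = np.abs(A[list(frontal), j]).sum() > np.abs(A[list(temporal), j]).sum()
        if lowfrac > low_freq_fraction and frontal_dominant:
            hit.append("low_frequency_frontal")
        if hit:
            report.flagged.append(j)
            report.criteria[j] = hit

    out = recording.copy()
    if report.flagged:
        S = S.copy()
        S[:, report.flagged] = 0.0
        out.samples = (S @ A.T + ica.mean_).T
        logger.info(
            "%s/%s: removed %d ICA component(s): %s",
            recording.participant_id, recording.stage, len(report.flagged), report.criteria,
        )
    return out, report


def epoch(recording: RawRecording, epoch_len: float = 1.0) -> EpochedRecording:
    """Cut the recording into contiguous non-overlapping ``epoch_len``-second epochs.

    The trailing partial epoch is discarded; a recording shorter than one
    epoch raises :class:`DataError`.
    """
    if recording.has_missing():
        raise OrderingError("recording has missing samples; impute before epoching")
    spe = int(round(epoch_len * recording.fs))
    if spe < 1:
        raise ConfigurationError(f"epoch_len {epoch_len} too short for fs {recording.fs}")
    n_epochs = recording.n_samples // spe
    if n_epochs < 1:
        raise DataError(
            f"recording ({recording.duration:.2f} s) shorter than one epoch ({epoch_len} s)"
        )
    used = n_epochs * spe
    epochs = recording.samples[:, :used].reshape(len(CHANNELS), n_epochs, spe).swapaxes(0, 1)
    starts = recording.timestamps[0] + np.arange(n_epochs) * epoch_len
    return EpochedRecording(
        recording.participant_id, recording.stage, recording.fs, epoch_len, epochs.copy(), starts
    )
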