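"""Synthetic Muse-style cohort generator with known, planted affective structure.

Signals are sums of band-limited Gaussian noise (filtered white noise, one
component per canonical band, each calibrated to a target band power), so
the spectrum is broadband like real EEG rather than a line spectrum.
Artifacts mimic the three dominant contaminants of consumer headband data:
eye-blink transients (frontal, low-frequency, high-amplitude), power-line
sinusoids, and contiguous sensor-dropout runs stored as missing samples.

The generator defines the study conditions: 32 participants, three 10-minute
design-task stages (A manual 2-D, B digital 2-D, C digital 3-D) in
counterbalanced order, 256 samples/s, cohort composition 19 female / 13
male, 17 state- / 15 private-university students, design-tool preferences
4 / 13 / 15 for 3-D / 2-D-digital / 2-D-manual.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import (
    BAND_NAMES,
    CANONICAL_BANDS,
    CHANNELS,
    ConfigurationError,
    DataError,
    FRONTAL_LEFT,
    FRONTAL_RIGHT,
    GENDERS,
    ParticipantMeta,
    RawRecording,
    STAGES,
    TOOL_PREFERENCES,
    UNIVERSITIES,
)

#: Canonical listing order of the six stage permutations.
PERMUTATIONS: tuple[str, ...] = ("ABC", "ACB", "BAC", "BCA", "CAB", "CBA")

# When n is not a multiple of 6, leftover participants (beyond the equal base
# count) are placed following the original counterbalancing table, whose two
# six-member groups were BCA and CBA; the remaining permutations follow in
# reverse canonical order.
_EXTRA_PRIORITY: tuple[str, ...] = ("BCA", "CBA", "CAB", "BAC", "ACB", "ABC")

_TOP_EDGE = max(b.high for b in CANONICAL_BANDS)


def counterbalance_orders(n_participants: int) -> list[str]:
    """Assign the six stage permutations to ``n_participants`` in balanced blocks.

    Full cycles are dealt in canonical order (ABC, ACB, BAC, BCA, CAB, CBA);
    once every permutation holds an equal base count, leftovers go to BCA and
    CBA first (the groups that carried the extra members in the study's
    counterbalancing table).  Group sizes differ by at most one; the result
    is deterministic and returned as contiguous blocks in canonical order.
    """
    if n_participants < 1:
        raise ValueError(f"n_participants must be >= 1, got {n_participants}")
    base, r = divmod(n_participants, 6)
    sizes = {p: base for p in PERMUTATIONS}
    extras = PERMUTATIONS[:r] if base == 0 else _EXTRA_PRIORITY[:r]
    for p in extras:
        sizes[p] += 1
    out: list[str] = []
    for p in PERMUTATIONS:
        out.extend([p] * sizes[p])
    return out


# --------------------------------------------------------------------------
# Signal synthesis
# --------------------------------------------------------------------------

def _band_noise(n: int, low: float, high: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-calibrated band-limited Gaussian noise of length n."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, white)


def synthesize_recording(
    band_targets: dict,
    duration: float,
    fs: float = 256.0,
    seed: int = 0,
    *,
    participant_id: str = "",
    stage: str = "A",
    t0: float = 0.0,
) -> RawRecording:
    """Synthesize a clean 4-channel recording with per-channel band powers.

    ``band_targets`` maps channel name -> {band name -> target power}; missing
    entries default to zero.  Per channel the signal is the sum over bands of
    band-limited Gaussian noise scaled so its variance equals the target, so
    Welch band powers approximate the targets (to within the band-edge
    roll-off of the synthesis filter).  Reproducible from ``seed``.
    """
    if fs < 2 * _TOP_EDGE:
        raise ConfigurationError(
            f"fs={fs} below twice the top band edge ({_TOP_EDGE} Hz)"
        )
    n = int(round(duration * fs))
    if n < 2 * fs:
        raise DataError(f"duration must cover at least 2 s, got {duration} s")
    for ch, targets in band_targets.items():
        if ch not in CHANNELS:
            raise DataError(f"unknown channel {ch!r}")
        for band, p in targets.items():
            if band not in BAND_NAMES:
                raise DataError(f"unknown band {band!r}")
            if p < 0:
                raise DataError(f"band-power target must be nonnegative, got {band}={p}")

    rng = np.random.default_rng(seed)
    samples = np.zeros((len(CHANNELS), n))
    for ci, ch in enumerate(CHANNELS):
        targets = band_targets.get(ch, {})
        for band in CANONICAL_BANDS:
            target = float(targets.get(band.name, 0.0))
            # draw even for zero targets so channel streams stay aligned
            noise = _band_noise(n, band.low, band.high, fs, rng)
            if target > 0:
                var = noise.var()
                samples[ci] += noise * np.sqrt(target / var)
    timestamps = t0 + np.arange(n) / fs
    return RawRecording(participant_id, stage, fs, timestamps, samples)


def inject_artifacts(
    recording: RawRecording,
    blink_rate: float = 0.0,
    dropout_fraction: float = 0.0,
    line_freq: float = 50.0,
    line_amp: float = 0.0,
    seed: int = 0,
) -> RawRecording:
    """Return a copy of ``recording`` with blink, line-noise and dropout artifacts.

    Blinks: Poisson-distributed events (``blink_rate`` per minute) on the
    frontal channels AF7/AF8 only, each a 400 ms raised-cosine pulse of
    amplitude five channel standard deviations and random polarity.
    Line noise: an additive sinusoid at ``line_freq`` on all channels.
    Dropouts: contiguous runs (exponential lengths, mean 0.5 s) replaced by
    missing markers on all channels until ``dropout_fraction`` of the sample
    columns is missing (final run truncated to land on the target).

    With all rates zero the output equals the input.
    """
    if not 0 <= dropout_fraction < 1:
        raise ValueError(f"dropout_fraction must be in [0, 1), got {dropout_fraction}")
    if blink_rate < 0:
        raise ValueError(f"blink_rate must be nonnegative, got {blink_rate}")
    out = recording.copy()
    n = out.n_samples
    fs = out.fs
    rng = np.random.default_rng(seed)

    if blink_rate > 0:
        n_blinks = rng.poisson(blink_rate * out.duration / 60.0)
        width = max(2, int(round(0.4 * fs)))
        pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / (width - 1)))
        frontal = [CHANNELS.index(FRONTAL_LEFT), CHANNELS.index(FRONTAL_RIGHT)]
        stds = {ci: max(out.samples[ci].std(), 1e-12) for ci in frontal}
        for _ in range(n_blinks):
            start = int(rng.integers(0, max(1, n - width)))
            polarity = 1.0 if rng.random() < 0.5 else -1.0
            for ci in frontal:
                out.samples[ci, start:start + width] += polarity * 5.0 * stds[ci] * pulse

    if line_amp != 0:
        tone = line_amp * np.sin(2 * np.pi * line_freq * out.timestamps)
        out.samples += tone[None, :]

    if dropout_fraction > 0:
        target = int(round(dropout_fraction * n))
        missing = np.zeros(n, dtype=bool)
        guard = 0
        while missing.sum() < target and guard < 10_000:
            guard += 1
            length = max(1, int(round(rng.exponential(0.5) * fs)))
            length = min(length, target - int(missing.sum()))
            if length <= 0:
                break
            start = int(rng.integers(0, max(1, n - length)))
            missing[start:start + length] = True
        out.samples[:, missing] = np.nan

    return out


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def default_stage_targets() -> dict:
    """Per-stage, per-channel band-power targets (arbitrary power units).

    The baseline follows the typical descending EEG band-power profile with a
    prominent alpha peak; all channels and stages share it, so any affective
    structure must be planted explicitly (see :class:`CohortConfig`).
    """
    baseline = {"delta": 2.0, "theta": 1.2, "alpha": 1.5, "beta": 0.8, "gamma": 0.3}
    return {s: {ch: dict(baseline) for ch in CHANNELS} for s in STAGES}


@dataclass
class CohortConfig:
    """Configuration for a synthetic cohort.

    Defaults mirror the study conditions: 32 participants, three 600 s
    stages at 256 samples/s, counterbalanced stage orders, a 50 Hz mains
    environment and mild blink/dropout contamination.  ``alpha_left_ratio``
    scales the AF7 alpha target relative to AF8 (planting frontal alpha
    asymmetry: ratio > 1 means left dominance, hence positive raw arousal);
    ``frontal_beta_gain_private`` multiplies the frontal beta targets of
    private-university participants (planting a group valence contrast).
    """

    n_participants: int = 32
    fs: float = 256.0
    stage_duration: float = 600.0
    stage_targets: dict = field(default_factory=default_stage_targets)
    blink_rate: float = 10.0            # events/min
    dropout_fraction: float = 0.02
    line_noise_freq: float = 50.0       # Hz
    line_noise_amplitude: float = 0.5   # signal units
    alpha_left_ratio: float = 1.0
    frontal_beta_gain_private: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.fs < 2 * _TOP_EDGE:
            raise ConfigurationError(f"fs must be >= {2 * _TOP_EDGE}")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")


def _quota(n: int, proportions: list[float]) -> list[int]:
    """Largest-remainder apportionment of n into len(proportions) groups."""
    raw = [n * p for p in proportions]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_metadata(n: int, rng: np.random.Generator) -> list[ParticipantMeta]:
    """Participant metadata with study-matching composition and counterbalanced orders."""
    orders = counterbalance_orders(n)
    genders = [g for g, c in zip(GENDERS, _quota(n, [19 / 32, 13 / 32])) for _ in range(c)]
    unis = [u for u, c in zip(UNIVERSITIES, _quota(n, [17 / 32, 15 / 32])) for _ in range(c)]
    prefs = [
        p for p, c in zip(TOOL_PREFERENCES, _quota(n, [4 / 32, 13 / 32, 15 / 32]))
        for _ in range(c)
    ]
    # decorrelate attributes from the order blocks
    genders = list(rng.permutation(genders))
    unis = list(rng.permutation(unis))
    prefs = list(rng.permutation(prefs))
    width = max(2, len(str(n)))
    return [
        ParticipantMeta(f"P{i + 1:0{width}d}", genders[i], unis[i], orders[i], prefs[i])
        for i in range(n)
    ]


def generate_cohort(config: CohortConfig):
    """Generate (metas, recordings) for a full synthetic cohort.

    ``recordings`` is a dict keyed by ``(participant_id, stage)``; every
    participant has one recording per stage with the planted per-stage
    band-power profile, blink/line/dropout artifacts, and a seed chain fully
    determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    metas = generate_metadata(config.n_participants, rng)
    seeds = rng.integers(0, 2**31, size=(config.n_participants, len(STAGES), 2))
    recordings: dict[tuple[str, str], RawRecording] = {}
    for i, meta in enumerate(metas):
        for si, stage in enumerate(STAGES):
            targets = copy.deepcopy(config.stage_targets[stage])
            if config.alpha_left_ratio != 1.0:
                targets[FRONTAL_LEFT]["alpha"] = (
                    config.alpha_left_ratio * targets[FRONTAL_RIGHT]["alpha"]
                )
            if meta.university == "private" and config.frontal_beta_gain_private != 1.0:
                for ch in (FRONTAL_LEFT, FRONTAL_RIGHT):
                    targets[ch]["beta"] *= config.frontal_beta_gain_private
            rec = synthesize_recording(
                targets,
                config.stage_duration,
                config.fs,
                int(seeds[i, si, 0]),
                participant_id=meta.id,
                stage=stage,
            )
            rec = inject_artifacts(
                rec,
                blink_rate=config.blink_rate,
                dropout_fraction=config.dropout_fraction,
                line_freq=config.line_noise_freq,
                line_amp=config.line_noise_amplitude,
                seed=int(seeds[i, si, 1]),
            )
            recordings[(meta.id, stage)] = rec
    return metas, recordings


def write_metadata_csv(metas: list[ParticipantMeta], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("participant_id,gender,university,stage_order,tool_preference\n")
        for m in metas:
            fh.write(f"{m.id},{m.gender},{m.university},{m.stage_order},{m.tool_preference}\n")


def read_metadata_csv(path) -> list[ParticipantMeta]:
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    return [
        ParticipantMeta(r.participant_id, r.gender, r.university, r.stage_order, r.tool_preference)
        for r in df.itertuples()
    ]
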