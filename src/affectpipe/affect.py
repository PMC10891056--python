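"""Arousal, valence, approach-withdrawal index and circumplex emotion labels.

The three per-epoch metrics come from the frontal electrodes (AF7 left,
AF8 right):

* raw arousal  = alpha(AF7) - alpha(AF8)                 (left-minus-right
  frontal alpha asymmetry; left-alpha dominance means positive arousal)
* raw valence  = mean frontal beta / mean frontal alpha  (beta/alpha ratio)
* AW index     = (alpha(AF8) - alpha(AF7)) / (alpha(AF8) + alpha(AF7)),
  bounded in [-1, 1]; positive values indicate approach motivation.

Arousal and valence are min-max normalized to [-1, 1] per series (one
series = one participant x stage), then mapped to an angle on Russell's
circumplex with valence on the horizontal axis and arousal on the vertical
axis, a quadrant label (LVLA/LVHA/HVLA/HVHA) and an 8-sector emotion word.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ALPHA_IDX,
    BETA_IDX,
    DataError,
    EpochBandPowers,
    FRONTAL_LEFT_IDX,
    FRONTAL_RIGHT_IDX,
    logger,
)

DEFAULT_EPS = 1e-12

QUADRANTS = ("LVLA", "LVHA", "HVLA", "HVHA")

#: 45-degree sectors of the circumplex, left-closed [lo, hi), listed from
#: -180 degrees.  The wheel's word set is a synthetic stand-in following the
#: conventional circumplex layout (pleasant at 0, activated at 90).
EMOTION_SECTORS: tuple[tuple[float, float, str], ...] = (
    (-180.0, -135.0, "sad"),
    (-135.0, -90.0, "depressed"),
    (-90.0, -45.0, "bored"),
    (-45.0, 0.0, "calm"),
    (0.0, 45.0, "happy"),
    (45.0, 90.0, "excited"),
    (90.0, 135.0, "angry"),
    (135.0, 180.0, "distressed"),
)

NEUTRAL_LABEL = "neutral"


def _frontal(values_by_channel: np.ndarray, agg: str) -> float:
    pair = (values_by_channel[FRONTAL_LEFT_IDX], values_by_channel[FRONTAL_RIGHT_IDX])
    if agg == "mean":
        return float(np.mean(pair))
    if agg == "sum":
        return float(np.sum(pair))
    raise DataError(f"frontal_agg must be 'mean' or 'sum', got {agg!r}")


def arousal_raw(bp: EpochBandPowers) -> float:
    """Left-minus-right frontal alpha power: alpha(AF7) - alpha(AF8)."""
    return float(bp.power[ALPHA_IDX, FRONTAL_LEFT_IDX] - bp.power[ALPHA_IDX, FRONTAL_RIGHT_IDX])


def valence_raw(bp: EpochBandPowers, eps: float = DEFAULT_EPS, frontal_agg: str = "mean") -> float:
    """Frontal beta over frontal alpha, with an epsilon floor on the denominator."""
    beta = _frontal(bp.power[BETA_IDX], frontal_agg)
    alpha = _frontal(bp.power[ALPHA_IDX], frontal_agg)
    if alpha < eps:
        logger.warning(
            "%s/%s epoch %d: frontal alpha below eps; valence floored",
            bp.participant_id, bp.stage, bp.epoch_index,
        )
    return beta / max(alpha, eps)


def aw_index(bp: EpochBandPowers, eps: float = DEFAULT_EPS) -> float:
    """Normalized right-minus-left frontal alpha: (alpha_R - alpha_L)/(alpha_R + alpha_L).

    In [-1, 1] for nonnegative powers; positive values mean right-alpha
    dominance, i.e. relatively greater *left* cortical activation (alpha is
    inversely related to activation) and hence approach motivation.
    """
    left = bp.power[ALPHA_IDX, FRONTAL_LEFT_IDX]
    right = bp.power[ALPHA_IDX, FRONTAL_RIGHT_IDX]
    return float((right - left) / (right + left + eps))


def normalize_series(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max map onto [-1, 1]: x -> 2(x - min)/(max - min) - 1.

    Constant series map to all zeros.  Returns the (min, max) record needed
    to invert the mapping.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DataError("cannot normalize an empty series")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x), (lo, hi)
    return 2.0 * (x - lo) / (hi - lo) - 1.0, (lo, hi)


def circumplex_angle(arousal: float, valence: float) -> float:
    """Quadrant-preserving angle (degrees) of the point (valence, arousal).

    Valence is the horizontal axis, arousal the vertical; the result lies in
    (-180, 180].  The origin has no direction: (0, 0) yields NaN (the
    undefined marker), not an exception.
    """
    if arousal == 0 and valence == 0:
        return math.nan
    theta = math.degrees(math.atan2(arousal, valence))
    if theta <= -180.0:
        theta = 180.0
    return theta


def quadrant_label(valence: float, arousal: float) -> str:
    """LV/HV x LA/HA label; ties at exactly zero go to the high side."""
    v = "HV" if valence >= 0 else "LV"
    a = "HA" if arousal >= 0 else "LA"
    return v + a


def emotion_label(theta_deg: float) -> str:
    """Map an angle to one of the 8 named 45-degree sectors.

    Sectors are left-closed [lo, hi); the angle is first reduced modulo 360
    into [-180, 180), so +180 falls in the sector starting at -180.  An
    undefined angle (NaN) yields the neutral label.
    """
    if theta_deg is None or (isinstance(theta_deg, float) and math.isnan(theta_deg)):
        return NEUTRAL_LABEL
    phi = ((theta_deg + 180.0) % 360.0) - 180.0
    idx = int((phi + 180.0) // 45.0)
    idx = min(max(idx, 0), len(EMOTION_SECTORS) - 1)
    return EMOTION_SECTORS[idx][2]


@dataclass
class AffectSample:
    """Per-epoch affect metrics and labels."""

    epoch_index: int
    arousal_raw: float
    valence_raw: float
    arousal: float
    valence: float
    aw: float
    theta_deg: float
    quadrant: str
    emotion: str


@dataclass
class AffectSeries:
    """Ordered affect samples for one participant x stage, plus the
    normalization record ((min, max) per metric) needed to invert it."""

    participant_id: str
    stage: str
    samples: list[AffectSample] = field(default_factory=list)
    normalization: dict = field(default_factory=dict)
    norm_scope: str = "stage"

    def __len__(self) -> int:
        return len(self.samples)

    def values(self, metric: str) -> np.ndarray:
        return np.array([getattr(s, metric) for s in self.samples], dtype=float)

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "stage": self.stage,
                "epoch": [s.epoch_index for s in self.samples],
                "arousal_raw": [s.arousal_raw for s in self.samples],
                "valence_raw": [s.valence_raw for s in self.samples],
                "arousal": [s.arousal for s in self.samples],
                "valence": [s.valence for s in self.samples],
                "aw": [s.aw for s in self.samples],
                "theta_deg": [s.theta_deg for s in self.samples],
                "quadrant": [s.quadrant for s in self.samples],
                "emotion": [s.emotion for s in self.samples],
            }
        )


def compute_affect_series(
    bps: list[EpochBandPowers],
    eps: float = DEFAULT_EPS,
    frontal_agg: str = "mean",
) -> AffectSeries:
    """Full per-epoch affect pipeline for one participant x stage.

    Raw metrics per epoch, arousal/valence min-max normalized over the
    series (each metric independently), then angles and labels from the
    normalized values.  Cardinality is preserved (one sample per epoch).
    """
    if not bps:
        raise DataError("compute_affect_series needs at least one epoch")
    ar_raw = np.array([arousal_raw(bp) for bp in bps])
    va_raw = np.array([valence_raw(bp, eps, frontal_agg) for bp in bps])
    aw = np.array([aw_index(bp, eps) for bp in bps])
    ar, ar_rec = normalize_series(ar_raw)
    va, va_rec = normalize_series(va_raw)
    series = AffectSeries(
        bps[0].participant_id,
        bps[0].stage,
        normalization={"arousal": ar_rec, "valence": va_rec},
    )
    for i, bp in enumerate(bps):
        theta = circumplex_angle(ar[i], va[i])
        series.samples.append(
            AffectSample(
                epoch_index=bp.epoch_index,
                arousal_raw=float(ar_raw[i]),
                valence_raw=float(va_raw[i]),
                arousal=float(ar[i]),
                valence=float(va[i]),
                aw=float(aw[i]),
                theta_deg=theta,
                quadrant=quadrant_label(va[i], ar[i]),
                emotion=emotion_label(theta),
            )
        )
    return series


def affect_frame(series_list: list[AffectSeries]):
    """Concatenate series into one long-format DataFrame."""
    import pandas as pd

    return pd.concat([s.frame() for s in series_list], ignore_index=True)
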