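# Methods

## The model

The pipeline estimates momentary affect from 4-channel EEG using frontal
asymmetry metrics. Only AF7 (left frontal) and AF8 (right frontal) enter the
affect formulas; TP9/TP10 are temporal electrodes and are carried through
preprocessing but not used in the metrics.

Per 1-second epoch, with `α(·)` and `β(·)` the alpha- and beta-band powers:

- **Arousal** `A = α(AF7) − α(AF8)`. Alpha power is inversely related to
  cortical activation, so this left-minus-right alpha difference indexes
  relative right-hemisphere activation.
- **Valence** `V = β_front / α_front`, the frontal beta/alpha ratio with
  `x_front = (x(AF7) + x(AF8))/2`. Using the sum instead of the mean changes
  nothing (the constant cancels); the aggregation is configurable
  (`frontal_agg`).
- **Approach–withdrawal** `AW = (α(AF8) − α(AF7)) / (α(AF8) + α(AF7) + ε)`,
  a normalized asymmetry bounded in [−1, 1]; positive values (right-alpha
  dominance, i.e. greater left activation) indicate approach motivation.

A and V are min–max normalized onto [−1, 1] **per series** (one participant
× stage × metric), because the downstream summaries compare emotional
dynamics within stages. The (min, max) record is stored so the mapping is
invertible. A constant series maps to all-zeros. Consequence worth being
explicit about: per-series normalization removes *level* differences
between participants — a participant who is uniformly higher in raw valence
looks identical after normalization. Group contrasts therefore expose a
`value_kind` switch; the normalized scale reflects within-series shape, the
raw scale preserves between-participant levels and is the one on which
planted group effects are recoverable.

The normalized pair is mapped to Russell's circumplex with valence on the
horizontal axis and arousal on the vertical axis. The angle uses the
two-argument arctangent `θ = atan2(A, V) ∈ (−180°, 180°]`: a single-argument
`arctan(A/V)` cannot distinguish opposite quadrants, and the per-quadrant
angles of the circumplex force the quadrant-preserving reading. The origin
has no direction and yields an undefined angle (NaN), labelled `neutral`.

Quadrant labels compose LV/HV (valence < 0 / ≥ 0) with LA/HA (arousal < 0 /
≥ 0); ties at exactly zero go to the high side, so the degenerate all-zero
series labels as HVHA. Emotion words come from eight 45° sectors,
left-closed `[lo, hi)`, reduced modulo 360° into [−180°, 180°): calm, happy,
excited, angry, distressed, sad, depressed, bored counter-clockwise from
−45°. The word set is a synthetic stand-in following the conventional
circumplex layout (pleasant at 0°, activated at 90°); the sector geometry,
not the vocabulary, is what the code depends on.

## Preprocessing

Order is enforced as impute → filter → ICA → epoch; later stages raise an
ordering error if missing markers remain.

- **Imputation**: each missing sample becomes the mean of valid samples in
  a centered 129-sample window (~0.5 s at 256 Hz); windows that are
  entirely missing fall back to the mean of the nearest valid neighbour on
  each side. Valid samples are never modified, so the operation is
  idempotent. A fully missing channel is an error (there is no spatial
  interpolation to fall back on with only four electrodes).
- **Bandpass**: 4th-order Butterworth, 0.5–50 Hz, applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase with 8th-order magnitude. Butterworth
  was chosen for its flat passband. Near recording boundaries the 0.5 Hz
  edge rings for a couple of seconds; measurements of stopband attenuation
  exclude a 3 s margin for this reason.
- **ICA**: scikit-learn fastICA into 4 components, fixed seed,
  `tol = 1e-3`, `max_iter = 1000`. A component is removed when its excess
  kurtosis exceeds 5 (blink pulses are strongly super-Gaussian) or when
  more than 60% of its power lies below 4 Hz *and* its mixing column is
  frontal-dominant (ocular topography). Thresholds are parameters and the
  removal report is returned and logged. Non-convergence raises an error
  carrying the iteration budget; the batch runner treats that as
  "skip artifact removal for this recording" with a warning, because
  mixtures that are close to Gaussian (as clean synthetic signals are) are
  genuinely unidentifiable for ICA and aborting a cohort run over one
  recording would be wrong.
- **Epochs**: contiguous, non-overlapping, aligned to the recording start;
  the trailing partial epoch is discarded. The per-second feature cadence
  is obtained with 1 s epochs; finer/coarser cadence is just `epoch_len`.
  (A sliding 4 s window with 1 s hop was considered and rejected: it would
  break the non-overlap invariant that the band-power cardinality
  contracts rely on.)

## Spectral estimation

Welch PSD with a Hamming window; segment length defaults to
`min(epoch, 1 s)` with 50% overlap, so a 1 s epoch degenerates to a single
windowed periodogram (documented and intentional — it is what a 1 Hz
feature cadence admits). Band power is the trapezoidal integral of the PSD
over the band, with interior grid points selected half-open `[low, high)`
and the PSD linearly interpolated at the exact edges, so a flat PSD of
height h over an L-Hz band integrates to exactly L·h. The five canonical
bands follow the conventional printed edges verbatim, including the gaps at
7.5–8, 13–14 and 29–30 Hz; no renormalization is applied, so the sum of
band powers is ≤ the total integrated PSD.

## Synthetic cohorts

The generator emulates the study conditions: 32 participants (19 female /
13 male, 17 state- / 15 private-university, tool preferences 4/13/15 for
3D / 2D-digital / 2D-manual), three 600 s stages at 256 samples/s (the
headband's nominal rate; the source study does not state it), stage orders
counterbalanced over the six permutations.

Counterbalancing deals full cycles in canonical order (ABC, ACB, BAC, BCA,
CAB, CBA); once every permutation holds an equal base count, leftover
participants go to BCA and CBA first — the groups that carried the extra
members in the original counterbalancing table — continuing CAB, BAC, ACB,
ABC. Group sizes differ by at most one for every n, and n = 32 reproduces
the study's (5, 5, 5, 6, 5, 6).

Signals are sums over bands of band-limited Gaussian noise: white noise →
4th-order Butterworth bandpass per band → scaled so the component variance
equals the target band power. This gives a broadband spectrum like real
EEG rather than a line spectrum. Calibration is stochastic: the Welch band
power of a 60 s synthesis lands within ±25% of the target on the mean over
≥10 seeds (band-edge roll-off of the synthesis filter biases it a few
percent low). Default band targets per channel are delta 2.0, theta 1.2,
alpha 1.5, beta 0.8, gamma 0.3 (arbitrary power units, the typical
descending EEG profile with a prominent alpha peak), identical across
channels and stages — so any affective structure is *planted explicitly*
via `alpha_left_ratio` (left/right frontal alpha ratio; >1 forces positive
raw arousal) and `frontal_beta_gain_private` (frontal beta multiplier for
private-university participants; >1 forces a group valence contrast).

Artifacts: blinks are 400 ms raised-cosine pulses on AF7/AF8 only, five
channel standard deviations in amplitude, random polarity, Poisson times
(default 10/min); line noise is an additive sinusoid (default 50 Hz,
amplitude 0.5); dropouts are contiguous runs (exponential lengths, mean
0.5 s) replaced by missing markers across all channels until the target
fraction (default 2%) is reached, mimicking headband non-contact.

What the generator does **not** emulate: 1/f spectral slope within bands,
inter-channel correlation of background activity, non-stationarity (drowsiness,
movement), muscle (EMG) contamination, and any genuine neural response to
the design tasks. Passing tests therefore demonstrate that the pipeline
recovers *planted spectral structure* under realistic contamination — not
that the affect metrics are valid measurements of human emotion.

## Clustering

Participants are clustered on per-stage mean normalized arousal and valence
(six features for three stages); an epoch-level mode can be assembled from
the exported affect tables. Distances are Euclidean, accumulated feature by
feature so results are bit-identical to the element-wise definition. The
agglomeration is implemented in-package via the Lance–Williams recurrence
because the tie-break is part of the contract: among equally close pairs,
the pair whose smallest original leaf indices sort lowest merges first.
Offered linkages are single, complete, average (default — the common choice
for Euclidean affect features) and Ward (on squared distances internally,
square-rooted heights); all four are monotone, so merge heights never
decrease (centroid/median linkage, which can invert, is deliberately not
offered). scipy's implementation is used in the test suite as an
independent cross-check, never as the implementation.

Flat cuts remove the k−1 highest merges; clusters are numbered by their
lowest-index member. When k is not given, it is chosen at the largest
relative gap between consecutive merge heights — a simple, deterministic
heuristic (the source analysis reports 4/5/4 clusters per stage without
stating a selection rule).

## Reporting

Quadrant proportions pool epochs (not participants) within a stage; a
participant-level variant is a trivial aggregation of the exported tables.
Group contrasts are means of per-participant means (so participants, not
epochs, are the units) and are descriptive only — no hypothesis tests are
attached, deliberately. The AW table reports each participant's mean AW
with university/gender tags and the majority quadrant (ties resolved in
LVLA < LVHA < HVLA < HVHA order). The pipeline runner stamps a manifest
(config, seed, linkage, feature columns, input hashes) and is byte-identical
across reruns of the same config.

## Numerical choices and degenerate inputs

- Missing marker: NaN in memory, empty field in CSV; the reader never
  fabricates values (missing count equals empty-cell count).
- CSV round-trips: samples are written with the shortest round-tripping
  decimal representation and parsed with correctly rounded conversion, so
  write → read → write is byte-identical; timestamps carry millisecond
  precision.
- ε-guards: valence and AW use `ε = 1e-12` denominators; a zero frontal
  alpha yields a large finite valence and a logged warning, not an
  exception.
- Degenerate series: constant metrics normalize to zero, label HVHA (tie
  rule), emotion `neutral` (undefined angle).
- Band-power CSVs imported from the headband app are log-scaled (Bels) by
  default and exponentiated on read (`bandpower_scale="linear"` disables
  this); the affect formulas operate on linear power.
- Problem sizes in tests and the acceptance script are scaled to what the
  checks need: 60 s recordings and 20-participant cohorts for planted-effect
  recovery, 7-point instances for exhaustive clustering oracles. The
  defaults of the generator itself remain the full study conditions
  (32 × 3 × 600 s).

## Known limitations

- The AF7/AF8 ↔ "frontal left/right" mapping is the only sensible one on
  this electrode set but is an interpretation, not a calibration.
- Per-series normalization makes normalized group contrasts insensitive to
  level effects (see above); use the raw scale for those questions.
- With four channels, ICA can separate at most four sources and cannot
  distinguish two artifacts that co-occur in one component; residual
  contamination after removal is expected.
- The emotion-word wheel is a stand-in; only sector geometry is tested.
- fs inference from written CSVs is quantized by the millisecond timestamp
  format (e.g. 256 Hz reads back as ≈250 Hz from rounded spacings); pass
  `fs=` explicitly when the rate is known.
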