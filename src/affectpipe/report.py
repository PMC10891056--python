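"""Cohort-level summaries and the end-to-end pipeline runner.

Summaries mirror the structure of a design-stage affect study: per-stage
quadrant proportions (epoch-pooled), descriptive group contrasts (state vs
private university, female vs male), per-participant approach-withdrawal
tables, and design-tool preference percentages.  No hypothesis tests are
attached: the contrasts are descriptive by design.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import affect as _affect
from . import bandpower as _bandpower
from . import cluster as _cluster
from . import io as _io
from . import preprocess as _preprocess
from . import synth as _synth
from .core import AffectPipeError, DataError, ParticipantMeta, STAGES, logger
from .affect import QUADRANTS, AffectSeries


@dataclass
class QuadrantSummary:
    """Epoch-pooled quadrant counts and proportions for one stage."""

    stage: str
    counts: dict
    proportions: dict
    total: int


def quadrant_proportions(series_list, stage: str) -> QuadrantSummary:
    """Pool all epochs of ``stage`` across participants and count quadrants."""
    counts = {q: 0 for q in QUADRANTS}
    total = 0
    for s in series_list:
        if s.stage != stage:
            continue
        for sample in s.samples:
            counts[sample.quadrant] += 1
            total += 1
    if total == 0:
        raise DataError(f"no epochs found for stage {stage!r}")
    proportions = {q: counts[q] / total for q in QUADRANTS}
    return QuadrantSummary(stage, counts, proportions, total)


@dataclass
class GroupContrast:
    """Per-group mean arousal/valence (means of per-participant means)."""

    grouping: str
    stage: str
    value_kind: str
    groups: dict  # group -> {"mean_arousal", "mean_valence", "n"}


def group_contrast(
    series_list,
    metas: list[ParticipantMeta],
    grouping: str,
    stage: str,
    value_kind: str = "normalized",
) -> GroupContrast:
    """Contrast per-participant mean arousal and valence between groups.

    ``grouping`` is ``"university"`` or ``"gender"``.  ``value_kind``
    selects the scale: ``"normalized"`` uses the per-series min-max values
    (shape of the series; level differences between participants are
    removed by construction), ``"raw"`` uses the raw metrics and preserves
    between-participant level differences.
    """
    if grouping not in ("university", "gender"):
        raise DataError(f"grouping must be 'university' or 'gender', got {grouping!r}")
    if value_kind not in ("normalized", "raw"):
        raise DataError(f"value_kind must be 'normalized' or 'raw', got {value_kind!r}")
    meta_by_id = {m.id: m for m in metas}
    a_field = "arousal" if value_kind == "normalized" else "arousal_raw"
    v_field = "valence" if value_kind == "normalized" else "valence_raw"
    per_group: dict[str, list[tuple[float, float]]] = {}
    for s in series_list:
        if s.stage != stage:
            continue
        if s.participant_id not in meta_by_id:
            raise DataError(f"no metadata for participant {s.participant_id!r}")
        g = getattr(meta_by_id[s.participant_id], grouping)
        per_group.setdefault(g, []).append(
            (float(np.mean(s.values(a_field))), float(np.mean(s.values(v_field))))
        )
    groups = {
        g: {
            "mean_arousal": float(np.mean([t[0] for t in pairs])),
            "mean_valence": float(np.mean([t[1] for t in pairs])),
            "n": len(pairs),
        }
        for g, pairs in per_group.items()
    }
    return GroupContrast(grouping, stage, value_kind, groups)


def preference_summary(metas: list[ParticipantMeta]) -> pd.DataFrame:
    """Counts and percentages per design-tool preference (3 decimal places)."""
    if not metas:
        raise DataError("preference_summary needs at least one participant")
    n = len(metas)
    rows = []
    from .core import TOOL_PREFERENCES

    for pref in TOOL_PREFERENCES:
        count = sum(1 for m in metas if m.tool_preference == pref)
        rows.append((pref, count, 100.0 * count / n))
    # full precision kept so percentages sum to 100; CSV export rounds to
    # 3 decimal places
    return pd.DataFrame(rows, columns=["tool_preference", "count", "percentage"])


def aw_by_group(series_list, metas: list[ParticipantMeta], stage: str) -> pd.DataFrame:
    """Per-participant mean AW with university/gender/majority-quadrant tags.

    Majority quadrant is by epoch count; ties break in the order
    LVLA < LVHA < HVLA < HVHA.
    """
    meta_by_id = {m.id: m for m in metas}
    rows = []
    for s in series_list:
        if s.stage != stage:
            continue
        if s.participant_id not in meta_by_id:
            raise DataError(f"no metadata for participant {s.participant_id!r}")
        m = meta_by_id[s.participant_id]
        counts = {q: 0 for q in QUADRANTS}
        for sample in s.samples:
            counts[sample.quadrant] += 1
        majority = max(QUADRANTS, key=lambda q: (counts[q], -QUADRANTS.index(q)))
        rows.append(
            (s.participant_id, stage, float(np.mean(s.values("aw"))),
             m.university, m.gender, majority)
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "stage", "mean_aw", "university", "gender",
                 "majority_quadrant"],
    )


# --------------------------------------------------------------------------
# End-to-end pipeline
# --------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "simulate": True,
    "cohort": {},               # CohortConfig field overrides
    "input_dir": None,          # used when simulate is false
    "preprocess": {"low": 0.5, "high": 50.0, "ica": True,
                   "kurtosis_threshold": 5.0, "impute_window": 129},
    "epoch_len": 1.0,
    "linkage": "average",
    "k": None,                  # None -> suggest_k
    "seed": 0,
}


class PipelineError(AffectPipeError):
    def __init__(self, stage_name: str, cause: Exception):
        super().__init__(f"pipeline stage {stage_name!r} failed: {cause}")
        self.stage_name = stage_name


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(config or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def process_recording(rec, pp_cfg: dict, epoch_len: float, seed: int) -> AffectSeries:
    """Single-recording path: impute -> filter -> (ICA) -> epoch -> powers -> affect."""
    rec = _preprocess.impute_missing(rec, window=int(pp_cfg.get("impute_window", 129)))
    rec = _preprocess.bandpass_filter(rec, low=pp_cfg.get("low", 0.5),
                                      high=pp_cfg.get("high", 50.0))
    if pp_cfg.get("ica", True):
        try:
            rec, _report = _preprocess.remove_artifacts_ica(
                rec, kurtosis_threshold=pp_cfg.get("kurtosis_threshold", 5.0), seed=seed
            )
        except _preprocess.ConvergenceError:
            # near-Gaussian mixtures are unidentifiable for ICA; keep the
            # filtered signal rather than aborting a whole cohort run
            logger.warning(
                "%s/%s: fastICA did not converge; skipping artifact removal",
                rec.participant_id, rec.stage,
            )
    epoched = _preprocess.epoch(rec, epoch_len)
    bps = _bandpower.extract_band_powers(epoched)
    return _affect.compute_affect_series(bps)


def run_pipeline(config, out_dir) -> Path:
    """Execute simulate/ingest -> preprocess -> band powers -> affect ->
    cluster -> report, writing figure-ready CSVs and a reproducibility
    manifest to ``out_dir``.  A fixed config (including seed) makes reruns
    byte-identical."""
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "inputs": {}}

    try:
        if cfg["simulate"]:
            cohort_cfg = _synth.CohortConfig(seed=int(cfg["seed"]), **cfg["cohort"])
            metas, recordings = _synth.generate_cohort(cohort_cfg)
        else:
            if not cfg["input_dir"]:
                raise DataError("input_dir required when simulate is false")
            input_dir = Path(cfg["input_dir"])
            metas = _synth.read_metadata_csv(input_dir / "metadata.csv")
            recordings = {}
            for m in metas:
                for stage in STAGES:
                    p = input_dir / f"{m.id}_{stage}.csv"
                    if not p.exists():
                        raise DataError(f"missing input file {p}")
                    manifest["inputs"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
                    recordings[(m.id, stage)] = _io.read_csv(
                        p, participant_id=m.id, stage=stage
                    )
    except AffectPipeError as e:
        raise PipelineError("ingest", e) from e

    try:
        rng = np.random.default_rng(int(cfg["seed"]) + 1)
        seeds = rng.integers(0, 2**31, size=len(recordings))
        series_list = []
        for i, ((pid, stage), rec) in enumerate(sorted(recordings.items())):
            series_list.append(
                process_recording(rec, cfg["preprocess"], float(cfg["epoch_len"]),
                                  int(seeds[i]))
            )
    except AffectPipeError as e:
        raise PipelineError("preprocess", e) from e

    try:
        _synth.write_metadata_csv(metas, out / "metadata.csv")
        _affect.affect_frame(series_list).to_csv(out / "affect.csv", index=False)

        qrows = []
        for stage in STAGES:
            qs = quadrant_proportions(series_list, stage)
            for q in QUADRANTS:
                qrows.append((stage, q, qs.counts[q], qs.proportions[q]))
        pd.DataFrame(qrows, columns=["stage", "quadrant", "count", "proportion"]).to_csv(
            out / "quadrant_summary.csv", index=False
        )

        crows = []
        for grouping in ("university", "gender"):
            for stage in STAGES:
                for kind in ("normalized", "raw"):
                    gc = group_contrast(series_list, metas, grouping, stage, kind)
                    for g, v in sorted(gc.groups.items()):
                        crows.append((grouping, stage, kind, g, v["mean_arousal"],
                                      v["mean_valence"], v["n"]))
        pd.DataFrame(
            crows,
            columns=["grouping", "stage", "value_kind", "group", "mean_arousal",
                     "mean_valence", "n"],
        ).to_csv(out / "group_contrasts.csv", index=False)

        pd.concat(
            [aw_by_group(series_list, metas, s) for s in STAGES], ignore_index=True
        ).to_csv(out / "aw_by_group.csv", index=False)
        preference_summary(metas).round({"percentage": 3}).to_csv(
            out / "preferences.csv", index=False
        )
    except AffectPipeError as e:
        raise PipelineError("report", e) from e

    try:
        X = _cluster.participant_feature_matrix(series_list)
        dist = _cluster.euclidean_distance_matrix(X)
        dend = _cluster.agglomerate(dist, linkage=cfg["linkage"])
        k = int(cfg["k"]) if cfg["k"] else _cluster.suggest_k(dend)
        assignment = _cluster.cut(dend, k)
        assignment.frame().to_csv(out / "clusters.csv", index=False)
        (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        manifest["clustering"] = {"linkage": cfg["linkage"], "k": k,
                                  "feature_columns": list(X.columns)}
    except AffectPipeError as e:
        raise PipelineError("cluster", e) from e

    manifest["n_participants"] = len(metas)
    manifest["n_recordings"] = len(recordings)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out)
    return out
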