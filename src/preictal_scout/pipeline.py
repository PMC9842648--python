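"""Per-seizure pipeline orchestration and cohort summaries.

``run_seizure`` chains preprocessing, feature extraction (up to three
groups), preparation, the embedding/clustering sweep, categorization,
preictal characterization and sleep-wake association, and returns a
JSON-serializable report plus a manifest sufficient to re-run the
analysis bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .analysis import (CategoryRules, ControlSpec, categorize,
                       characterize_preictal, make_control_interval,
                       sleepwake_association)
from .embedding import EmbeddingConfig, embed_and_select
from .features.network import extract_multivariate
from .features.univariate import extract_univariate, window_signal
from .prep import EmptyMatrixError, prepare
from .preprocess import (BadSegmentParams, EEGRecord, SeizureEvent,
                         SeizureRoster, build_analysis_window,
                         detect_bad_segments, filter_signal,
                         segment_and_rereference)

FEATURE_GROUPS = ("univariate_linear", "univariate_nonlinear", "multivariate")


@dataclass
class PipelineConfig:
    feature_groups: tuple = FEATURE_GROUPS
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    category_rules: CategoryRules = field(default_factory=CategoryRules)
    bad_segment_params: BadSegmentParams = field(
        default_factory=BadSegmentParams)
    sph_minutes: float = 10.0
    postictal_minutes: float = 30.0
    max_hours: float = 4.5
    rng_seed: int = 0

    def seeded(self, seed: int) -> "PipelineConfig":
        """Copy of the config with all stage seeds derived from ``seed``."""
        emb = dataclasses.replace(self.embedding, rng_seed=seed % (2 ** 31))
        return dataclasses.replace(self, rng_seed=seed, embedding=emb)


def _manifest(config: PipelineConfig, seizure_id) -> dict:
    return {
        "software_version": __version__,
        "seizure_id": seizure_id,
        "rng_seed": config.rng_seed,
        "config": _to_jsonable(dataclasses.asdict(config)),
    }


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _extract_group(group, windows, times, validity, fs, names):
    if group in ("univariate_linear", "univariate_nonlinear"):
        return extract_univariate(windows, times, validity, fs, names,
                                  group=group)
    if group == "multivariate":
        return extract_multivariate(windows, times, validity, fs)
    raise ValueError(f"unknown feature group: {group}")


def run_seizure(record: EEGRecord, roster: SeizureRoster,
                config: PipelineConfig,
                seizure: SeizureEvent | None = None,
                sleepwake=None,
                analysis_window=None,
                extra_artifact_mask: np.ndarray | None = None) -> dict:
    """Run the full pipeline for one seizure.

    ``sleepwake`` may be ``(vector, window_start_times)`` with one binary
    value (1 = wake) per 5-s window on the recording grid; it is aligned
    to the valid analysis windows by timestamp.  ``analysis_window``
    overrides the default pre-onset window (used for control intervals).
    ``extra_artifact_mask`` (per sample of ``record``) is OR-ed with the
    rule-based detector's mask — the hook for an external artifact
    classifier.
    """
    if seizure is None:
        # seizure whose onset coincides with the end of the recording
        candidates = [ev for ev in roster
                      if abs(ev.onset - record.end_time) < 1.0]
        if not candidates:
            raise ValueError("no roster seizure at the end of the recording")
        seizure = candidates[0]

    report = {"seizure_id": seizure.seizure_id, "groups": {},
              "status": "ok"}
    window = analysis_window
    if window is None:
        window = build_analysis_window(
            seizure, roster, sph_min=config.sph_minutes,
            postictal_min=config.postictal_minutes,
            max_hours=config.max_hours,
            available_start=record.start_time)
    report["effective_duration_hours"] = round(
        window.effective_duration_hours, 4)

    # crop to span, filter, artifact-mask, segment
    i0 = int(round((window.span[0] - record.start_time) * record.fs))
    i1 = int(round((window.span[1] - record.start_time) * record.fs))
    i0, i1 = max(i0, 0), min(i1, record.n_samples)
    cropped = EEGRecord(signal=record.signal[:, i0:i1], fs=record.fs,
                        channel_names=record.channel_names,
                        start_time=record.start_time + i0 / record.fs)
    filtered = filter_signal(cropped)
    mask = detect_bad_segments(filtered, config.bad_segment_params)
    if extra_artifact_mask is not None:
        mask = mask | np.asarray(extra_artifact_mask[i0:i1], dtype=bool)
    report["artifact_fraction"] = float(mask.mean())
    segments = segment_and_rereference(filtered)
    windows, times, validity = window_signal(
        segments, onset=seizure.onset, analysis=window,
        artifact_mask=mask, mask_t0=cropped.start_time, mask_fs=record.fs)
    report["n_windows"] = int(times.size)
    report["n_valid_windows"] = int(validity.sum())

    sw_aligned = None
    if sleepwake is not None:
        sw_vec, sw_times = sleepwake
        sw_aligned = _align_sleepwake(sw_vec, sw_times, times)

    for group in config.feature_groups:
        gr = {"group": group}
        try:
            fm = _extract_group(group, windows, times, validity,
                                record.fs, record.channel_names)
            prepared = prepare(fm)
            emb, sol = embed_and_select(prepared.values, config.embedding)
            cat = categorize(emb, sol, prepared.window_times,
                             config.category_rules)
            gr.update({
                "n_features": len(prepared.feature_names),
                "n_dropped_features": len(prepared.dropped_features),
                "method": sol.method,
                "embedding_params": list(sol.embedding_params),
                "dunn_index": (None if np.isnan(sol.dunn_index)
                               else float(sol.dunn_index)),
                "category": cat.category,
                "rule_trace": _to_jsonable(cat.rule_trace),
            })
            if cat.category in (3, 6):
                pi = characterize_preictal(sol, prepared.window_times,
                                           cat.preictal_cluster,
                                           config.category_rules)
                gr["preictal"] = {
                    "cluster_id": pi.cluster_id,
                    "start_before_onset_min": round(pi.start_before_onset, 4),
                    "duration_min": round(pi.duration, 4),
                    "density": round(pi.density, 4),
                    "ends_at_onset": pi.ends_at_onset,
                }
            if sw_aligned is not None and cat.category in (2, 3, 6):
                valid_rows = np.isin(times, prepared.window_times)
                assoc = sleepwake_association(sol, sw_aligned[valid_rows], cat)
                gr["sleepwake_phi"] = (None if np.isnan(assoc.phi)
                                       else round(float(assoc.phi), 4))
                gr["sleepwake_contingency"] = assoc.contingency.tolist()
        except EmptyMatrixError as err:
            gr.update({"status": "refused", "reason": str(err)})
        report["groups"][group] = gr

    report["manifest"] = _manifest(config, seizure.seizure_id)
    return _to_jsonable(report)


def _align_sleepwake(sw_vec, sw_times, window_times) -> np.ndarray:
    sw_vec = np.asarray(sw_vec)
    sw_times = np.asarray(sw_times, dtype=np.float64)
    idx = np.searchsorted(np.round(sw_times, 6), np.round(window_times, 6))
    idx = np.clip(idx, 0, sw_vec.size - 1)
    return sw_vec[idx]


def run_control(record: EEGRecord, roster: SeizureRoster,
                config: PipelineConfig,
                seizure: SeizureEvent,
                spec: ControlSpec = ControlSpec()) -> dict:
    """Run the same pipeline on the matched control interval, or return a
    refusal report when the seizure-free requirement is unmet."""
    decision = make_control_interval(seizure, roster, spec)
    if not decision.accepted:
        return {"seizure_id": seizure.seizure_id, "status": "refused",
                "reason": decision.reason}
    return run_seizure(record, roster, config, seizure=seizure,
                       analysis_window=decision.window)


def _percentiles(x):
    x = np.asarray(x, dtype=float)
    return {
        "mean": round(float(x.mean()), 4),
        "sd": round(float(x.std(ddof=1)) if x.size > 1 else 0.0, 4),
        "q25": round(float(np.percentile(x, 25)), 4),
        "median": round(float(np.median(x)), 4),
        "q75": round(float(np.percentile(x, 75)), 4),
        "n": int(x.size),
    }


def cohort_summary(reports: list) -> dict:
    """Category prevalences per feature group, preictal characterization
    statistics (categories 3 and 6), and seizure-level discovery rates.

    A seizure counts as "preictal found" when any feature group assigned
    category 3 or 6; the extended rate additionally counts category 5.
    When several groups found a preictal, the final interval is the one
    with the earliest start time.
    """
    if not reports:
        raise ValueError("need at least one report")
    groups = sorted({g for r in reports for g in r.get("groups", {})})
    out = {"n_seizures": len(reports), "groups": {}}
    for g in groups:
        cats = [r["groups"][g].get("category") for r in reports
                if g in r.get("groups", {})
                and r["groups"][g].get("category") is not None]
        n = len(cats)
        prevalence = {str(c): round(100.0 * cats.count(c) / n, 2)
                      for c in range(1, 7)} if n else {}
        chars = {"start_min": [], "duration_min": [], "density": []}
        for r in reports:
            gr = r.get("groups", {}).get(g, {})
            if gr.get("category") in (3, 6) and "preictal" in gr:
                chars["start_min"].append(
                    gr["preictal"]["start_before_onset_min"])
                chars["duration_min"].append(gr["preictal"]["duration_min"])
                chars["density"].append(gr["preictal"]["density"])
        out["groups"][g] = {
            "n": n,
            "prevalence_pct": prevalence,
            "characterization": {k: (_percentiles(v) if v else None)
                                 for k, v in chars.items()},
        }

    found, extended, finals = 0, 0, []
    for r in reports:
        cats = {g: gr.get("category") for g, gr in r.get("groups", {}).items()}
        has36 = any(c in (3, 6) for c in cats.values())
        found += has36
        extended += has36 or any(c == 5 for c in cats.values())
        starts = [(gr["preictal"]["start_before_onset_min"], gr["preictal"])
                  for gr in r.get("groups", {}).values()
                  if gr.get("category") in (3, 6) and "preictal" in gr]
        if starts:
            finals.append(max(starts, key=lambda s: s[0])[1])
    out["seizure_level"] = {
        "preictal_found_pct": round(100.0 * found / len(reports), 2),
        "preictal_found_extended_pct":
            round(100.0 * extended / len(reports), 2),
        "final_start_min": _percentiles(
            [f["start_before_onset_min"] for f in finals]) if finals else None,
    }
    return out
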