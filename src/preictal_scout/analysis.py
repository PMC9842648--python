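"""Categorization of clustering solutions and preictal characterization.

The six distribution categories (operational rules, every threshold in
:class:`CategoryRules`):

1. no evidence of preictal structure (default verdict);
2. two evenly sized clusters (size ratio within the evenness band) with
   neither passing the preictal test — typical of an external driver such
   as the sleep-wake cycle;
3. two differently sized clusters whose smaller one passes the preictal
   test: a time-compact cluster within the 120 min before onset;
4. samples following a temporal trajectory (time-coherent path);
5. a compact pre-onset stretch that clustering could not isolate
   (silhouette-like compactness of a time-contiguous suffix block);
6. more than two clusters with at least one passing the preictal test —
   the preictal cluster is the passing one nearest the onset.

The preictal test for a cluster: after trimming temporal outliers
(member times outside the Tukey fences Q1 - 1.5 IQR, Q3 + 1.5 IQR), at
least ``in_window_fraction`` of retained members lie within the 120-min
search window before onset, and the cluster's within-span density is at
least ``density_floor``.

Also here: the phi (Matthews) coefficient between binary vectors, its
application to cluster-vs-sleep-wake association for categories 2/3/6,
and matched control-interval construction (a 4.5-h window ending 24 h
before onset, requiring 33 h of seizure-free signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import ClusterSolution
from .preprocess import AnalysisWindow, SeizureEvent, SeizureRoster

WINDOW_S = 5.0
SEARCH_WINDOW_MIN = 120.0


@dataclass(frozen=True)
class CategoryRules:
    """Thresholds of the rule cascade (config, defaults as documented)."""

    search_window_min: float = SEARCH_WINDOW_MIN
    even_ratio_low: float = 0.8      # small/large ratio for "evenly sized"
    in_window_fraction: float = 0.9
    density_floor: float = 0.5
    trajectory_threshold: float = 0.9
    compactness_threshold: float = 0.25
    suffix_min_minutes: float = 10.0
    suffix_max_minutes: float = 120.0
    tukey_k: float = 1.5


@dataclass
class CategoryLabel:
    category: int
    rule_trace: list = field(default_factory=list)
    preictal_cluster: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.category <= 6:
            raise ValueError("category must be 1..6")
        if not self.rule_trace:
            raise ValueError("rule_trace must be non-empty")


@dataclass
class PreictalInterval:
    cluster_id: int
    start_before_onset: float   # minutes
    duration: float             # minutes
    density: float
    ends_at_onset: bool

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.duration > self.start_before_onset + 1e-9:
            raise ValueError("duration cannot exceed start_before_onset")


@dataclass
class AssociationResult:
    phi: float
    contingency: np.ndarray     # 2x2: [cluster x wake] counts


@dataclass
class ControlDecision:
    accepted: bool
    window: AnalysisWindow | None = None
    reason: str | None = None


@dataclass(frozen=True)
class ControlSpec:
    start_hours_before: float = 28.5
    end_hours_before: float = 24.0
    min_seizure_free_hours: float = 33.0


def _tukey_trim(times: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of member times inside the Tukey fences."""
    q1, q3 = np.percentile(times, [25, 75])
    iqr = q3 - q1
    return (times >= q1 - k * iqr) & (times <= q3 + k * iqr)


def _preictal_test(member_times: np.ndarray, all_times: np.ndarray,
                   rules: CategoryRules) -> dict:
    """Evaluate the preictal test for one cluster; returns diagnostics."""
    keep = _tukey_trim(member_times, rules.tukey_k)
    trimmed = member_times[keep]
    lo = -rules.search_window_min * 60.0
    frac_in = float(np.mean((trimmed >= lo) & (trimmed < 0)))
    span = (trimmed.min(), trimmed.max())
    n_span = int(np.sum((all_times >= span[0]) & (all_times <= span[1])))
    density = trimmed.size / n_span if n_span else 0.0
    passed = (frac_in >= rules.in_window_fraction
              and density >= rules.density_floor)
    return {"passed": passed, "frac_in_window": frac_in,
            "density": float(density), "span_s": span,
            "n_trimmed": int(member_times.size - trimmed.size)}


def _trajectory_score(embedding: np.ndarray, times: np.ndarray,
                      distances: np.ndarray) -> float:
    """Time-coherence of the embedding trajectory in [~0, 1]: one minus
    the ratio of the mean consecutive-in-time step length to the mean
    distance between arbitrary point pairs.  Near 1 for a smooth
    temporal path, near 0 for time-shuffled structure."""
    order = np.argsort(times)
    e = embedding[order]
    step = float(np.linalg.norm(np.diff(e, axis=0), axis=1).mean())
    mean_pair = float(distances[np.triu_indices_from(distances, 1)].mean())
    if mean_pair == 0:
        return 0.0
    return 1.0 - step / mean_pair


def _best_suffix_block(times: np.ndarray, distances: np.ndarray,
                       rules: CategoryRules):
    """Most compact time-contiguous suffix block: for candidate lengths
    between ``suffix_min_minutes`` and ``suffix_max_minutes`` (5-min
    steps), a silhouette-like score (b - a)/max(a, b) of block vs rest;
    returns (best score, block mask)."""
    t_end = times.max()
    best, best_mask = -np.inf, None
    lengths = np.arange(rules.suffix_min_minutes,
                        rules.suffix_max_minutes + 1e-9, 5.0)
    for length in lengths:
        mask = times >= t_end - length * 60.0 + WINDOW_S
        nb = int(mask.sum())
        if nb < 2 or nb > times.size - 2:
            continue
        a = distances[np.ix_(mask, mask)]
        a = a[np.triu_indices(nb, 1)].mean()
        b = distances[np.ix_(mask, ~mask)].mean()
        score = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
        if score > best:
            best, best_mask = score, mask
    return best, best_mask


def categorize(embedding: np.ndarray, solution: ClusterSolution,
               window_times: np.ndarray,
               rules: CategoryRules = CategoryRules()) -> CategoryLabel:
    """Deterministic rule cascade mapping a clustering solution to one of
    the six categories, with an auditable trace of fired rules."""
    times = np.asarray(window_times, dtype=np.float64)
    trace = []
    labels = (solution.labels if solution.labels is not None
              else np.zeros(times.size, dtype=int))
    ids = [c for c in np.unique(labels) if c >= 0]
    sizes = {c: int((labels == c).sum()) for c in ids}
    n_clusters = 0 if solution.unclustered else len(ids)
    trace.append(("clusters", {"n": n_clusters, "sizes": sizes}))

    tests = {}
    if n_clusters >= 2:
        for c in ids:
            tests[c] = _preictal_test(times[labels == c], times, rules)

    if n_clusters >= 3:
        passing = [c for c in ids if tests[c]["passed"]]
        trace.append(("multi_cluster_preictal_test",
                      {c: tests[c]["passed"] for c in ids}))
        if passing:
            nearest = max(passing,
                          key=lambda c: float(np.median(times[labels == c])))
            trace.append(("category6", {"preictal_cluster": int(nearest)}))
            return CategoryLabel(6, trace, preictal_cluster=int(nearest))

    if n_clusters == 2:
        small, large = sorted(ids, key=lambda c: sizes[c])
        ratio = sizes[small] / sizes[large]
        trace.append(("two_cluster_ratio", {"ratio": round(ratio, 4)}))
        even = ratio >= rules.even_ratio_low
        if even and not tests[small]["passed"] and not tests[large]["passed"]:
            trace.append(("category2", {}))
            return CategoryLabel(2, trace)
        if not even and tests[small]["passed"]:
            trace.append(("category3", {"preictal_cluster": int(small),
                                        **tests[small]}))
            return CategoryLabel(3, trace, preictal_cluster=int(small))
        trace.append(("two_cluster_no_match",
                      {c: tests[c]["passed"] for c in ids}))

    distances = squareform(pdist(embedding))
    traj = _trajectory_score(embedding, times, distances)
    trace.append(("trajectory_score", {"score": round(traj, 4)}))
    if traj >= rules.trajectory_threshold:
        trace.append(("category4", {}))
        return CategoryLabel(4, trace)

    score, mask = _best_suffix_block(times, distances, rules)
    trace.append(("suffix_compactness", {"score": round(float(score), 4)
                                         if np.isfinite(score) else None}))
    if mask is not None and score >= rules.compactness_threshold:
        trace.append(("category5", {"block_windows": int(mask.sum())}))
        return CategoryLabel(5, trace)

    trace.append(("category1", {}))
    return CategoryLabel(1, trace)


def characterize_preictal(solution: ClusterSolution,
                          window_times: np.ndarray, cluster_id: int,
                          rules: CategoryRules = CategoryRules()
                          ) -> PreictalInterval:
    """Start / duration / density of the preictal cluster after outlier
    trimming.

    start = minutes before onset of the earliest retained member window;
    duration spans earliest to latest member window (inclusive of the
    final 5-s window); density = retained members over all valid windows
    inside that span; ``ends_at_onset`` marks the cluster reaching the
    last pre-SPH window.
    """
    times = np.asarray(window_times, dtype=np.float64)
    member = times[solution.labels == cluster_id]
    if member.size == 0:
        raise ValueError("empty preictal cluster (upstream bug)")
    member = member[_tukey_trim(member, rules.tukey_k)]
    t0, t1 = member.min(), member.max()
    n_span = int(np.sum((times >= t0) & (times <= t1)))
    return PreictalInterval(
        cluster_id=int(cluster_id),
        start_before_onset=-t0 / 60.0,
        duration=(t1 - t0 + WINDOW_S) / 60.0,
        density=member.size / n_span,
        ends_at_onset=bool(np.isclose(t1, times.max())))


def phi_coefficient(a, b) -> float:
    """Phi (Matthews) coefficient of two binary vectors from their 2x2
    contingency table; NaN when either vector is constant."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if a.all() or (~a).all() or b.all() or (~b).all():
        return np.nan
    n11 = float(np.sum(a & b))
    n10 = float(np.sum(a & ~b))
    n01 = float(np.sum(~a & b))
    n00 = float(np.sum(~a & ~b))
    denom = np.sqrt((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
    return (n11 * n00 - n10 * n01) / denom


def sleepwake_association(solution: ClusterSolution,
                          sleepwake_vector: np.ndarray,
                          category: CategoryLabel) -> AssociationResult:
    """Phi between the sleep-wake vector (1 = wake) and the binary cluster
    vector: preictal-cluster membership for categories 3/6, membership in
    one of the two clusters for category 2."""
    sw = np.asarray(sleepwake_vector).astype(bool)
    if solution.labels is None or sw.size != solution.labels.size:
        raise ValueError("sleep-wake vector misaligned with windows")
    if category.category in (3, 6):
        cluster_vec = solution.labels == category.preictal_cluster
    elif category.category == 2:
        ids = [c for c in np.unique(solution.labels) if c >= 0]
        cluster_vec = solution.labels == ids[0]
    else:
        raise ValueError("association defined for categories 2, 3, 6 only")
    phi = phi_coefficient(cluster_vec, sw)
    cont = np.array([[np.sum(cluster_vec & sw), np.sum(cluster_vec & ~sw)],
                     [np.sum(~cluster_vec & sw), np.sum(~cluster_vec & ~sw)]])
    return AssociationResult(phi=phi, contingency=cont)


def make_control_interval(seizure: SeizureEvent, roster: SeizureRoster,
                          spec: ControlSpec = ControlSpec()
                          ) -> ControlDecision:
    """Matched control window [onset - 28.5 h, onset - 24 h), emitted only
    with at least 33 h of seizure-free signal before onset (which also
    separates the control from the previous seizure by >= 4.5 h)."""
    onset = seizure.onset
    prev = roster.previous_event(seizure)
    if prev is not None:
        free_h = (onset - prev.offset) / 3600.0
        if free_h < spec.min_seizure_free_hours:
            return ControlDecision(
                accepted=False,
                reason=f"only {free_h:.2f} h seizure-free before onset "
                       f"(need {spec.min_seizure_free_hours})")
    span = (onset - spec.start_hours_before * 3600.0,
            onset - spec.end_hours_before * 3600.0)
    window = AnalysisWindow(seizure_id=seizure.seizure_id, span=span,
                            onset=onset, sph_minutes=0.0,
                            excluded_intervals=[])
    return ControlDecision(accepted=True, window=window)
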