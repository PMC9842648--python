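"""Rule-based categorization, preictal characterization, phi coefficient,
sleep-wake association, control intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preictal_scout.analysis import (CategoryLabel, CategoryRules,
                                     ControlSpec, categorize,
                                     characterize_preictal,
                                     make_control_interval, phi_coefficient,
                                     sleepwake_association)
from preictal_scout.embedding import ClusterSolution
from preictal_scout.preprocess import SeizureEvent, SeizureRoster

H = 3600.0
RULES = CategoryRules()


def times_grid(minutes, sph_min=10.0):
    """5-s window start times covering [-minutes, -sph) before onset."""
    return np.arange(-minutes * 60.0, -sph_min * 60.0, 5.0)


def solution(labels, method="kmeans_k2"):
    return ClusterSolution(labels=np.asarray(labels), method=method,
                           embedding_params=(10, 0.1), dunn_index=1.0)


def embed_from_labels(labels, rng, spread=0.4):
    """Well-separated blob per label (geometry consistent with labels)."""
    centers = {c: 10.0 * rng.normal(size=3)
               for c in np.unique(labels)}
    return np.vstack([centers[c] + spread * rng.normal(size=3)
                      for c in labels])


class TestCategorize:
    def test_small_compact_preonset_cluster_is_category3(self, rng):
        t = times_grid(120)
        labels = np.where((t >= -45 * 60) & (t < -25 * 60), 1, 0)
        emb = embed_from_labels(labels, rng)
        cat = categorize(emb, solution(labels), t)
        assert cat.category == 3
        assert cat.preictal_cluster == 1

    def test_even_alternating_clusters_are_category2(self, rng):
        t = times_grid(260)  # ~4.2 h of windows
        half = 45 * 60.0  # 90-min period
        labels = (np.floor((t - t[0]) / half).astype(int) % 2)
        emb = embed_from_labels(labels, rng)
        cat = categorize(emb, solution(labels), t)
        sizes = np.bincount(labels)
        assert 0.8 <= sizes.min() / sizes.max() <= 1.25
        assert cat.category == 2

    def test_multi_cluster_with_preonset_member_is_category6(self, rng):
        t = times_grid(240)
        labels = np.zeros(t.size, dtype=int)
        # four interictal sub-states plus one compact cluster at [-30,-10)
        for k, (a, b) in enumerate([(-240, -180), (-180, -130), (-130, -80),
                                    (-80, -30)]):
            labels[(t >= a * 60) & (t < b * 60)] = k
        labels[(t >= -30 * 60)] = 4
        emb = embed_from_labels(labels, rng)
        cat = categorize(emb, solution(labels, "hdbscan"), t)
        assert cat.category == 6
        assert cat.preictal_cluster == 4  # nearest the onset

    def test_helix_trajectory_is_category4(self, rng):
        t = times_grid(120)
        s = np.linspace(0, 4 * np.pi, t.size)
        emb = np.column_stack([np.cos(s), np.sin(s),
                               np.linspace(0, 3, t.size)])
        emb += 0.01 * rng.normal(size=emb.shape)
        sol = ClusterSolution(labels=np.zeros(t.size, int),
                              method="unclustered",
                              embedding_params=(10, 0.1),
                              dunn_index=np.nan, unclustered=True)
        cat = categorize(emb, sol, t)
        assert cat.category == 4

    def test_structureless_cloud_is_category1(self, rng):
        t = times_grid(120)
        emb = rng.normal(size=(t.size, 3))
        sol = ClusterSolution(labels=np.zeros(t.size, int),
                              method="unclustered",
                              embedding_params=(10, 0.1),
                              dunn_index=np.nan, unclustered=True)
        cat = categorize(emb, sol, t)
        assert cat.category == 1

    def test_compact_suffix_without_separation_is_category5(self, rng):
        t = times_grid(120)
        emb = rng.normal(size=(t.size, 3))
        suffix = t >= -40 * 60
        emb[suffix] = np.array([2.5, 0, 0]) + 0.35 * rng.normal(
            size=(suffix.sum(), 3))
        sol = ClusterSolution(labels=np.zeros(t.size, int),
                              method="unclustered",
                              embedding_params=(10, 0.1),
                              dunn_index=np.nan, unclustered=True)
        cat = categorize(emb, sol, t)
        assert cat.category == 5

    def test_every_input_gets_exactly_one_category_with_trace(self, rng):
        t = times_grid(60)
        for seed in range(5):
            r = np.random.default_rng(seed)
            labels = r.integers(0, 3, size=t.size)
            emb = r.normal(size=(t.size, 3))
            cat = categorize(emb, solution(labels, "gmm_k3"), t)
            assert 1 <= cat.category <= 6
            assert len(cat.rule_trace) >= 2


class TestCharacterize:
    def test_full_occupancy_interval(self):
        t = times_grid(120)
        labels = np.where((t >= -40 * 60) & (t < -20 * 60), 1, 0)
        pi = characterize_preictal(solution(labels), t, 1)
        assert pi.start_before_onset == pytest.approx(40.0)
        assert pi.duration == pytest.approx(20.0)
        assert pi.density == pytest.approx(1.0)
        assert not pi.ends_at_onset

    def test_partial_density(self):
        t = times_grid(120)
        span = (t >= -30 * 60) & (t < -29 * 60)  # 12 windows
        idx = np.flatnonzero(span)
        labels = np.zeros(t.size, dtype=int)
        labels[idx[[0, 1, 2, 4, 5, 7, 8, 10, 11]]] = 1  # 9 of 12
        pi = characterize_preictal(solution(labels), t, 1)
        assert pi.density == pytest.approx(0.75)

    def test_cluster_reaching_sph_ends_at_onset(self):
        t = times_grid(120)
        labels = np.where(t >= -25 * 60, 1, 0)
        pi = characterize_preictal(solution(labels), t, 1)
        assert pi.ends_at_onset

    def test_isolated_straggler_trimmed(self):
        t = times_grid(120)
        labels = np.where((t >= -40 * 60) & (t < -20 * 60), 1, 0)
        labels[0] = 1  # lone member 80 min before the cluster
        pi = characterize_preictal(solution(labels), t, 1)
        assert pi.start_before_onset == pytest.approx(40.0)
        assert pi.duration == pytest.approx(20.0)

    def test_empty_cluster_rejected(self):
        t = times_grid(30)
        with pytest.raises(ValueError):
            characterize_preictal(solution(np.zeros(t.size, int)), t, 5)


class TestPhi:
    def test_identity_and_complement(self, rng):
        v = rng.integers(0, 2, size=50).astype(bool)
        v[0], v[1] = True, False  # non-constant
        assert phi_coefficient(v, v) == pytest.approx(1.0)
        assert phi_coefficient(v, ~v) == pytest.approx(-1.0)

    def test_independent_quadrants_zero(self):
        assert phi_coefficient([1, 1, 0, 0], [1, 0, 1, 0]) == 0.0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_equals_pearson_correlation(self, seed):
        r = np.random.default_rng(seed)
        a = r.integers(0, 2, size=30)
        b = r.integers(0, 2, size=30)
        if a.min() == a.max() or b.min() == b.max():
            assert np.isnan(phi_coefficient(a, b))
        else:
            assert phi_coefficient(a, b) == pytest.approx(
                np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(phi_coefficient([1, 1, 1], [0, 1, 0]))


class TestSleepwakeAssociation:
    def test_cluster_coinciding_with_sleep(self, rng):
        t = times_grid(120)
        sleep = (t >= -60 * 60) & (t < -20 * 60)
        labels = np.where(sleep, 1, 0)
        cat = categorize(embed_from_labels(labels, rng),
                         solution(labels), t)
        res = sleepwake_association(solution(labels), ~sleep, cat)
        assert abs(res.phi) == pytest.approx(1.0)
        assert res.contingency.sum() == t.size

    def test_random_placement_near_zero(self):
        t = times_grid(120)
        n_members = 200
        cat_stub = CategoryLabel(3, [("stub", {})], preictal_cluster=1)
        sw = np.zeros(t.size, dtype=bool)
        sw[: t.size // 2] = True
        phis = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            labels = np.zeros(t.size, dtype=int)
            labels[r.choice(t.size, n_members, replace=False)] = 1
            phis.append(abs(sleepwake_association(
                solution(labels), sw, cat_stub).phi))
        assert np.mean(phis) <= 0.1


class TestControlIntervals:
    def test_span_arithmetic(self):
        ev = SeizureEvent(1, 100.0 * H, 100.0 * H + 60)
        dec = make_control_interval(ev, SeizureRoster([ev]))
        assert dec.accepted
        assert dec.window.span == (71.5 * H, 76.0 * H)
        assert (dec.window.span[1] - dec.window.span[0]) == 4.5 * H

    def test_short_seizure_free_time_refused(self):
        prev = SeizureEvent(1, 60.0 * H, 70.0 * H)  # offset 30 h before
        ev = SeizureEvent(2, 100.0 * H, 100.0 * H + 60)
        dec = make_control_interval(ev, SeizureRoster([prev, ev]))
        assert not dec.accepted
        assert "seizure-free" in dec.reason

    def test_forty_hours_free_accepted(self):
        prev = SeizureEvent(1, 59.0 * H, 60.0 * H)  # offset 40 h before
        ev = SeizureEvent(2, 100.0 * H, 100.0 * H + 60)
        dec = make_control_interval(ev, SeizureRoster([prev, ev]))
        assert dec.accepted
        # control start is >= 4.5 h after the previous offset
        assert dec.window.span[0] - prev.offset >= 4.5 * H
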