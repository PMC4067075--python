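"""Nearest neighbours, hypergeometric class hypotheses and p0p1."""

import itertools

import numpy as np
import pytest

from facespace.query import (nearest_neighbors, p0p1_similarity, query_report,
                             rank_class_hypotheses)
from facespace.space import EmbeddedFace
from facespace.synthetic import PopulationSpec, sample_feature_population


def _space(points, labels=None, prefix="f"):
    labels = [None] * len(points) if labels is None else labels
    return [EmbeddedFace(np.atleast_1d(p), f"{prefix}{i:04d}", l)
            for i, (p, l) in enumerate(zip(points, labels))]


class TestNearestNeighbors:
    def test_duplicate_point_ranks_first(self):
        space = _space([[0.0], [5.0], [9.0]])
        q = EmbeddedFace(np.array([0.0]), "query")
        nbs = nearest_neighbors(q, space, k=2)
        assert nbs[0].image_id == "f0000"
        assert nbs[0].distance == 0.0

    def test_k1_on_collinear_points(self):
        space = _space([[0.0], [1.0], [5.0]])
        q = EmbeddedFace(np.array([0.4]), "query")
        assert nearest_neighbors(q, space, k=1)[0].image_id == "f0000"

    def test_matches_brute_force_sort(self, rng):
        pts = rng.normal(0, 1, (500, 4))
        space = _space(pts)
        q = EmbeddedFace(rng.normal(0, 1, 4), "query")
        nbs = nearest_neighbors(q, space, k=20)
        d = np.linalg.norm(pts - q.vector, axis=1)
        want = np.argsort(d, kind="stable")[:20]
        assert [n.image_id for n in nbs] == [f"f{i:04d}" for i in want]
        assert all(a.distance <= b.distance
                   for a, b in zip(nbs[:-1], nbs[1:]))

    def test_ties_broken_by_id(self):
        space = _space([[1.0], [-1.0], [1.0]])
        q = EmbeddedFace(np.array([0.0]), "query")
        nbs = nearest_neighbors(q, space, k=3)
        assert [n.image_id for n in nbs] == ["f0000", "f0001", "f0002"]

    def test_query_excluded_and_k_truncated(self):
        space = _space([[0.0], [1.0]])
        q = space[0]
        nbs = nearest_neighbors(q, space, k=10)
        assert [n.image_id for n in nbs] == ["f0001"]


def _enumeration_tail(m_total, k, prevalence, n_obs):
    """Exhaustive oracle: fraction of C(M, k) draws with >= n_obs hits."""
    pop = [1] * prevalence + [0] * (m_total - prevalence)
    hits = 0
    total = 0
    for draw in itertools.combinations(range(m_total), k):
        total += 1
        if sum(pop[i] for i in draw) >= n_obs:
            hits += 1
    return hits / total


class TestClassHypotheses:
    def test_two_of_two_class_a_from_four(self):
        # population 2A+2B, draw 2, both A: 1 of the C(4,2)=6 draws
        space = _space([[0.0], [0.1], [5.0], [5.1]],
                       labels=["A", "A", "B", "B"])
        q = EmbeddedFace(np.array([0.05]), "query")
        nbs = nearest_neighbors(q, space, k=2)
        hyps = rank_class_hypotheses(nbs, space, k=2)
        assert hyps[0].label == "A"
        assert hyps[0].probability == pytest.approx(1.0 / 6.0)

    def test_absent_class_not_reported(self):
        space = _space([[0.0], [0.1], [9.0], [9.1]],
                       labels=["A", "A", "B", "B"])
        q = EmbeddedFace(np.array([0.05]), "query")
        hyps = rank_class_hypotheses(nearest_neighbors(q, space, k=2), space)
        assert [h.label for h in hyps] == ["A"]

    @pytest.mark.parametrize("m_total,k,prev", [(8, 3, 3), (10, 4, 5),
                                                (12, 5, 4)])
    def test_matches_exhaustive_enumeration(self, m_total, k, prev, rng):
        labels = ["x"] * prev + ["y"] * (m_total - prev)
        rng.shuffle(labels)
        pts = rng.normal(0, 1, (m_total, 2))
        space = _space(pts, labels=labels)
        q = EmbeddedFace(rng.normal(0, 1, 2), "query")
        nbs = nearest_neighbors(q, space, k=k)
        hyps = rank_class_hypotheses(nbs, space, k=k)
        for h in hyps:
            prev_h = labels.count(h.label)
            want = _enumeration_tail(m_total, k, prev_h, h.observed)
            assert h.probability == pytest.approx(want, abs=1e-12)

    def test_top_rank_accuracy_increases_with_separation(self):
        accs = []
        for sep in (0.5, 3.0, 8.0):
            pop = sample_feature_population(PopulationSpec(
                n_classes=8, n_per_class=15, dim_informative=8,
                class_separation=sep, nuisance_scale=0.5, seed=3))
            space = _space(pop.features, labels=list(pop.labels))
            hits = 0
            for i in range(0, pop.n, 3):
                nbs = nearest_neighbors(space[i], space, k=20)
                hyps = rank_class_hypotheses(nbs, space, k=20)
                hits += hyps[0].label == pop.labels[i]
            accs.append(hits / len(range(0, pop.n, 3)))
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[2] > 0.9


def _bisector_space(k, g, d01):
    """Query and partner d01 apart; k satellites equidistant (g) from both."""
    q = np.array([0.0, 0.0, 0.0])
    nb = np.array([d01, 0.0, 0.0])
    mid = (q + nb) / 2.0
    r = np.sqrt(g ** 2 - (d01 / 2.0) ** 2)
    sats = [mid + r * np.array([0.0, np.cos(a), np.sin(a)])
            for a in 2 * np.pi * np.arange(k) / k]
    return _space([q, nb, *sats])


class TestP0P1:
    def test_unit_value_when_pair_matches_local_scale(self):
        space = _bisector_space(k=6, g=1.0, d01=1.0)
        val = p0p1_similarity(space[0], space[1], space, k=6)
        assert val == pytest.approx(1.0, rel=1e-9)

    def test_pair_five_percent_closer_scores_1_05(self):
        space = _bisector_space(k=6, g=1.0, d01=1.0 / 1.05)
        val = p0p1_similarity(space[0], space[1], space, k=6)
        assert val == pytest.approx(1.05, rel=1e-9)

    def test_symmetric_in_the_two_points(self, rng):
        pts = rng.normal(0, 1, (40, 3))
        space = _space(pts)
        a = p0p1_similarity(space[3], space[17], space, k=10)
        b = p0p1_similarity(space[17], space[3], space, k=10)
        assert a == pytest.approx(b, rel=1e-12)

    def test_exact_duplicate_flagged_infinite(self):
        pts = np.vstack([np.zeros(2), np.zeros(2),
                         np.random.default_rng(0).normal(0, 1, (10, 2))])
        space = _space(pts)
        assert p0p1_similarity(space[0], space[1], space, k=5) == np.inf

    def test_structureless_cloud_has_unit_median_among_neighbors(self, rng):
        pts = rng.uniform(0, 1, (200, 2))
        space = _space(pts)
        by_id = {f.image_id: f for f in space}
        vals = []
        for i in range(100):
            for nb in nearest_neighbors(space[i], space, k=20)[5:10]:
                vals.append(p0p1_similarity(space[i], by_id[nb.image_id],
                                            space, k=20))
        assert abs(np.median(vals) - 1.0) < 0.15

    def test_literal_ratio_form_available(self, rng):
        pts = rng.normal(0, 1, (30, 2))
        space = _space(pts)
        lit = p0p1_similarity(space[0], space[1], space, k=5, literal=True)
        d01 = float(np.linalg.norm(pts[0] - pts[1]))
        assert lit == pytest.approx(d01 / (_arith(pts, 0, 1, 5)
                                           * _arith(pts, 1, 0, 5)))


def _arith(pts, i, j, k):
    d = np.linalg.norm(pts - pts[i], axis=1)
    d = np.delete(d, [i, j])
    return float(np.sort(d)[:k].mean())


def test_query_report_is_complete(rng):
    pts = rng.normal(0, 1, (50, 3))
    labels = ["a"] * 25 + ["b"] * 25
    space = _space(pts, labels=labels)
    rep = query_report(space[0], space, k=10)
    assert len(rep.neighbors) == 10
    assert len(rep.p0p1) == 10
    assert rep.hypotheses[0].probability <= rep.hypotheses[-1].probability
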