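"""Querying the phenotype space.

A query face is related to the database through (1) its k nearest
neighbours, (2) ranked syndrome hypotheses -- how surprising is the
observed neighbour count of each syndrome given its prevalence, a
hypergeometric tail probability -- and (3) the p0p1 local-density
similarity: the mutual distance of a pair normalized by the geometric
mean of their own neighbourhood scales.  p0p1 > 1 flags pairs closer
than their local density predicts (candidate novel clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom


@dataclass
class Neighbor:
    image_id: str
    label: object
    distance: float


@dataclass
class ClassHypothesis:
    label: object
    observed: int          # N among the k neighbours
    probability: float     # Pr(X >= N) under hypergeometric sampling
    prevalence: int        # class count in the space
    dispersion: float      # mean intra-class pairwise distance


@dataclass
class QueryReport:
    query_id: str
    k: int
    neighbors: list[Neighbor]
    hypotheses: list[ClassHypothesis]
    p0p1: list[float] = field(default_factory=list)


def _as_matrix(space) -> tuple[np.ndarray, list, list]:
    vecs = np.stack([f.vector for f in space])
    ids = [f.image_id for f in space]
    labels = [f.label for f in space]
    return vecs, ids, labels


def nearest_neighbors(query, space: list, k: int = 20) -> list[Neighbor]:
    """k nearest faces by metric distance, ascending; ties broken by id.

    The query itself (same ``image_id``) is excluded.  If fewer than k
    candidates exist the list is truncated.
    """
    if not space:
        raise ValueError("space is empty")
    vecs, ids, labels = _as_matrix(space)
    d = np.linalg.norm(vecs - np.asarray(query.vector), axis=1)
    order = sorted(
        (i for i in range(len(space)) if ids[i] != query.image_id),
        key=lambda i: (d[i], ids[i]),
    )
    return [Neighbor(ids[i], labels[i], float(d[i])) for i in order[:k]]


def rank_class_hypotheses(
    neighbors: list[Neighbor],
    space: list,
    k: int | None = None,
) -> list[ClassHypothesis]:
    """Hypergeometric surprise ranking of syndromes among the neighbours.

    For each class with N >= 1 members among the k neighbours, the
    enrichment probability is Pr(X >= N) for k draws without
    replacement from the space's composition; classes are ranked by
    ascending probability (most surprising first).  Dispersion (mean
    intra-class pairwise distance) and prevalence are reported as
    context, not folded into the rank.
    """
    if k is None:
        k = len(neighbors)
    vecs, _, labels = _as_matrix(space)
    labels_arr = np.array(labels, dtype=object)
    classes, counts = np.unique(labels_arr, return_counts=True)
    composition = dict(zip(classes.tolist(), counts.tolist()))
    m_total = len(space)

    observed: dict = {}
    for nb in neighbors:
        observed[nb.label] = observed.get(nb.label, 0) + 1

    out = []
    for label, n_obs in observed.items():
        if label not in composition:
            raise ValueError(f"class {label!r} missing from composition")
        prevalence = composition[label]
        # tail Pr(X >= N) with X ~ Hypergeom(M=m_total, K=prevalence, n=k)
        prob = float(hypergeom.sf(n_obs - 1, m_total, prevalence, k))
        members = vecs[labels_arr == label]
        if len(members) > 1:
            dd = cdist(members, members)
            dispersion = float(dd[np.triu_indices(len(members), 1)].mean())
        else:
            dispersion = 0.0
        out.append(ClassHypothesis(label, n_obs, prob, prevalence, dispersion))
    out.sort(key=lambda h: (h.probability, -h.observed))
    return out


def _local_scale(point, exclude_id: str, space: list, k: int) -> float:
    """Geometric mean distance to the point's k NN, excluding a partner."""
    candidates = [f for f in space
                  if f.image_id not in (point.image_id, exclude_id)]
    if len(candidates) < k:
        raise ValueError(f"need at least {k} neighbours for the local scale")
    vecs = np.stack([f.vector for f in candidates])
    d = np.linalg.norm(vecs - np.asarray(point.vector), axis=1)
    dk = np.sort(d, kind="stable")[:k]
    dk = np.maximum(dk, np.finfo(float).tiny)
    return float(np.exp(np.mean(np.log(dk))))


def p0p1_similarity(query, neighbor, space: list, k: int = 20,
                    literal: bool = False) -> float:
    """Local-density-normalized pair similarity.

    Default form: sqrt(g0 * g1) / d01, where g0 and g1 are the
    geometric means of each point's distances to its own k nearest
    neighbours (each excluding the other member of the pair) and d01 is
    the pair's mutual distance.  Values above 1 mean the pair is closer
    than the local density predicts.  ``literal=True`` gives the raw
    ratio d01 / (d0 * d1) with arithmetic-mean scales instead.
    """
    d01 = float(np.linalg.norm(
        np.asarray(query.vector) - np.asarray(neighbor.vector)))
    if d01 == 0:
        return float("inf")
    if literal:
        d0 = _arith_scale(query, neighbor.image_id, space, k)
        d1 = _arith_scale(neighbor, query.image_id, space, k)
        return d01 / (d0 * d1)
    g0 = _local_scale(query, neighbor.image_id, space, k)
    g1 = _local_scale(neighbor, query.image_id, space, k)
    return float(np.sqrt(g0 * g1) / d01)


def _arith_scale(point, exclude_id: str, space: list, k: int) -> float:
    candidates = [f for f in space
                  if f.image_id not in (point.image_id, exclude_id)]
    if len(candidates) < k:
        raise ValueError(f"need at least {k} neighbours for the local scale")
    vecs = np.stack([f.vector for f in candidates])
    d = np.linalg.norm(vecs - np.asarray(point.vector), axis=1)
    return float(np.sort(d, kind="stable")[:k].mean())


def query_report(query, space: list, k: int = 20,
                 with_p0p1: bool = True) -> QueryReport:
    """Full neighbour + hypothesis + p0p1 report for one query face."""
    nbs = nearest_neighbors(query, space, k)
    hyps = rank_class_hypotheses(nbs, space, k=len(nbs))
    p0p1 = []
    if with_p0p1:
        by_id = {f.image_id: f for f in space}
        for nb in nbs:
            p0p1.append(p0p1_similarity(query, by_id[nb.image_id], space,
                                        k=min(k, len(space) - 2)))
    return QueryReport(query.image_id, k, nbs, hyps, p0p1)
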