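"""Clustering Improvement Factor (CIF).

For a syndrome with Np members ("positives") among Nn other faces
("negatives"), querying from each member, the rank of its nearest
same-syndrome match measures how clustered the syndrome is.  Under a
random ranking -- each of the other Np-1 positives placed independently
and uniformly among the Nn negatives -- the expected rank of the first
positive match has the closed form

    E(r) = 1 + sum_{j=1..Nn} (1 - j/(Nn+1))^(Np-1)

The CIF is E(r) divided by the observed average rank O(r): the factor
by which the embedding shrinks the diagnostic search space relative to
chance.  A randomly placed class has CIF ~= 1; a fully separated class
attains the maximum CIF = E(r) (every observed rank 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class CIFResult:
    label: object
    n_positive: int
    n_negative: int
    expected_rank: float
    observed_rank: float
    cif: float
    per_query_ranks: np.ndarray
    max_cif: float                       # attained when O(r) = 1
    ci95: tuple[float, float] | None = None


def expected_rank(n_positive: int, n_negative: int) -> float:
    """Expected rank of the nearest positive match under random ranking.

    Computed stably in log space; exact for the degenerate cases
    (no negatives -> 1; a single positive has no match partner, but the
    formula's empty product still yields the correct 1 + Nn/... limit).
    """
    np_, nn = int(n_positive), int(n_negative)
    if np_ < 1 or nn < 0:
        raise ValueError("need n_positive >= 1 and n_negative >= 0")
    if nn == 0:
        return 1.0
    j = np.arange(1, nn + 1, dtype=float)
    base = 1.0 - j / (nn + 1.0)
    if np_ == 1:
        # no other positive: the "first match" never arrives; the sum is Nn
        return 1.0 + float(nn)
    with np.errstate(divide="ignore"):
        terms = np.exp((np_ - 1) * np.log(base))
    return 1.0 + float(np.sum(terms))


def _rank_of_query(d_query: np.ndarray, pos_mask: np.ndarray,
                   query: int) -> float:
    """1 + negatives strictly closer than the nearest positive (ties half)."""
    d = d_query.copy()
    d[query] = np.inf
    d_pos = d[pos_mask].min()
    d_neg = d[~pos_mask]
    closer = int(np.sum(d_neg < d_pos))
    ties = int(np.sum(d_neg == d_pos))
    return 1.0 + closer + 0.5 * ties


def observed_rank(
    points: np.ndarray,
    labels: np.ndarray,
    class_label: object,
) -> tuple[float, np.ndarray]:
    """Observed average rank of the nearest same-class match.

    For every member of the class, rank = 1 + number of out-of-class
    instances strictly closer than its nearest same-class instance;
    out-of-class instances at exactly that distance count one half
    (average over tie-break orders).  Returns (O(r), per-query ranks).
    """
    x = np.asarray(points, float)
    labels = np.asarray(labels)
    members = np.where(labels == class_label)[0]
    if len(members) < 2:
        raise ValueError("observed rank needs at least 2 class members")
    d = cdist(x, x)
    ranks = []
    for q in members:
        pos_mask = labels == class_label
        pos_mask = pos_mask.copy()
        pos_mask[q] = False
        full_mask = np.zeros(len(x), bool)
        full_mask[pos_mask] = True
        ranks.append(_rank_of_query(d[q], full_mask, q))
    ranks = np.array(ranks)
    return float(ranks.mean()), ranks


def clustering_improvement_factor(
    points: np.ndarray,
    labels: np.ndarray,
    class_label: object,
    bootstrap: int = 0,
    seed: int = 0,
) -> CIFResult:
    """CIF = E(r) / O(r) for one class in an embedded point set.

    With ``bootstrap`` > 0, a 95% interval on the CIF is estimated by
    resampling the per-query ranks.
    """
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == class_label))
    n_neg = int(len(labels) - n_pos)
    e_r = expected_rank(n_pos, n_neg)
    o_r, ranks = observed_rank(points, labels, class_label)
    ci = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(ranks), size=(bootstrap, len(ranks)))
        boots = e_r / ranks[idx].mean(axis=1)
        ci = (float(np.percentile(boots, 2.5)),
              float(np.percentile(boots, 97.5)))
    return CIFResult(
        label=class_label,
        n_positive=n_pos,
        n_negative=n_neg,
        expected_rank=e_r,
        observed_rank=o_r,
        cif=e_r / o_r,
        per_query_ranks=ranks,
        max_cif=e_r,
        ci95=ci,
    )
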