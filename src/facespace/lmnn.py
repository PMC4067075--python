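"""Large-margin nearest neighbour (LMNN) metric learning.

Learns a linear transform L so that the induced Mahalanobis distance
d(x, y)^2 = (x-y)^T L^T L (x-y) pulls each point's k same-class
"target neighbours" close while pushing differently-labelled
"impostors" at least a unit margin further away:

    f(L) = (1-mu) * sum_{j~>i} |L(x_i-x_j)|^2
         + mu * sum_{j~>i, l: y_l != y_i}
               [1 + |L(x_i-x_j)|^2 - |L(x_i-x_l)|^2]_+

Target neighbours are fixed from the input (Euclidean) space.  The
objective is minimized by gradient descent with an adaptive step:
steps that would increase f are rejected and the step size halved, so
the accepted objective sequence is non-increasing by construction.
L may be rectangular (out_dim x in_dim); it is initialized from the
leading principal directions of the training data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class LMNNResult:
    L: np.ndarray                 # (out_dim, in_dim)
    objective_path: np.ndarray    # accepted objective values, non-increasing
    n_iter: int


def _target_neighbors(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """(n, k) indices of each point's k nearest same-class neighbours."""
    n = len(x)
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    targets = np.empty((n, k), dtype=int)
    for i in range(n):
        same = np.where(y == y[i])[0]
        same = same[same != i]
        if len(same) < k:
            raise ValueError(
                f"class {y[i]!r} needs at least k+1={k + 1} members")
        order = same[np.argsort(d[i, same], kind="stable")]
        targets[i] = order[:k]
    return targets


def _objective_and_grad_matrix(
    x: np.ndarray, y: np.ndarray, L: np.ndarray,
    targets: np.ndarray, mu: float,
) -> tuple[float, np.ndarray]:
    """Objective f(L) and the PSD matrix M with grad = 2 L M."""
    n, d = x.shape
    z = x @ L.T
    dist2 = cdist(z, z, "sqeuclidean")

    pull = 0.0
    m = np.zeros((d, d))
    hinge = 0.0
    for i in range(n):
        diff_mask = y != y[i]
        for j in targets[i]:
            dij = dist2[i, j]
            pull += dij
            vij = x[i] - x[j]
            m += (1.0 - mu) * np.outer(vij, vij)
            # impostors: y_l != y_i with dist2[i,l] < dij + 1
            viol = diff_mask & (dist2[i] < dij + 1.0)
            idx = np.where(viol)[0]
            if len(idx):
                hinge += np.sum(1.0 + dij - dist2[i, idx])
                m += mu * len(idx) * np.outer(vij, vij)
                vil = x[i] - x[idx]
                m -= mu * (vil.T @ vil)
    f = (1.0 - mu) * pull + mu * hinge
    return f, m


def lmnn_fit(
    x: np.ndarray,
    y: np.ndarray,
    out_dim: int | None = None,
    k: int = 3,
    mu: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-7,
    seed: int = 0,
) -> LMNNResult:
    """Fit the LMNN transform; see module docstring.

    ``seed`` only matters for the (deterministic) PCA initialization
    tie-breaks and is kept for interface stability.
    """
    x = np.asarray(x, float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("metric learning needs at least 2 classes")
    n, d = x.shape
    out_dim = d if out_dim is None else int(out_dim)
    if out_dim > d:
        raise ValueError("out_dim cannot exceed the input dimension")

    targets = _target_neighbors(x, y, k)

    # initialize from the leading principal directions (rows of L)
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    L = vt[:out_dim].copy()

    f, m = _objective_and_grad_matrix(x, y, L, targets, mu)
    path = [f]
    lr = 1e-6 / max(1.0, abs(f) / (n * d))  # conservative initial step
    it = 0
    for it in range(1, max_iter + 1):
        grad = 2.0 * L @ m
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            break
        accepted = False
        for _ in range(30):
            cand = L - lr * grad
            f_new, m_new = _objective_and_grad_matrix(x, y, cand, targets, mu)
            if f_new < f:
                L, f, m = cand, f_new, m_new
                path.append(f)
                lr *= 1.15
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            break
        if len(path) > 1 and (path[-2] - path[-1]) < tol * max(1.0, abs(path[-2])):
            break
    return LMNNResult(L=L, objective_path=np.array(path), n_iter=it)
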