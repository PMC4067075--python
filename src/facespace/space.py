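"""Clinical face phenotype space construction.

Shape (630-d) and appearance (1937-d) descriptors are reduced by
independent per-block PCA (default 100 + 240 = 340 components), then a
rectangular LMNN transform L (default 270 x 340) is learned on the
concatenated scores.  Distances in the resulting space are plain
Euclidean distances of the embedded vectors, equivalently the
Mahalanobis distance induced by L on the PCA scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .descriptors import APPEARANCE_DIM, SHAPE_DIM
from .lmnn import lmnn_fit

DEFAULT_N_SHAPE = 100
DEFAULT_N_APPEARANCE = 240
DEFAULT_OUT_DIM = 270


@dataclass
class EmbeddedFace:
    vector: np.ndarray
    image_id: str = ""
    label: object = None


@dataclass
class PhenotypeSpaceModel:
    shape_pca: PCA | None = None
    appearance_pca: PCA | None = None
    L: np.ndarray | None = None
    training_labels: np.ndarray | None = None
    k_lmnn: int = 3
    seed: int = 0
    config: dict = field(default_factory=dict)

    @property
    def is_fitted(self) -> bool:
        return (self.shape_pca is not None and self.appearance_pca is not None
                and self.L is not None)

    @property
    def pca_dim(self) -> int:
        return (self.shape_pca.n_components_
                + self.appearance_pca.n_components_)

    @property
    def out_dim(self) -> int:
        return self.L.shape[0]

    def class_counts(self) -> dict:
        vals, counts = np.unique(self.training_labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def fit_reduction(
    shape_matrix: np.ndarray,
    appearance_matrix: np.ndarray,
    n_shape: int = DEFAULT_N_SHAPE,
    n_appearance: int = DEFAULT_N_APPEARANCE,
) -> tuple[PCA, PCA, np.ndarray]:
    """Independent PCA per descriptor block.

    Returns the fitted blocks and the concatenated training scores
    (n_samples, n_shape + n_appearance).
    """
    s = np.asarray(shape_matrix, float)
    a = np.asarray(appearance_matrix, float)
    if s.shape[0] != a.shape[0]:
        raise ValueError("blocks disagree on the number of samples")
    max_rank = s.shape[0] - 1
    if n_shape > min(max_rank, s.shape[1]) or n_appearance > min(max_rank, a.shape[1]):
        raise ValueError("more PCA components than the data rank supports")
    shape_pca = PCA(n_components=n_shape, svd_solver="full").fit(s)
    app_pca = PCA(n_components=n_appearance, svd_solver="full").fit(a)
    scores = np.hstack([shape_pca.transform(s), app_pca.transform(a)])
    return shape_pca, app_pca, scores


def fit_metric(
    scores: np.ndarray,
    labels: np.ndarray,
    out_dim: int = DEFAULT_OUT_DIM,
    k: int = 3,
    max_iter: int = 200,
    seed: int = 0,
):
    """Learn the LMNN transform on PCA scores; returns the fit result."""
    return lmnn_fit(scores, labels, out_dim=out_dim, k=k,
                    max_iter=max_iter, seed=seed)


def fit_phenotype_space(
    shape_matrix: np.ndarray,
    appearance_matrix: np.ndarray,
    labels: np.ndarray,
    n_shape: int = DEFAULT_N_SHAPE,
    n_appearance: int = DEFAULT_N_APPEARANCE,
    out_dim: int = DEFAULT_OUT_DIM,
    k: int = 3,
    max_iter: int = 200,
    seed: int = 0,
) -> tuple[PhenotypeSpaceModel, np.ndarray]:
    """End-to-end fit; returns (model, embedded training vectors)."""
    shape_pca, app_pca, scores = fit_reduction(
        shape_matrix, appearance_matrix, n_shape, n_appearance)
    res = fit_metric(scores, labels, out_dim=out_dim, k=k,
                     max_iter=max_iter, seed=seed)
    model = PhenotypeSpaceModel(
        shape_pca=shape_pca,
        appearance_pca=app_pca,
        L=res.L,
        training_labels=np.asarray(labels),
        k_lmnn=k,
        seed=seed,
        config={
            "n_shape": n_shape, "n_appearance": n_appearance,
            "out_dim": out_dim, "k": k, "max_iter": max_iter,
        },
    )
    return model, scores @ res.L.T


def transform_scores(model: PhenotypeSpaceModel,
                     shape_matrix: np.ndarray,
                     appearance_matrix: np.ndarray) -> np.ndarray:
    """PCA scores (pre-metric) for descriptor matrices."""
    if not model.is_fitted:
        raise ValueError("model not fitted")
    return np.hstack([
        model.shape_pca.transform(np.asarray(shape_matrix, float)),
        model.appearance_pca.transform(np.asarray(appearance_matrix, float)),
    ])


def embed(
    shape_vec: np.ndarray,
    appearance_vec: np.ndarray,
    model: PhenotypeSpaceModel,
    image_id: str = "",
    label: object = None,
) -> EmbeddedFace:
    """Embed one face: v = L @ concat(PCA_shape(s), PCA_app(a))."""
    s = np.asarray(shape_vec, float).reshape(1, -1)
    a = np.asarray(appearance_vec, float).reshape(1, -1)
    if s.shape[1] != SHAPE_DIM or a.shape[1] != APPEARANCE_DIM:
        raise ValueError(
            f"descriptor lengths must be {SHAPE_DIM}/{APPEARANCE_DIM}")
    scores = transform_scores(model, s, a)
    return EmbeddedFace((scores @ model.L.T)[0], image_id=image_id,
                        label=label)


def metric_distance(a: EmbeddedFace, b: EmbeddedFace) -> float:
    """Euclidean distance between embedded faces (the learned metric)."""
    va, vb = np.asarray(a.vector), np.asarray(b.vector)
    if va.shape != vb.shape:
        raise ValueError("embedding dimension mismatch")
    return float(np.linalg.norm(va - vb))
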