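"""File formats, model persistence and graph export.

Tabular artifacts are TSV/CSV for inspectability; the fitted space
model is the single binary container (NumPy archive with an embedded
JSON config, seed and checksum).  Landmark files use one row per point:

    image_id  point_index  point_name  x  y  confidence

with 1-based ``point_index`` consistent with the scheme (9 or 36
points per image) and 0-based pixel coordinates, origin top-left.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .geometry import Constellation
from .landmarks import scheme_names
from .space import PhenotypeSpaceModel
from .synthetic import Population

_COORD_COMMENT = ("# coordinates: 0-based pixels, origin top-left, "
                  "x rightward, y downward")
_LM_COLUMNS = ["image_id", "point_index", "point_name", "x", "y", "confidence"]
MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# landmark TSV
# ---------------------------------------------------------------------------

def write_landmarks(path, constellations, confidences=None) -> None:
    """Write constellations (iterable or dict of them) as landmark TSV."""
    if isinstance(constellations, dict):
        items = list(constellations.values())
    elif isinstance(constellations, Constellation):
        items = [constellations]
    else:
        items = list(constellations)
    rows = []
    for c in sorted(items, key=lambda c: c.image_id):
        names = scheme_names(c.scheme)
        conf = None if confidences is None else confidences.get(c.image_id)
        for i, (x, y) in enumerate(c.points):
            rows.append((c.image_id, i + 1, names[i], repr(float(x)),
                         repr(float(y)),
                         "" if conf is None else repr(float(conf[i]))))
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_COORD_COMMENT + "\n")
        fh.write("\t".join(_LM_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")


def read_landmarks(path) -> dict[str, Constellation]:
    """Parse a landmark TSV into constellations keyed by image id.

    Malformed rows raise with their line number; every image must have
    a complete 9- or 36-point index set.
    """
    path = Path(path)
    per_image: dict[str, dict[int, tuple[float, float]]] = {}
    with path.open(encoding="utf-8") as fh:
        lines = fh.readlines()
    data_started = False
    for ln, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if not data_started:
            if parts[: len(_LM_COLUMNS) - 1] != _LM_COLUMNS[:-1]:
                raise ValueError(f"{path}:{ln}: unexpected header {parts!r}")
            data_started = True
            continue
        if len(parts) < 5:
            raise ValueError(f"{path}:{ln}: expected >=5 columns, "
                             f"got {len(parts)}")
        try:
            idx = int(parts[1])
            x, y = float(parts[3]), float(parts[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed row: {exc}") from exc
        per_image.setdefault(parts[0], {})[idx] = (x, y)

    out = {}
    for image_id, pts in per_image.items():
        n = len(pts)
        # intended scheme from the largest index present
        expected = 9 if max(pts) <= 9 else 36
        missing = sorted(set(range(1, expected + 1)) - set(pts))
        if missing:
            raise ValueError(
                f"{path}: image {image_id!r} missing point index "
                f"{missing[0]} (found {n} of {expected} points)")
        if n not in (9, 36):
            raise ValueError(
                f"{path}: image {image_id!r} has {n} points; expected 9 or 36")
        arr = np.array([pts[i + 1] for i in range(n)])
        out[image_id] = Constellation(arr, "C9" if n == 9 else "C36",
                                      image_id)
    return out


def read_landmark_dir(directory) -> dict[str, Constellation]:
    """Parse every ``*.tsv`` in a directory (C9 and C36 files may mix)."""
    out = {}
    for p in sorted(Path(directory).glob("*.tsv")):
        out.update(read_landmarks(p))
    return out


# ---------------------------------------------------------------------------
# population CSV
# ---------------------------------------------------------------------------

def write_population(path, population: Population) -> None:
    population.to_frame().to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

def _model_arrays(model: PhenotypeSpaceModel) -> dict[str, np.ndarray]:
    return {
        "shape_mean": model.shape_pca.mean_,
        "shape_components": model.shape_pca.components_,
        "shape_variance": model.shape_pca.explained_variance_,
        "app_mean": model.appearance_pca.mean_,
        "app_components": model.appearance_pca.components_,
        "app_variance": model.appearance_pca.explained_variance_,
        "L": model.L,
        "training_labels": np.asarray(model.training_labels, dtype="U64"),
    }


def _checksum(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arrays[key]).tobytes())
    return h.hexdigest()


def save_space_model(model: PhenotypeSpaceModel, path) -> None:
    """Persist a fitted model; embeddings reload bit-identically."""
    if not model.is_fitted:
        raise ValueError("cannot save an unfitted model")
    arrays = _model_arrays(model)
    meta = {
        "version": MODEL_FORMAT_VERSION,
        "k_lmnn": model.k_lmnn,
        "seed": model.seed,
        "config": model.config,
        "checksum": _checksum(arrays),
    }
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_space_model(path) -> PhenotypeSpaceModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        if meta.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model container version {meta.get('version')}")
        arrays = {k: npz[k] for k in npz.files if k != "meta"}
    if _checksum(arrays) != meta["checksum"]:
        raise ValueError("model container checksum mismatch; refusing load")

    def _pca(mean: np.ndarray, components: np.ndarray,
             variance: np.ndarray) -> PCA:
        p = PCA(n_components=components.shape[0])
        p.mean_ = mean
        p.components_ = components
        p.explained_variance_ = variance
        p.n_components_ = components.shape[0]
        p.n_features_in_ = mean.shape[0]
        return p

    return PhenotypeSpaceModel(
        shape_pca=_pca(arrays["shape_mean"], arrays["shape_components"],
                       arrays["shape_variance"]),
        appearance_pca=_pca(arrays["app_mean"], arrays["app_components"],
                            arrays["app_variance"]),
        L=arrays["L"],
        training_labels=arrays["training_labels"],
        k_lmnn=meta["k_lmnn"],
        seed=meta["seed"],
        config=meta["config"],
    )


# ---------------------------------------------------------------------------
# neighbour-graph export
# ---------------------------------------------------------------------------

def neighbor_graph(vectors: np.ndarray, ids: list[str],
                   k: int = 10) -> pd.DataFrame:
    """Directed k-NN edge list (source, target, distance), n*k rows.

    Suitable for external force-directed layout tools; distances are
    the learned-metric (Euclidean) distances between embeddings.
    """
    x = np.asarray(vectors, float)
    n = len(x)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points")
    from scipy.spatial.distance import cdist
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    rows = []
    for i in range(n):
        order = np.lexsort((np.array(ids, dtype=object), d[i]))[:k]
        for j in order:
            rows.append((ids[i], ids[j], d[i, j]))
    return pd.DataFrame(rows, columns=["source", "target", "distance"])


def export_neighbor_graph(path, vectors: np.ndarray, ids: list[str],
                          k: int = 10) -> pd.DataFrame:
    frame = neighbor_graph(vectors, ids, k)
    frame.to_csv(path, index=False)
    return frame
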