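"""Constellation data model and Procrustes registration.

Similarity Procrustes (rotation + isotropic scale + translation, with
reflection optionally allowed) is the work-horse registration used by
the shape descriptor, the exemplar shape prior and face averaging.
The generalized (iterative) mean follows the usual align/re-average
scheme with the mean normalized to centroid 0 and centroid size 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .landmarks import SCHEMES, C9_IN_C36, mirror_map


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class Constellation:
    """An ordered 2-D landmark set in pixel coordinates.

    ``scheme`` is ``"C9"`` or ``"C36"``; coordinates are 0-based pixels
    with the origin at the top-left corner, y downward.
    """

    points: np.ndarray
    scheme: str = "C36"
    image_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        expected = SCHEMES[self.scheme]
        if self.points.shape != (expected, 2):
            raise ValueError(
                f"{self.scheme} requires {expected} points, got shape "
                f"{self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def copy(self) -> "Constellation":
        return replace(self, points=self.points.copy())

    def c9(self) -> "Constellation":
        """The inner 9-point subset of a C36 constellation."""
        if self.scheme == "C9":
            return self.copy()
        return Constellation(self.points[list(C9_IN_C36)], "C9", self.image_id)

    def mirrored(self, width: float) -> "Constellation":
        """Mirror about the vertical axis of an image of given width.

        Flips x -> width-1-x and applies the scheme's left/right index
        swap so that point semantics are preserved.
        """
        pts = self.points.copy()
        pts[:, 0] = (width - 1.0) - pts[:, 0]
        return Constellation(pts[mirror_map(self.scheme)], self.scheme,
                             self.image_id)


@dataclass
class PoseTransform:
    """Similarity transform ``p -> scale * R(rotation) @ F @ p + translation``.

    ``F`` flips the x axis when ``reflection`` is set.  Angles are in
    radians, positive in the direction from +x towards +y (screen
    clockwise, as y points down).
    """

    rotation: float = 0.0
    scale: float = 1.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    reflection: bool = False

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        r = np.array([[c, -s], [s, c]])
        if self.reflection:
            r = r @ np.diag([-1.0, 1.0])
        return self.scale * r

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.matrix.T + self.translation

    def apply_constellation(self, c: Constellation) -> Constellation:
        return replace(c, points=self.apply(c.points))

    def inverse(self) -> "PoseTransform":
        a_inv = np.linalg.inv(self.matrix)
        t_inv = -a_inv @ self.translation
        return PoseTransform.from_matrix(a_inv, t_inv)

    def compose(self, other: "PoseTransform") -> "PoseTransform":
        """Transform applying ``other`` first, then ``self``."""
        a = self.matrix @ other.matrix
        t = self.matrix @ other.translation + self.translation
        return PoseTransform.from_matrix(a, t)

    @staticmethod
    def from_matrix(a: np.ndarray, t: np.ndarray) -> "PoseTransform":
        det = np.linalg.det(a)
        if det == 0:
            raise ValueError("degenerate linear part")
        reflection = det < 0
        b = a @ np.diag([-1.0, 1.0]) if reflection else a
        scale = float(np.sqrt(abs(det)))
        rotation = float(np.arctan2(b[1, 0], b[0, 0]))
        return PoseTransform(rotation, scale, np.asarray(t, float), reflection)


@dataclass
class ProcrustesFit:
    transform: PoseTransform
    aligned: Constellation
    sse: float


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def procrustes_align(source: Constellation, target: Constellation,
                     allow_reflection: bool = False) -> ProcrustesFit:
    """Least-squares similarity registration of ``source`` onto ``target``.

    Returns the similarity transform minimizing the sum of squared
    point-to-point distances, the transformed source, and the residual
    sum of squares (px^2).  Reflection is excluded unless requested;
    mirror handling elsewhere is explicit through the landmark swap map.
    """
    if source.scheme != target.scheme:
        raise ValueError(
            f"scheme mismatch: {source.scheme} vs {target.scheme}")
    x = source.points
    y = target.points
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    norm_x = np.linalg.norm(xc)
    if norm_x == 0 or np.linalg.norm(yc) == 0:
        raise ValueError("degenerate constellation: all points coincident")

    # orthogonal part via SVD of the cross-covariance
    m = yc.T @ xc
    u, s, vt = np.linalg.svd(m)
    d = np.ones(2)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        d[-1] = -1.0
    r = u @ np.diag(d) @ vt
    scale = float((s @ d) / (norm_x ** 2))
    if scale <= 0:
        # pathological anti-correlated configuration; fall back to tiny scale
        scale = np.finfo(float).tiny
    a = scale * r
    t = my - a @ mx
    aligned_pts = x @ a.T + t
    sse = float(np.sum((aligned_pts - y) ** 2))
    return ProcrustesFit(
        transform=PoseTransform.from_matrix(a, t),
        aligned=replace(source, points=aligned_pts),
        sse=sse,
    )


def centroid_size(points: np.ndarray) -> float:
    c = points - points.mean(axis=0)
    return float(np.linalg.norm(c))


def generalized_procrustes_mean(
    constellations: list[Constellation],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Constellation:
    """Iterative Procrustes mean shape.

    Aligns every constellation to the current mean, re-averages, and
    repeats until the mean moves by less than ``tol`` (in normalized
    units) or ``max_iter`` is reached.  The returned mean is centred at
    the origin with centroid size 1.
    """
    if not constellations:
        raise ValueError("need at least one constellation")
    scheme = constellations[0].scheme
    if any(c.scheme != scheme for c in constellations):
        raise ValueError("mixed schemes")

    def _normalize(p: np.ndarray) -> np.ndarray:
        p = p - p.mean(axis=0)
        return p / centroid_size(p)

    mean = _normalize(constellations[0].points)
    for _ in range(max_iter):
        ref = Constellation(mean, scheme)
        aligned = np.stack([
            procrustes_align(c, ref).aligned.points for c in constellations
        ])
        new_mean = _normalize(aligned.mean(axis=0))
        shift = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if shift < tol:
            break
    # canonical orientation (removes the rotation ambiguity of the mean,
    # making it independent of input order): inter-ocular axis horizontal
    i, j = (8, 14) if scheme == "C36" else (0, 3)
    v = mean[j] - mean[i]
    ang = np.arctan2(v[1], v[0])
    c, s = np.cos(-ang), np.sin(-ang)
    mean = mean @ np.array([[c, -s], [s, c]]).T
    return Constellation(mean, scheme, image_id="<mean>")


# ---------------------------------------------------------------------------
# auxiliary anatomical measures (C9)
# ---------------------------------------------------------------------------

def auxiliary_points(c9: Constellation) -> np.ndarray:
    """Left eye centre, right eye centre, nasion and mouth centre.

    Eye centres are the midpoints of each eye's canthi, the nasion the
    midpoint between the medial canthi, and the mouth centre the
    midpoint of the vermilion lateral midpoints.  Returned in that
    fixed order as a (4, 2) array.
    """
    if c9.scheme != "C9":
        raise ValueError("auxiliary_points requires a C9 constellation")
    p = c9.points
    left_eye = (p[0] + p[1]) / 2.0
    right_eye = (p[2] + p[3]) / 2.0
    nasion = (p[1] + p[2]) / 2.0
    mouth = (p[7] + p[8]) / 2.0
    return np.stack([left_eye, right_eye, nasion, mouth])


def pf_length(c9: Constellation) -> float:
    """Palpebral fissure length: mean canthus-to-canthus span of the eyes."""
    if c9.scheme != "C9":
        raise ValueError("pf_length requires a C9 constellation")
    p = c9.points
    left = float(np.linalg.norm(p[0] - p[1]))
    right = float(np.linalg.norm(p[2] - p[3]))
    return 0.5 * (left + right)
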