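"""Average faces, control-to-syndrome morphs and distortion graphs.

Faces are registered to a canonical mesh (Delaunay triangulation of a
generalized Procrustes mean constellation, rastered on a fixed canvas),
their pixel content mapped triangle-by-triangle by piecewise affine
warping, and averaged pixelwise.  Morphs linearly interpolate both the
mesh, M_k = M_s + k/K (M_c - M_s), and the appearance,
A_k = A_s + k/K (A_c - A_s); each frame warps A_k onto M_k.
Distortion graphs report the relative change of every pairwise
landmark distance of a syndrome mean against the control mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial.distance import pdist
from skimage.transform import PiecewiseAffineTransform, warp

from .geometry import Constellation, generalized_procrustes_mean, procrustes_align

DEFAULT_CANVAS_SIZE = 256


@dataclass
class FaceCanvas:
    """Canonical raster frame holding the mean mesh."""

    points: np.ndarray            # (36, 2) mean constellation, canvas coords
    size: int
    triangles: np.ndarray = field(init=False)
    mask: np.ndarray = field(init=False)  # inside-hull pixels

    def __post_init__(self) -> None:
        tri = Delaunay(self.points)
        self.triangles = tri.simplices.copy()
        yy, xx = np.mgrid[0:self.size, 0:self.size]
        grid = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
        inside = tri.find_simplex(grid) >= 0
        self.mask = inside.reshape(self.size, self.size)

    @classmethod
    def from_mean(cls, mean: Constellation, size: int = DEFAULT_CANVAS_SIZE,
                  margin: float = 0.08) -> "FaceCanvas":
        p = mean.points
        lo, hi = p.min(axis=0), p.max(axis=0)
        span = float((hi - lo).max())
        scale = size * (1.0 - 2.0 * margin) / span
        centre = (lo + hi) / 2.0
        pts = (p - centre) * scale + size / 2.0
        return cls(pts, size)


@dataclass
class MeanFace:
    canvas: FaceCanvas
    constellation: Constellation   # group mean shape in canvas coordinates
    appearance: np.ndarray         # (size, size) masked mean of warped faces
    n_faces: int
    excluded: list[str] = field(default_factory=list)


def warp_to_mesh(image: np.ndarray, src_points: np.ndarray,
                 dst_points: np.ndarray, size: int) -> np.ndarray:
    """Piecewise affine warp placing ``src_points`` onto ``dst_points``.

    Returns a (size, size) raster; pixels with no source default to 0.
    """
    # warp() needs the output->input map: dst raster coords -> image coords
    if hasattr(PiecewiseAffineTransform, "from_estimate"):
        tf = PiecewiseAffineTransform.from_estimate(dst_points, src_points)
        if not tf:
            raise ValueError("degenerate mesh: piecewise affine fit failed")
    else:  # older scikit-image
        tf = PiecewiseAffineTransform()
        if not tf.estimate(dst_points, src_points):
            raise ValueError("degenerate mesh: piecewise affine fit failed")
    return warp(np.asarray(image, float), tf, output_shape=(size, size),
                mode="constant", cval=0.0, preserve_range=True)


def _landmarks_in_bounds(image: np.ndarray, c: Constellation) -> bool:
    h, w = image.shape[:2]
    p = c.points
    return bool((p[:, 0] >= 0).all() and (p[:, 0] <= w - 1).all()
                and (p[:, 1] >= 0).all() and (p[:, 1] <= h - 1).all())


def mean_face(
    records: list[tuple[np.ndarray, Constellation]],
    canvas: FaceCanvas | None = None,
    size: int = DEFAULT_CANVAS_SIZE,
) -> MeanFace:
    """Average a group of faces on a canonical mesh.

    The mesh defaults to the group's own generalized Procrustes mean;
    passing a shared ``canvas`` (e.g. built from controls) registers
    several groups to one template so their averages can be morphed.
    Faces whose landmarks fall outside their image are excluded and
    reported.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 faces to average")
    excluded = [c.image_id for img, c in records
                if not _landmarks_in_bounds(img, c)]
    usable = [(img, c) for img, c in records if _landmarks_in_bounds(img, c)]
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable faces after bounds check")

    shapes = [c for _, c in usable]
    group_mean = generalized_procrustes_mean(shapes)
    if canvas is None:
        canvas = FaceCanvas.from_mean(group_mean, size)
    # group mean expressed in canvas coordinates
    mean_in_canvas = procrustes_align(
        group_mean,
        Constellation(canvas.points, "C36"),
    ).aligned

    acc = np.zeros((canvas.size, canvas.size))
    for img, c in usable:
        acc += warp_to_mesh(img, c.points, canvas.points, canvas.size)
    appearance = acc / len(usable)
    appearance[~canvas.mask] = 0.0
    return MeanFace(canvas, mean_in_canvas, appearance, len(usable), excluded)


@dataclass
class MorphSequence:
    k_frames: int
    meshes: list[np.ndarray]        # M_k, canvas coordinates
    appearances: list[np.ndarray]   # A_k on the canonical mesh
    canvas: FaceCanvas
    endpoints: tuple[str, str] = ("syndrome", "control")

    def rendered_frame(self, k: int) -> np.ndarray:
        """Frame k: appearance A_k warped onto mesh M_k."""
        return warp_to_mesh(self.appearances[k], self.canvas.points,
                            self.meshes[k], self.canvas.size)


def morph_sequence(avg_s: MeanFace, avg_c: MeanFace, k_frames: int,
                   labels: tuple[str, str] = ("syndrome", "control")
                   ) -> MorphSequence:
    """Linear morph from a syndrome average (k=0) to controls (k=K)."""
    if avg_s.canvas.size != avg_c.canvas.size or not np.allclose(
            avg_s.canvas.points, avg_c.canvas.points):
        raise ValueError("group averages were not built on a shared canvas")
    if k_frames < 1:
        raise ValueError("need at least 1 frame step")
    m_s, m_c = avg_s.constellation.points, avg_c.constellation.points
    a_s, a_c = avg_s.appearance, avg_c.appearance
    meshes, appearances = [], []
    for k in range(k_frames + 1):
        if k == k_frames:          # exact endpoint, no float residue
            meshes.append(m_c.copy())
            appearances.append(a_c.copy())
            continue
        t = k / k_frames
        meshes.append(m_s + t * (m_c - m_s))
        appearances.append(a_s + t * (a_c - a_s))
    return MorphSequence(k_frames, meshes, appearances, avg_s.canvas, labels)


def distortion_graph(mean_s: Constellation,
                     mean_c: Constellation) -> np.ndarray:
    """Per-edge relative distance change of a syndrome mean vs controls.

    Returns the 630-vector of (registered syndrome distance / control
    distance) - 1 in lexicographic pair order; negative entries mark
    distances shorter than in controls.
    """
    if mean_s.scheme != "C36" or mean_c.scheme != "C36":
        raise ValueError("distortion graph requires C36 means")
    ref = pdist(mean_c.points)
    if np.any(ref <= 0):
        raise ValueError("degenerate control distance")
    aligned = procrustes_align(mean_s, mean_c).aligned
    return pdist(aligned.points) / ref - 1.0
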