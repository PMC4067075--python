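"""Shape, appearance and PHOG patch descriptors.

* The shape descriptor is the vector of all 630 pairwise distances
  among the 36 landmarks, measured after similarity registration to a
  canonical mean constellation and divided elementwise by the same
  distances on the average control face, so 1.0 means "identical to
  controls".
* The appearance descriptor concatenates grayscale samples from 13
  elliptical patches (9 inner points + 4 auxiliary points), 149 samples
  per patch, total 1937.  The patch geometry is defined once on a
  canonical face template; an affine transform fitted to the 13 points
  carries the sampling lattice into each image.
* PHOG (pyramidal histogram of oriented gradients) describes square
  patches for the part detectors of the consensus-of-exemplars search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import pdist

from .geometry import Constellation, auxiliary_points, pf_length, procrustes_align
from .landmarks import C36_TEMPLATE, C9_IN_C36

SHAPE_DIM = 630          # C(36, 2)
N_PATCHES = 13
SAMPLES_PER_PATCH = 149
APPEARANCE_DIM = N_PATCHES * SAMPLES_PER_PATCH  # 1937
COMBINED_DIM = SHAPE_DIM + APPEARANCE_DIM       # 2567

#: ring sizes of the per-patch sampling lattice (1 centre + 7 rings = 149)
_RING_COUNTS = (8, 12, 16, 20, 24, 28, 40)


@dataclass
class ShapeDescriptor:
    values: np.ndarray  # (630,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (SHAPE_DIM,):
            raise ValueError(f"shape descriptor must have {SHAPE_DIM} entries")


@dataclass
class AppearanceDescriptor:
    values: np.ndarray  # (1937,)
    out_of_bounds: bool = False  # any lattice sample fell outside the image

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (APPEARANCE_DIM,):
            raise ValueError(
                f"appearance descriptor must have {APPEARANCE_DIM} entries")


def _lattice_offsets(radius: float) -> np.ndarray:
    """Fixed concentric-ring lattice of 149 unit positions, scaled."""
    pts = [np.zeros(2)]
    n_rings = len(_RING_COUNTS)
    for k, count in enumerate(_RING_COUNTS, start=1):
        r = radius * k / n_rings
        ang = 2.0 * np.pi * np.arange(count) / count
        pts.append(np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1))
    out = np.concatenate([np.atleast_2d(p) for p in pts], axis=0)
    assert out.shape == (SAMPLES_PER_PATCH, 2)
    return out


@dataclass
class PatchTemplate:
    """Canonical 13-point face shape template with its sampling lattice.

    Patch radius defaults to 0.35 palpebral-fissure lengths of the
    canonical template: large enough to cover local anatomy, small
    enough that eye and nose patches do not overlap.
    """

    points: np.ndarray = field(default=None)  # (13, 2) canonical coordinates
    radius_pf: float = 0.35

    def __post_init__(self) -> None:
        if self.points is None:
            c9 = Constellation(C36_TEMPLATE[list(C9_IN_C36)], "C9")
            self.points = np.vstack([c9.points, auxiliary_points(c9)])
        self.points = np.asarray(self.points, float)
        if self.points.shape != (N_PATCHES, 2):
            raise ValueError("patch template requires 13 points")
        c9 = Constellation(self.points[:9], "C9")
        self.radius = self.radius_pf * pf_length(c9)
        self.lattice = _lattice_offsets(self.radius)


def thirteen_points(c9: Constellation) -> np.ndarray:
    """The 9 inner points plus the 4 derived auxiliary points, (13, 2)."""
    return np.vstack([c9.points, auxiliary_points(c9)])


# ---------------------------------------------------------------------------
# shape descriptor
# ---------------------------------------------------------------------------

def reference_distances(canonical_mean: Constellation) -> np.ndarray:
    """Control reference: pairwise distances of the mean control face."""
    d = pdist(canonical_mean.points)
    if np.any(d <= 0):
        raise ValueError("degenerate reference: zero pairwise distance")
    return d


def shape_descriptor(
    c36: Constellation,
    canonical_mean: Constellation,
    control_reference: np.ndarray | None = None,
) -> ShapeDescriptor:
    """Relative pairwise-distance shape vector (630 entries).

    The constellation is similarity-registered to ``canonical_mean``;
    its pairwise distances (lexicographic i<j order) are divided by the
    corresponding distances of the control reference (by default the
    canonical mean itself), so the average control face maps to all-ones.
    """
    if c36.scheme != "C36":
        raise ValueError("shape descriptor requires a C36 constellation")
    if control_reference is None:
        control_reference = reference_distances(canonical_mean)
    ref = np.asarray(control_reference, float)
    if ref.shape != (SHAPE_DIM,) or np.any(ref <= 0):
        raise ValueError("control reference must hold 630 positive distances")
    fit = procrustes_align(c36, canonical_mean)
    return ShapeDescriptor(pdist(fit.aligned.points) / ref)


# ---------------------------------------------------------------------------
# appearance descriptor
# ---------------------------------------------------------------------------

def _fit_affine(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine ``dst ~ A @ src + t``; returns (A, t)."""
    n = src.shape[0]
    g = np.hstack([src, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(g, dst, rcond=None)
    return coef[:2].T, coef[2]


def appearance_descriptor(
    image: np.ndarray,
    c9: Constellation,
    template: PatchTemplate | None = None,
) -> AppearanceDescriptor:
    """Concatenated grayscale patch samples around the 13 face points.

    An affine transform T is fitted from the 13 image points to the
    canonical template; the canonical circular lattice of each patch is
    mapped back through T^-1 (becoming an ellipse in the image) and the
    min-max normalized image is sampled by bilinear interpolation.
    Samples outside the image take the nearest border value and set the
    ``out_of_bounds`` flag.
    """
    if c9.scheme != "C9":
        raise ValueError("appearance descriptor requires a C9 constellation")
    if template is None:
        template = PatchTemplate()
    img = np.asarray(image, float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        # constant image: nothing to normalize, sample the value itself
        img = np.clip(img, 0.0, 1.0)

    pts13 = thirteen_points(c9)
    a, t = _fit_affine(pts13, template.points)
    a_inv = np.linalg.inv(a)

    # canonical lattice -> image coordinates through T^-1
    canon = (template.points[:, None, :] + template.lattice[None, :, :])
    flat = canon.reshape(-1, 2)
    img_xy = (flat - t) @ a_inv.T

    h, w = img.shape
    oob = bool((img_xy[:, 0] < 0).any() or (img_xy[:, 0] > w - 1).any()
               or (img_xy[:, 1] < 0).any() or (img_xy[:, 1] > h - 1).any())
    samples = map_coordinates(img, [img_xy[:, 1], img_xy[:, 0]],
                              order=1, mode="nearest")
    return AppearanceDescriptor(samples, out_of_bounds=oob)


# ---------------------------------------------------------------------------
# PHOG
# ---------------------------------------------------------------------------

def phog_length(levels: int, bins: int) -> int:
    return bins * sum(4 ** l for l in range(levels + 1))


def phog_descriptor(patch: np.ndarray, levels: int = 2, bins: int = 8) -> np.ndarray:
    """Pyramidal histogram of (unsigned) gradient orientations.

    Level l divides the square patch into a 2^l x 2^l grid of cells;
    each cell is a magnitude-weighted orientation histogram over
    [0, pi).  Cell histograms are concatenated in raster order and each
    level is L1-normalized independently.  A constant patch yields the
    all-zero vector.
    """
    p = np.asarray(patch, float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("patch must be square")
    side = p.shape[0]
    if side < 2 ** levels:
        raise ValueError(f"patch side {side} too small for {levels} levels")
    gy, gx = np.gradient(p)
    mag = np.hypot(gx, gy)
    ori = np.mod(np.arctan2(gy, gx), np.pi)
    bin_idx = np.minimum((ori / np.pi * bins).astype(int), bins - 1)

    out = []
    for l in range(levels + 1):
        ncell = 2 ** l
        edges = np.linspace(0, side, ncell + 1).astype(int)
        hist = np.zeros((ncell, ncell, bins))
        for i in range(ncell):
            for j in range(ncell):
                sl = (slice(edges[i], edges[i + 1]),
                      slice(edges[j], edges[j + 1]))
                hist[i, j] = np.bincount(bin_idx[sl].ravel(),
                                         weights=mag[sl].ravel(),
                                         minlength=bins)
        level_vec = hist.reshape(-1)
        s = level_vec.sum()
        if s > 0:
            level_vec = level_vec / s
        out.append(level_vec)
    return np.concatenate(out)
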