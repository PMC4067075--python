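"""Automatic landmark annotation.

Three stages locate the 36-point constellation in a photo:

1. a pluggable *base detector* proposes the 9 inner points (C9) with a
   confidence index;
2. *transformation consensus*: the image is re-submitted under ~100
   variants (mirror x partial rotations within +/-45 degrees x frame
   paddings); detections are mapped back through the inverse transform
   and the high-confidence ones are confidence-weighted averaged;
3. *consensus of exemplars* (CoE): annotated reference faces provide a
   shape prior that, per landmark, restricts the search to a region of
   interest; Gaussian-kernel SVM part detectors on PHOG patches score
   candidate positions; registered exemplar constellations vote; the
   final point maximizes the product of the candidate and exemplar
   density maps.

The shipped :class:`SketchOracleDetector` reads the ground truth
embedded in synthetic sketches (optionally corrupted by noise) so the
consensus machinery can be validated without a trained face detector;
any external detector can be adapted through :class:`BaseDetector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.spatial.distance import cdist
from skimage.transform import AffineTransform, warp

from .descriptors import phog_descriptor
from .geometry import Constellation, PoseTransform, pf_length, procrustes_align
from .landmarks import C9_MIRROR_MAP, C36_MIRROR_MAP


# ---------------------------------------------------------------------------
# images and detectors
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedImage:
    """An image optionally carrying ground truth (synthetic sketches)."""

    pixels: np.ndarray
    truth_c9: Constellation | None = None
    truth_c36: Constellation | None = None
    image_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def as_annotated(image) -> AnnotatedImage:
    if isinstance(image, AnnotatedImage):
        return image
    return AnnotatedImage(np.asarray(image, float))


@dataclass
class Detection:
    box: tuple[float, float, float, float]  # x0, y0, width, height
    c9: Constellation
    confidence: float


class BaseDetector(Protocol):
    """Face/landmark detector interface: image -> optional detection."""

    def detect(self, image: AnnotatedImage) -> Detection | None: ...


class SketchOracleDetector:
    """Oracle detector for synthetic sketches with injectable noise.

    Returns the embedded ground-truth C9 perturbed by isotropic
    Gaussian noise; its confidence is 1/(1 + RMS of the injected
    perturbation), so confidence genuinely tracks reliability.  A
    ``failure_rate`` fraction of calls returns no detection.
    """

    def __init__(self, noise_sd: float = 0.0, failure_rate: float = 0.0,
                 seed: int = 0) -> None:
        self.noise_sd = noise_sd
        self.failure_rate = failure_rate
        self._rng = np.random.default_rng(seed)

    def detect(self, image: AnnotatedImage) -> Detection | None:
        image = as_annotated(image)
        if image.truth_c9 is None:
            return None
        if self.failure_rate > 0 and self._rng.random() < self.failure_rate:
            return None
        pts = image.truth_c9.points.copy()
        if self.noise_sd > 0:
            noise = self._rng.normal(0.0, self.noise_sd, pts.shape)
            pts = pts + noise
            rms = float(np.sqrt(np.mean(np.sum(noise ** 2, axis=1))))
        else:
            rms = 0.0
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        box = (float(lo[0]), float(lo[1]),
               float(hi[0] - lo[0]), float(hi[1] - lo[1]))
        return Detection(box, Constellation(pts, "C9", image.image_id),
                         1.0 / (1.0 + rms))


# ---------------------------------------------------------------------------
# transformation-consensus C9 annotation
# ---------------------------------------------------------------------------

def variant_grid(
    shape: tuple[int, int],
    n_rotations: int = 10,
    paddings: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20),
    mirrors: tuple[bool, ...] = (False, True),
) -> list[tuple[PoseTransform, tuple[int, int], bool]]:
    """The (mirror x rotation x padding) grid of image transforms.

    Defaults produce 2 x 10 x 5 = 100 variants.  Each entry is the
    forward coordinate transform, the variant image shape, and whether
    the variant is mirrored.
    """
    h, w = shape
    out = []
    angles = np.linspace(-45.0, 45.0, n_rotations)
    for m in mirrors:
        for pad_frac in paddings:
            p = int(round(pad_frac * w))
            hw, ww = h + 2 * p, w + 2 * p
            pad_t = PoseTransform(translation=(p, p))
            centre = np.array([(ww - 1) / 2.0, (hw - 1) / 2.0])
            for ang in angles:
                theta = np.deg2rad(ang)
                rot = PoseTransform(rotation=theta)
                rot = PoseTransform(theta, 1.0,
                                    centre - rot.matrix @ centre)
                f = rot.compose(pad_t)
                if m:
                    mir = PoseTransform(reflection=True,
                                        translation=(ww - 1.0, 0.0))
                    f = mir.compose(f)
                out.append((f, (hw, ww), m))
    return out


def _warp_variant(image: AnnotatedImage, f: PoseTransform,
                  out_shape: tuple[int, int], mirrored: bool) -> AnnotatedImage:
    inv = f.inverse()
    m3 = np.eye(3)
    m3[:2, :2] = inv.matrix
    m3[:2, 2] = inv.translation
    pix = warp(image.pixels, AffineTransform(matrix=m3),
               output_shape=out_shape, mode="edge", preserve_range=True)
    truth = None
    if image.truth_c9 is not None:
        pts = f.apply(image.truth_c9.points)
        if mirrored:
            pts = pts[C9_MIRROR_MAP]
        truth = Constellation(pts, "C9", image.image_id)
    return AnnotatedImage(pix, truth_c9=truth, image_id=image.image_id)


def consensus_annotate9(
    image,
    detector: BaseDetector,
    n_transforms: int = 100,
    min_success: float = 0.10,
    confidence_quantile: float = 0.75,
) -> Constellation:
    """Transformation-consensus refinement of the base C9 detection.

    Runs the detector on the variant grid, maps every returned C9 back
    through the inverse transform (mirror variants also swap the
    left/right indices), keeps annotations with confidence at or above
    the run's ``confidence_quantile``, and returns their
    confidence-weighted mean.
    """
    image = as_annotated(image)
    n_rot = max(1, round(n_transforms / 10))
    grid = variant_grid(image.shape, n_rotations=n_rot)
    results: list[tuple[np.ndarray, float]] = []
    for f, out_shape, mirrored in grid:
        det = detector.detect(_warp_variant(image, f, out_shape, mirrored))
        if det is None:
            continue
        pts = det.c9.points
        if mirrored:
            pts = pts[C9_MIRROR_MAP]
        results.append((f.inverse().apply(pts), det.confidence))
    if len(results) < max(1, int(min_success * len(grid))):
        raise RuntimeError(
            f"detection failed: {len(results)}/{len(grid)} variants detected")
    confs = np.array([c for _, c in results])
    thresh = np.quantile(confs, confidence_quantile)
    keep = [(p, c) for p, c in results if c >= thresh]
    pts = np.stack([p for p, _ in keep])
    w = np.array([c for _, c in keep])
    mean = np.einsum("kij,k->ij", pts, w) / w.sum()
    return Constellation(mean, "C9", image.image_id)


# ---------------------------------------------------------------------------
# exemplar database and regions of interest
# ---------------------------------------------------------------------------

@dataclass
class ExemplarDB:
    """Annotated control faces supplying the CoE shape prior."""

    pairs: list[tuple[Constellation, Constellation]]  # (C9, C36)

    def __post_init__(self) -> None:
        for c9, c36 in self.pairs:
            if c9.scheme != "C9" or c36.scheme != "C36":
                raise ValueError("exemplar pairs must be (C9, C36)")
            if not np.allclose(c9.points, c36.c9().points, atol=1e-6):
                raise ValueError("exemplar C9 inconsistent with its C36")

    @classmethod
    def from_c36(cls, constellations: list[Constellation]) -> "ExemplarDB":
        return cls([(c.c9(), c.copy()) for c in constellations])

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RegionOfInterest:
    landmark_index: int      # 0-based index into the C36 ordering
    center: np.ndarray
    side: float              # = 2 x palpebral fissure length of the query

    def contains(self, p: np.ndarray, slack: float = 1e-9) -> bool:
        h = self.side / 2.0 + slack
        return bool(np.all(np.abs(np.asarray(p) - self.center) <= h))


def build_exemplar_rois(
    query_c9: Constellation,
    db: ExemplarDB,
    n_sample: int = 1000,
    n_top: int = 20,
    seed: int = 0,
) -> tuple[list[RegionOfInterest], Constellation]:
    """Shape-prior regions of interest for all 36 landmarks.

    Samples ``n_sample`` exemplars with replacement, registers each
    exemplar C9 to the query C9 by Procrustes, ranks by residual error,
    maps the best ``n_top`` exemplars' C36 through their fitted
    transforms and averages them into a consensus C36.  Each ROI is a
    square of side two palpebral-fissure lengths centred on the
    consensus point.  Returns (ROIs, consensus C36).
    """
    if len(db) == 0:
        raise ValueError("empty exemplar database")
    if n_top > n_sample:
        raise ValueError("n_top cannot exceed n_sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(db), size=n_sample)
    fits = []
    for i in idx:
        c9_i, c36_i = db.pairs[i]
        fit = procrustes_align(c9_i, query_c9)
        fits.append((fit.sse, i, fit.transform))
    fits.sort(key=lambda t: (t[0], t[1]))
    mapped = np.stack([
        t.apply(db.pairs[i][1].points) for _, i, t in fits[:n_top]
    ])
    consensus = Constellation(mapped.mean(axis=0), "C36", query_c9.image_id)
    side = 2.0 * pf_length(query_c9)
    rois = [RegionOfInterest(j, consensus.points[j].copy(), side)
            for j in range(36)]
    return rois, consensus


# ---------------------------------------------------------------------------
# part detectors
# ---------------------------------------------------------------------------

def _crop_patch(image: np.ndarray, center: np.ndarray, size: int) -> np.ndarray:
    """Bilinear subpixel crop of a size x size patch centred on a point."""
    from scipy.ndimage import map_coordinates
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    xs = center[0] + ax
    ys = center[1] + ax
    gx, gy = np.meshgrid(xs, ys)
    return map_coordinates(np.asarray(image, float), [gy, gx],
                           order=1, mode="nearest")


@dataclass
class PartDetectorBank:
    """36 Gaussian-kernel SVM part classifiers over PHOG patch features."""

    svms: list
    patch_size: int
    levels: int
    bins: int

    def scores(self, image: np.ndarray, landmark: int,
               points: np.ndarray) -> np.ndarray:
        """Continuous decision values at candidate points (higher=better)."""
        pts = np.atleast_2d(np.asarray(points, float))
        feats = np.stack([
            phog_descriptor(_crop_patch(image, p, self.patch_size),
                            self.levels, self.bins)
            for p in pts
        ])
        return self.svms[landmark].decision_function(feats)


def train_part_detectors(
    training: list[tuple[np.ndarray, Constellation]],
    patch_size: int = 21,
    levels: int = 2,
    bins: int = 8,
    n_negatives: int = 4,
    seed: int = 0,
) -> PartDetectorBank:
    """Train one Gaussian-kernel SVM per landmark.

    Positives are PHOG descriptors of patches centred on the true
    point; negatives are patches at random offsets of 0.5-1.5
    palpebral-fissure lengths within the same face.
    """
    from sklearn.svm import SVC

    if len(training) < 20:
        raise ValueError("need at least 20 training faces")
    rng = np.random.default_rng(seed)
    pf = [pf_length(c36.c9()) for _, c36 in training]
    svms = []
    for lm in range(36):
        feats, labels = [], []
        for (img, c36), pf_i in zip(training, pf):
            true_pt = c36.points[lm]
            feats.append(phog_descriptor(
                _crop_patch(img, true_pt, patch_size), levels, bins))
            labels.append(1)
            for _ in range(n_negatives):
                r = pf_i * rng.uniform(0.5, 1.5)
                ang = rng.uniform(0, 2 * np.pi)
                off = true_pt + r * np.array([np.cos(ang), np.sin(ang)])
                feats.append(phog_descriptor(
                    _crop_patch(img, off, patch_size), levels, bins))
                labels.append(0)
        svm = SVC(kernel="rbf", gamma="scale", C=10.0)
        svm.fit(np.stack(feats), np.array(labels))
        svms.append(svm)
    return PartDetectorBank(svms, patch_size, levels, bins)


# ---------------------------------------------------------------------------
# consensus-of-exemplars C36 annotation
# ---------------------------------------------------------------------------

def _roi_grid(roi: RegionOfInterest, shape: tuple[int, int],
              stride: float) -> np.ndarray:
    h, w = shape
    half = roi.side / 2.0
    # lattice anchored on the ROI centre so the centre itself is a node
    offs = np.arange(0.0, half + 1e-9, stride)
    offs = np.concatenate([-offs[:0:-1], offs])
    xs = np.unique(np.clip(roi.center[0] + offs, 0, w - 1))
    ys = np.unique(np.clip(roi.center[1] + offs, 0, h - 1))
    gx, gy = np.meshgrid(xs, ys)
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def _kde(eval_pts: np.ndarray, sources: np.ndarray,
         weights: np.ndarray, bandwidth: float) -> np.ndarray:
    d2 = cdist(eval_pts, sources, "sqeuclidean")
    return np.exp(-d2 / (2.0 * bandwidth ** 2)) @ weights


@dataclass
class CoEResult:
    c36: Constellation
    fallback_landmarks: list[int] = field(default_factory=list)


def coe_annotate36(
    image,
    query_c9: Constellation,
    db: ExemplarDB,
    detectors: PartDetectorBank,
    n_candidates: int = 20,
    n_registrations: int = 500,
    n_keep: int = 20,
    candidate_stride: float = 2.0,
    bandwidth_pf: float = 0.1,
    seed: int = 0,
    rois: list[RegionOfInterest] | None = None,
) -> CoEResult:
    """Consensus-of-exemplars expansion from C9 to the full C36.

    Per landmark the part detector is evaluated on a lattice inside the
    shape-prior ROI and the ``n_candidates`` best positions kept.
    ``n_registrations`` exemplar constellations are registered to the
    query through three randomly chosen landmark/candidate matches,
    scored by the summed detector decision values at their 36 points,
    and the best ``n_keep`` retained.  The final position of each
    landmark maximizes the product of a decision-weighted kernel
    density over the candidates and a kernel density over the retained
    exemplar points, evaluated on a 1-px ROI lattice.
    """
    image = as_annotated(image)
    pix = image.pixels
    rng = np.random.default_rng(seed)
    if rois is None:
        rois, _ = build_exemplar_rois(query_c9, db,
                                      seed=int(rng.integers(2 ** 31)))
    pf = pf_length(query_c9)
    bandwidth = max(bandwidth_pf * pf, 0.5)

    # stage 1: candidate positions + decision maps per landmark
    cand_pts: list[np.ndarray] = []
    cand_dec: list[np.ndarray] = []
    grids: list[np.ndarray] = []
    grid_dec: list[np.ndarray] = []
    fallback = []
    for lm, roi in enumerate(rois):
        grid = _roi_grid(roi, pix.shape, candidate_stride)
        dec = detectors.scores(pix, lm, grid)
        grids.append(grid)
        grid_dec.append(dec)
        if len(grid) == 0:
            fallback.append(lm)
            cand_pts.append(roi.center[None, :])
            cand_dec.append(np.zeros(1))
            continue
        top = np.argsort(-dec, kind="stable")[:n_candidates]
        cand_pts.append(grid[top])
        cand_dec.append(dec[top])

    # candidate sampling probabilities for registration anchors: softmax of
    # decision values, discouraging spurious outliers from driving the fit
    cand_prob = []
    for dec in cand_dec:
        t = max(float(dec.std()), 1e-9)
        w = np.exp((dec - dec.max()) / t)
        cand_prob.append(w / w.sum())

    # stage 2: shape prior via randomly registered exemplars
    scored: list[tuple[float, np.ndarray]] = []
    for _ in range(n_registrations):
        lms = rng.choice(36, size=3, replace=False)
        tgt = np.stack([
            cand_pts[l][rng.choice(len(cand_pts[l]), p=cand_prob[l])]
            for l in lms
        ])
        _, c36_i = db.pairs[rng.integers(len(db))]
        # 3-point similarity fit (raw point sets, no scheme semantics)
        a, t = _similarity_fit(c36_i.points[lms], tgt)
        mapped = c36_i.points @ a.T + t
        score = 0.0
        for lm in range(36):
            d = np.linalg.norm(grids[lm] - mapped[lm], axis=1)
            score += float(grid_dec[lm][np.argmin(d)])
        scored.append((score, mapped))
    scored.sort(key=lambda s: -s[0])
    kept = np.stack([m for _, m in scored[:n_keep]])  # (n_keep, 36, 2)

    # stage 3: per-landmark density consensus on a fine lattice
    final = np.empty((36, 2))
    for lm, roi in enumerate(rois):
        fine = _roi_grid(roi, pix.shape, 1.0)
        if len(fine) == 0 or lm in fallback:
            final[lm] = roi.center
            continue
        # scale-free softmax of decision values: sharp, detector-agnostic
        dec = cand_dec[lm]
        temp = max(float(dec.std()), 1e-9)
        w = np.exp((dec - dec.max()) / temp)
        dens_c = _kde(fine, cand_pts[lm], w, bandwidth)
        dens_e = _kde(fine, kept[:, lm, :], np.ones(len(kept)), bandwidth)
        final[lm] = fine[int(np.argmax(dens_c * dens_e))]
    return CoEResult(Constellation(final, "C36", image.image_id), fallback)


def _similarity_fit(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform (no reflection) fitting src -> dst points."""
    ms, md = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - ms, dst - md
    m = dc.T @ sc
    u, s, vt = np.linalg.svd(m)
    d = np.ones(2)
    if np.linalg.det(u @ vt) < 0:
        d[-1] = -1.0
    r = u @ np.diag(d) @ vt
    denom = float(np.sum(sc ** 2))
    scale = float((s @ d) / denom) if denom > 0 else 1.0
    a = max(scale, 1e-12) * r
    return a, md - a @ ms
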