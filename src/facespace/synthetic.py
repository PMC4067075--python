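"""Ground-truthed synthetic cohorts.

Real dysmorphology photo collections are access controlled, so every
stage of the pipeline is exercised against synthetic data with known
ground truth:

* labelled multi-class feature populations whose informative dimensions
  carry the class signal while additive low-rank "nuisance" factors
  (emulating lighting and head rotation) dominate the raw variance;
* parametric face sketches rendered from the canonical 36-point
  template, with exact ground-truth constellations, controllable
  deformation, landmark noise and pose.

Sketches are vector-primitive rasters, not photorealistic faces: the
pipeline only requires locatable intensity gradients at the landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import Constellation, PoseTransform
from .landmarks import C36_TEMPLATE, C36_GROUPS

__all__ = [
    "PopulationSpec", "Population", "sample_feature_population",
    "SketchSpec", "make_template_constellation", "sample_constellation",
    "render_face_sketch", "render_from_constellation", "mirror_sketch",
    "random_deformation_modes", "sketch_cohort", "syndrome_sketch_cohort",
]


# ---------------------------------------------------------------------------
# labelled feature populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Parameters of a labelled multi-class feature population.

    ``class_separation`` is the Euclidean distance between class means,
    realized only in the informative dimensions.  Each nuisance factor
    (one entry of ``nuisance_levels``, e.g. 5 head rotations and 4
    lighting conditions) contributes a fixed random direction in the
    nuisance subspace whose coefficient is set by the discrete level,
    scaled by ``nuisance_scale``; levels are assigned independently of
    the class label.
    """

    n_classes: int = 5
    n_per_class: int = 20
    dim_informative: int = 6
    dim_nuisance: int = 4
    class_separation: float = 6.0
    nuisance_scale: float = 1.0
    nuisance_levels: Sequence[int] = (5, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_classes, self.n_per_class, self.dim_informative,
                  self.dim_nuisance, *self.nuisance_levels]
        if any(int(c) < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.nuisance_scale < 0:
            raise ValueError("nuisance_scale must be >= 0")


@dataclass
class Population:
    features: np.ndarray          # (n, dim_informative + dim_nuisance)
    labels: np.ndarray            # (n,) int class labels
    nuisance: np.ndarray          # (n, n_factors) int level labels
    spec: PopulationSpec

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def to_frame(self) -> pd.DataFrame:
        d = self.features.shape[1]
        cols = {"id": [f"inst_{i:05d}" for i in range(self.n)],
                "label": self.labels}
        for f in range(self.nuisance.shape[1]):
            cols[f"nuisance_{f}"] = self.nuisance[:, f]
        frame = pd.DataFrame(cols)
        feat = pd.DataFrame(self.features,
                            columns=[f"f{j + 1}" for j in range(d)])
        return pd.concat([frame, feat], axis=1)


def _class_means(rng: np.random.Generator, n_classes: int, dim: int,
                 separation: float) -> np.ndarray:
    """Class means pairwise ``separation`` apart (orthogonal design)."""
    if n_classes <= dim:
        # random orthonormal frame -> exact pairwise distances
        a = rng.standard_normal((dim, n_classes))
        q, _ = np.linalg.qr(a)
        dirs = q[:, :n_classes].T
    else:
        dirs = rng.standard_normal((n_classes, dim))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs * (separation / np.sqrt(2.0))


def sample_feature_population(spec: PopulationSpec) -> Population:
    """Draw a labelled population with orthogonal signal and nuisance.

    Informative dimensions: class mean + unit Gaussian noise.  Nuisance
    dimensions: sum of per-factor fixed directions scaled by the
    (centred) discrete level times ``nuisance_scale``, plus unit noise.
    Level combinations are assigned cyclically within every class, so
    nuisance is balanced across classes (independent of the label).
    """
    rng = np.random.default_rng(spec.seed)
    di, dn = spec.dim_informative, spec.dim_nuisance
    n = spec.n_classes * spec.n_per_class

    means = _class_means(rng, spec.n_classes, di, spec.class_separation)
    factors = np.array(list(spec.nuisance_levels), dtype=int)
    # one fixed random unit direction per nuisance factor
    dirs = rng.standard_normal((len(factors), dn))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    # enumerate the level cross-product cyclically within each class
    combos = np.stack(np.meshgrid(*[np.arange(l) for l in factors],
                                  indexing="ij"), axis=-1)
    combos = combos.reshape(-1, len(factors))
    idx = np.concatenate([np.arange(spec.n_per_class) % len(combos)
                          for _ in range(spec.n_classes)])
    nuisance = combos[idx]

    x_inf = means[labels] + rng.standard_normal((n, di))
    centred = nuisance - (factors - 1) / 2.0
    x_nui = (centred * spec.nuisance_scale) @ dirs
    x_nui = x_nui + rng.standard_normal((n, dn))
    return Population(np.hstack([x_inf, x_nui]), labels, nuisance, spec)


# ---------------------------------------------------------------------------
# face sketches
# ---------------------------------------------------------------------------

def make_template_constellation() -> Constellation:
    """The canonical 36-point face layout (template units, y downward)."""
    return Constellation(C36_TEMPLATE.copy(), "C36", image_id="<template>")


def random_deformation_modes(
    n_modes: int, seed: int, smoothness: float = 40.0,
) -> list[np.ndarray]:
    """Smooth random per-point displacement fields with unit RMS.

    Each mode is a (36, 2) field built from a Gaussian process over the
    template layout (squared-exponential kernel, length scale
    ``smoothness`` template units), so nearby landmarks move coherently.
    """
    rng = np.random.default_rng(seed)
    pts = C36_TEMPLATE
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    cov = np.exp(-d2 / (2.0 * smoothness ** 2)) + 1e-8 * np.eye(len(pts))
    chol = np.linalg.cholesky(cov)
    modes = []
    for _ in range(n_modes):
        f = chol @ rng.standard_normal((len(pts), 2))
        f /= np.sqrt(np.mean(np.sum(f ** 2, axis=1)))
        modes.append(f)
    return modes


@dataclass
class SketchSpec:
    """Recipe for one synthetic face sketch."""

    template: Constellation = field(default_factory=make_template_constellation)
    deformation_modes: Sequence[tuple[np.ndarray, float]] = ()
    landmark_noise_sd: float = 0.0
    pose: PoseTransform | None = None
    image_size: int = 128
    seed: int = 0

    def resolved_pose(self) -> PoseTransform:
        """Default pose centres the template in the image."""
        if self.pose is not None:
            return self.pose
        centroid = self.template.points.mean(axis=0)
        centre = np.array([self.image_size / 2.0, self.image_size / 2.0])
        return PoseTransform(translation=centre - centroid)


def sample_constellation(spec: SketchSpec) -> tuple[Constellation, PoseTransform]:
    """Deform + jitter the template, then pose it into image coordinates.

    Returns the posed ground-truth constellation and the true pose
    transform (for oracle tests).
    """
    if spec.template.scheme != "C36":
        raise ValueError("template must be a C36 constellation")
    pose = spec.resolved_pose()
    rng = np.random.default_rng(spec.seed)
    pts = spec.template.points.copy()
    for mode, amplitude in spec.deformation_modes:
        pts = pts + float(amplitude) * np.asarray(mode, float)
    if spec.landmark_noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.landmark_noise_sd, pts.shape)
    posed = pose.apply(pts)
    return Constellation(posed, "C36", f"sketch_{spec.seed:05d}"), pose


def _segment_field(grid: np.ndarray, a: np.ndarray, b: np.ndarray,
                   sigma: float) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        d2 = np.sum((grid - a) ** 2, axis=-1)
    else:
        t = np.clip(((grid - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[..., None] * ab
        d2 = np.sum((grid - proj) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _spot_field(grid: np.ndarray, p: np.ndarray, sigma: float) -> np.ndarray:
    d2 = np.sum((grid - p) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


# (index polyline, amplitude, sigma) drawing recipe; indices into C36
_POLYLINES = [
    ((0, 1, 2, 3), 0.35, 1.5),        # left brow
    ((4, 5, 6, 7), 0.35, 1.5),        # right brow
    ((8, 9, 10, 11, 8), 0.30, 1.0),   # left eye outline
    ((12, 13, 14, 15, 12), 0.30, 1.0),  # right eye outline
    ((16, 17), 0.15, 1.5),            # nasal dorsum
    ((18, 17, 19), 0.20, 1.2),        # alae
    ((23, 27, 24, 28, 25), 0.40, 1.5),  # upper lip
    ((23, 26, 25), 0.40, 1.5),        # lower lip
    ((29, 30, 31, 32, 33, 34, 35), 0.28, 2.0),  # jaw line
]

_SPOTS = [
    (20, 0.30, 1.5), (21, 0.30, 1.5), (22, 0.30, 1.5),  # subnasale/columella
    (17, 0.20, 1.8),                                     # nose tip
]

_BACKGROUND = 0.15


def render_from_constellation(c36: Constellation, image_size: int) -> np.ndarray:
    """Deterministic raster of face-like primitives anchored at landmarks.

    The head is a smoothly shaded ellipse fitted to the jaw/brow extent;
    brows, eye outlines, pupils, nose and mouth are drawn as Gaussian
    line/spot fields so that every landmark sits on an intensity
    gradient.  Background far from the face is the uniform constant
    ``0.15``.  Intensities lie in [0, 1].
    """
    pts = c36.points
    s = int(image_size)
    if (pts < -0.5).any() or (pts > s - 0.5).any():
        raise ValueError("constellation out of image bounds")
    yy, xx = np.mgrid[0:s, 0:s]
    grid = np.stack([xx, yy], axis=-1).astype(float)

    # head ellipse from landmark extent
    cx = 0.5 * (pts[29, 0] + pts[35, 0])
    top = pts[C36_GROUPS["supraorbital"]][:, 1].min() - 10.0
    bottom = pts[32, 1] + 4.0
    cy = 0.5 * (top + bottom)
    ax = 0.5 * abs(pts[35, 0] - pts[29, 0]) + 5.0
    ay = 0.5 * (bottom - top)
    q = ((grid[..., 0] - cx) / ax) ** 2 + ((grid[..., 1] - cy) / ay) ** 2
    w = np.clip((1.0 - q) / 0.08, 0.0, 1.0)
    img = _BACKGROUND + w * (0.62 - 0.18 * np.clip(q, 0.0, 1.0))

    dark = np.zeros_like(img)
    for chain, amp, sigma in _POLYLINES:
        for a, b in zip(chain[:-1], chain[1:]):
            dark += amp * _segment_field(grid, pts[a], pts[b], sigma)
    for idx, amp, sigma in _SPOTS:
        dark += amp * _spot_field(grid, pts[idx], sigma)
    # pupils at the eye centres
    for m1, m2 in ((8, 10), (12, 14)):
        centre = 0.5 * (pts[m1] + pts[m2])
        dark += 0.45 * _spot_field(grid, centre, 2.0)
    return np.clip(img - dark, 0.0, 1.0)


def render_face_sketch(spec: SketchSpec) -> tuple[np.ndarray, Constellation]:
    """Render a sketch and return (grayscale image, ground-truth C36)."""
    c36, _ = sample_constellation(spec)
    return render_from_constellation(c36, spec.image_size), c36


def mirror_sketch(image: np.ndarray,
                  c36: Constellation) -> tuple[np.ndarray, Constellation]:
    """Horizontally mirror a sketch and swap left/right landmark indices."""
    return np.fliplr(image).copy(), c36.mirrored(image.shape[1])


def sketch_cohort(
    n: int,
    seed: int,
    n_modes: int = 4,
    amplitude: float = 2.0,
    landmark_noise_sd: float = 0.5,
    image_size: int = 128,
) -> list[tuple[np.ndarray, Constellation]]:
    """A cohort of rendered sketches with individual shape variation."""
    modes = random_deformation_modes(n_modes, seed)
    rng = np.random.default_rng(seed + 1)
    out = []
    for i in range(n):
        amps = rng.normal(0.0, amplitude, n_modes)
        spec = SketchSpec(
            deformation_modes=[(m, a) for m, a in zip(modes, amps)],
            landmark_noise_sd=landmark_noise_sd,
            image_size=image_size,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        out.append(render_face_sketch(spec))
    return out


def syndrome_sketch_cohort(
    n_classes: int,
    n_per_class: int,
    seed: int,
    n_modes: int = 6,
    class_amplitude: float = 4.0,
    individual_amplitude: float = 1.0,
    landmark_noise_sd: float = 0.5,
    image_size: int = 128,
) -> tuple[list[tuple[np.ndarray, Constellation]], np.ndarray]:
    """Sketch cohort with class-specific facial gestalts.

    Every class ("syndrome") has a characteristic mean deformation of
    amplitude ``class_amplitude`` along shared smooth modes; individuals
    vary around it with ``individual_amplitude``.  Returns the rendered
    (image, constellation) records and the integer class labels.
    """
    template = make_template_constellation()
    modes = random_deformation_modes(n_modes, seed)
    rng = np.random.default_rng(seed + 1)
    class_amps = rng.normal(0.0, class_amplitude, (n_classes, n_modes))
    records, labels = [], []
    for c in range(n_classes):
        for i in range(n_per_class):
            # rejection-sample deformations that would leave the canvas
            for _ in range(50):
                amps = class_amps[c] + rng.normal(
                    0.0, individual_amplitude, n_modes)
                deformed = template.points + sum(
                    a * m for m, a in zip(modes, amps))
                centre = (deformed.max(0) + deformed.min(0)) / 2.0
                pose = PoseTransform(
                    translation=np.full(2, image_size / 2.0) - centre)
                spec = SketchSpec(
                    deformation_modes=[(m, a) for m, a in zip(modes, amps)],
                    landmark_noise_sd=landmark_noise_sd,
                    pose=pose,
                    image_size=image_size,
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                )
                try:
                    img, c36 = render_face_sketch(spec)
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError("could not fit deformed face on canvas; "
                                   "reduce the deformation amplitudes")
            c36.image_id = f"class{c}_{i:03d}"
            records.append((img, c36))
            labels.append(c)
    return records, np.array(labels)
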