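# Methods

This note documents the models, conventions and numerical choices
behind `facespace`, in the order of the pipeline.

## Landmark schemes and geometry

Two ordered point sets are used throughout: the 9 salient inner points
(`C9`: four eye canthi, two subnasales, columella, two mouth corners)
and the full 36-point mesh (`C36`: supra-orbital ridge 8, eyes 8, nose
7, mouth 6, jaw 7). Coordinates are 0-based pixels, origin top-left,
y downward; "left/right" refer to the image side. The C9 points are a
strict subset of C36, and the nose group is defined as {nasion, tip,
ala ×2, subnasale ×2, columella} so that this inclusion holds. A
single left/right index swap map per scheme defines mirroring; it is
an involution whose fixed points lie on the template midline.

Registration is similarity Procrustes (rotation + isotropic scale +
translation, solved by SVD of the cross-covariance); reflection is
excluded by default because mirror handling is explicit through the
swap map. The generalized (iterative) mean alternates align-to-mean
and re-averaging until the mean moves less than `tol = 1e-6`
(normalized units) or 100 iterations. The mean is normalized to
centroid 0 / centroid size 1 and then rotated so the inter-ocular axis
is horizontal; without this canonical orientation the mean would be
defined only up to rotation and would depend on input order. Whether
the original procedure used full similarity or rigid alignment is not
derivable from its description; similarity is assumed.

The palpebral fissure length (PF; mean canthus-to-canthus span of the
two eyes) is the face-local scale unit for patch sizes and regions of
interest.

## Synthetic data

Real patient photographs are access-controlled, so the generators are
first-class, tested code and define the conditions every downstream
claim is tested under.

**Feature populations.** Class means are placed pairwise
`class_separation` apart in the informative dimensions (orthogonal
design when dimensionality allows), with unit Gaussian noise. Each
nuisance factor (defaults: 5 "rotation" and 4 "lighting" levels,
mirroring a 5×4 design over 5 phenotype classes with 20 instances
each) contributes a fixed random direction in the nuisance subspace,
scaled by the centred level index times `nuisance_scale`, plus unit
noise; level combinations are assigned cyclically within each class,
so nuisance is balanced across classes by construction (measured
|correlation| < 0.1 at n = 1000). Additive low-rank nuisance is the
simplest structure that reproduces the qualitative phenomenon of
interest: with `nuisance_scale` ≳ 10 the leading principal component
of the raw features is a nuisance factor, not the class.

**Face sketches.** A fixed canonical 36-point template (face ~100
units tall) is deformed along smooth random modes (Gaussian-process
displacement fields, squared-exponential kernel, length scale 40
template units, unit RMS), jittered per landmark, and posed by a
similarity transform into a 128-px image by default. The renderer is
deterministic and purely distance-field based (Gaussian line/spot
fields for brows, eye outlines, pupils, nose, mouth, jaw; a smoothly
shaded head ellipse), so every landmark sits on an intensity gradient,
the background far from the face is exactly constant, and mirroring
the constellation mirrors the rendered image to float precision.
Sketches are deliberately not photorealistic: the pipeline needs
locatable gradients, not faces. Passing tests on sketches demonstrate
the machinery (consensus, shape prior, detectors, descriptors, metric)
under controlled truth; they do not certify accuracy on photographs,
where detector quality, occlusion and texture variation dominate.
The class-structured cohort (`syndrome_sketch_cohort`) gives each
class a characteristic mean deformation (amplitude 4 by default) with
individual variation (amplitude 1); draws that would push landmarks
off the canvas are rejection-sampled.

## Annotation

**Transformation consensus.** The variant grid is {original, mirror} ×
10 rotations evenly spaced in ±45° × 5 frame paddings (0–20% of image
width) = 100 variants; the total and the ingredient transforms are
fixed, the exact grid is this package's choice. Detections are mapped
back through each variant's inverse affine (mirror variants also swap
indices), detections below the run's 75th confidence percentile are
discarded (a quantile is scale-free across detectors), and the rest
are confidence-weighted averaged. At least 10% of variants must
detect, otherwise annotation fails loudly.

**Consensus of exemplars.** 1000 exemplars are sampled with
replacement, registered to the query C9, ranked by residual; the top
20 exemplars' C36 are mapped through their fitted transforms and
averaged into a consensus; each landmark gets a square ROI of side
2 PF centred on the consensus point. Part detectors are RBF-kernel
SVMs (C = 10) on PHOG features of 21-px patches; positives at the true
point, 4 negatives per face at random offsets of 0.5–1.5 PF. Within
each ROI the detector is evaluated on a stride-2 lattice anchored on
the ROI centre; the 20 best nodes are the candidates. 500 random
exemplars are registered via three random landmarks matched to
candidates sampled with softmax(decision) probabilities — weighting
anchors by decision value keeps spurious outliers from driving the
fit. Each registered constellation is scored by the *sum* of detector
decision values at its 36 points (nearest lattice lookup); sum was
chosen over mean/min as the aggregation because all 36 terms are
always present. The 20 best registrations are kept. The final
position of a landmark maximizes the product of two Gaussian kernel
densities (bandwidth 0.1 PF, floor 0.5 px) on a 1-px lattice: one over
candidates weighted by softmax of decision values (temperature = their
standard deviation, so the weighting is detector-scale-free), one over
the kept registrations' points. Product combination was chosen so a
location must be supported by both appearance and shape prior. An
empty candidate set falls back to the ROI centre and is flagged.

On held-out sketches the full chain annotates at ~0.05 eye-widths mean
error, against ~0.07 for the shape prior alone.

## Descriptors

**Shape (630).** Pairwise distances of the 36 registered landmarks in
lexicographic (i < j) order, divided elementwise by the same distances
on the average control face, so 1.0 means "as controls". Similarity
registration makes the vector pose- and scale-invariant to 1e-6.

**Appearance (1937 = 13 × 149).** The 9 inner points plus 4 derived
auxiliary points (eye centres, nasion, mouth centre) are mapped by a
least-squares affine T to a canonical 13-point template; each
template point carries a circular patch of radius 0.35 PF sampled on a
fixed lattice of 149 positions (centre + 7 concentric rings of
8/12/16/20/24/28/40 points). The lattice is mapped through T⁻¹
(ellipses in the image) and sampled bilinearly from the min–max
normalized image. Only the total length is externally fixed; the
per-patch count 149 = 1937/13 is forced, the ring geometry and patch
radius are this package's choice (patches cover local anatomy without
eye/nose overlap on the template). Min–max normalization makes
synthetic tests scale-free; a constant image is sampled as-is.
Samples outside the image take the border value and set a flag.

**PHOG.** Unsigned gradient orientations ([0, π), 8 bins), hard
binning, magnitude weighting, spatial pyramid of levels 0–2 (4^ℓ cells
per level), each level L1-normalized independently; length
bins·Σ4^ℓ = 168 at the defaults. A constant patch maps to the zero
vector rather than an arbitrary uniform histogram.

## Averaging and morphs

Group averages warp each face's pixels triangle-by-triangle (piecewise
affine, bilinear) onto the Delaunay mesh of the group's Procrustes
mean, rastered on a 256×256 canvas with an 8% margin, and average
pixelwise; pixels outside the mesh hull are ignored (the mesh does not
cover hair/background). Morphs interpolate mesh and appearance
linearly between two group averages built on a shared canvas,
`A_k = A_s + k/K (A_c − A_s)`, with the k = K endpoint returned
exactly (no floating-point residue); frame k is rendered by warping
A_k onto M_k. Distortion graphs report, per landmark pair, the
relative change of registered pairwise distance versus the control
mean (negative = shorter). Plain pixel averaging is used, without an
appearance-PCA truncation step, which is sufficient for average-face
visualization.

## Phenotype space

Per-block PCA (defaults 100 shape + 240 appearance = 340, split
roughly proportional to block dimensionality; only the total is
externally fixed) followed by LMNN. The transform L is rectangular
(270 × 340 by default), initialized from the leading principal
directions of the training scores; learning L directly at the output
dimensionality reconciles a 340-d input with a 270-d space without a
separate truncation step. The objective is the standard pull/push
trade-off (μ = 0.5, unit margin, k = 3 target neighbours fixed from
the input space); minimization is gradient descent with an adaptive
step in which increasing steps are rejected and halved, so the
accepted objective sequence is non-increasing by construction.
Impostor sets are recomputed every accepted step. Distances are
reported as the square root (a true metric), ranking-equivalent to the
squared form.

## CIF

`E(r) = 1 + Σ_{j=1..Nn} (1 − j/(Nn+1))^(Np−1)`, evaluated in
exp/log form for numerical stability at large Np. The formula is the
*independent placement* model — each of the other Np−1 class members
falls independently and uniformly among the Nn negatives — and the
Monte-Carlo oracle in the tests simulates exactly that model.
`O(r)` counts, per query, the negatives strictly closer than the
nearest same-class instance; negatives at exactly that distance count
one half (the average over tie-break orders), removing any dependence
on point order. A bootstrap (resampling queries) provides an optional
95% interval on CIF. Under the null (labels unrelated to position)
the median CIF measures ≈ 0.92–0.94 rather than exactly 1: O(r) under
a true random configuration follows the permutation model, whose mean
rank is slightly above the independent-placement E(r), and the
median-of-means adds a small downward bias. This is the behaviour of
the statistic itself, reproduced by the acceptance script.

## Querying

Neighbour lists are exact (brute force), ascending by distance, ties
broken by id. Syndrome hypotheses are ranked by the hypergeometric
tail Pr(X ≥ N) of seeing N class members among k = 20 draws from the
database composition — the smaller, the more surprising; class
dispersion (mean intra-class distance) and prevalence are reported as
context, not folded into the rank, since no combination rule is
specified. p0p1 uses geometric-mean neighbourhood scales
`√(g0·g1)/d01`: this form is symmetric in the pair, dimensionless, and
reads directly as "x% closer than the local density predicts" (1.05 =
5% closer); each point's k-neighbourhood excludes its partner so a
genuinely isolated pair is not masked by itself. The raw ratio
`d01/(d0·d1)` (arithmetic scales) is available behind a flag but has
units of 1/distance and is not used. For structureless data, p0p1 of
pairs drawn among a query's 20 neighbours has median ≈ 1.

## Classification protocols

Binary: linear SVMs per descriptor block on 4:1 train/test splits,
training on each instance and its mirror, threshold tuned on training
summed (original + mirror) decision values for equal false-positive /
false-negative counts (sweep of interval midpoints, ties resolved to
the midpoint of the optimal interval). Test instances are scored on
both versions, block scores are summed, fusion adds the
threshold-centred block scores. Forced choice: all pairwise linear
classifiers, decision values calibrated to probabilities by a logistic
(Platt) fit on the training decisions (a raw clipped decision value
would be scale-dependent); instance votes P for the positive and 1−P
for the negative class, argmax of the vote totals, confusion averaged
over 10 repeats. Gaussian kernels are reserved for the part
detectors; classification experiments are linear.

## Problem sizes

The test suite and acceptance script run on deliberately modest
problem sizes chosen as the smallest that exercise each claim: 24
sketches (20 training / 4 held out) for annotation, 350 sketches
(5 classes × 70) for the full-dimensionality check, 200-instance
populations for metric recovery, 500 replicates for the null CIF,
10⁵ replicates for Monte-Carlo oracles.

## Known limitations

* No trained photographic face detector ships with the package; real
  photos require plugging an external detector into `BaseDetector`.
  The oracle detector validates the consensus machinery only.
* LMNN's target neighbours are fixed from the input space; the
  adaptive-step descent guarantees monotone objective decrease but not
  a global optimum.
* The appearance descriptor samples raw grayscale; illumination
  robustness comes entirely from the metric, not the descriptor.
* Morph appearance interpolation is linear in pixel space; crossfade
  artefacts can appear where groups differ strongly in texture.
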