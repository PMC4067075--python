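# facespace

Clinical face phenotype analysis from ordinary 2-D photographs.

About a third of genetic disorders show craniofacial dysmorphism, and
clinicians routinely use the facial *gestalt* to narrow a diagnosis.
`facespace` implements a fully automatic pipeline that turns a plain
photo into a point in a learned **clinical face phenotype space** in
which distances reflect dysmorphic similarity, so that patients with
the same (possibly undocumented) syndrome cluster together:

1. **Landmark annotation** — a pluggable base detector proposes the 9
   inner facial points; a transformation consensus (mirror × partial
   rotations × frame paddings, ~100 variants) makes the detection
   robust; a *consensus of exemplars* expands it to the full 36-point
   constellation using Gaussian-kernel SVM part detectors on PHOG
   patches plus a shape prior from annotated reference faces.
2. **Descriptors** — a 630-d shape vector (all pairwise landmark
   distances, registered to and normalized by the average control
   face) and a 1937-d appearance vector (13 elliptical patches × 149
   grayscale samples), 2567 dimensions in total.
3. **Metric learning** — per-block PCA to 340 components, then a
   large-margin nearest-neighbour (LMNN) transform `L` (270 × 340).
   Distances are `d(x, y)² = (x−y)ᵀ Lᵀ L (x−y)`: dimensions that carry
   phenotype are expanded, nuisance dimensions (lighting, pose) are
   compressed.
4. **Query statistics** —
   * the **clustering improvement factor** (CIF): for a syndrome with
     `Np` members among `Nn` other faces, the expected rank of the
     nearest same-syndrome match under random ranking is

     `E(r) = 1 + Σ_{j=1..Nn} (1 − j/(Nn+1))^(Np−1)`

     and `CIF = E(r) / O(r)`, the fold reduction of the diagnostic
     search space relative to chance (`O(r)` is the observed average
     rank; a random class has CIF ≈ 1, a fully separated one attains
     the maximum CIF = E(r));
   * hypergeometric prioritization of syndrome hypotheses among the
     k = 20 nearest neighbours;
   * the **p0p1** local-density similarity
     `p0p1 = √(g0·g1) / d01` (geometric-mean neighbourhood scales over
     the pair's mutual distance) — values above 1 flag pairs closer
     than their neighbourhood predicts, i.e. candidate novel clusters.

Patient photo collections are access-controlled, so the package ships
a first-class synthetic module: labelled feature populations with
controlled class signal and structured lighting/rotation nuisance, and
rendered face sketches with exact ground-truth constellations, against
which every stage is validated.

## Worked example

```python
import numpy as np
from facespace import expected_rank, clustering_improvement_factor
from facespace.synthetic import PopulationSpec, sample_feature_population
from facespace.lmnn import lmnn_fit

print(f"E(r) = {expected_rank(20, 100):.3f}")

pop = sample_feature_population(PopulationSpec(
    n_classes=5, n_per_class=40, class_separation=6.0,
    nuisance_scale=12.0, seed=0))
res = lmnn_fit(pop.features, pop.labels, out_dim=6, k=3, max_iter=120)
z = pop.features @ res.L.T
for cls in range(3):
    raw = clustering_improvement_factor(pop.features, pop.labels, cls)
    lrn = clustering_improvement_factor(z, pop.labels, cls)
    print(f"class {cls}: CIF {raw.cif:.2f} -> {lrn.cif:.2f} "
          f"(max {lrn.max_cif:.2f})")
```

prints

```
E(r) = 5.566
class 0: CIF 3.56 -> 4.55 (max 4.55)
class 1: CIF 4.23 -> 4.55 (max 4.55)
class 2: CIF 4.13 -> 4.55 (max 4.55)
```

A 20-member class among 100 background faces is expected at rank 5.6
by chance. In the raw feature space — where lighting/rotation nuisance
dominates the variance — each synthetic syndrome clusters ~3.5–4.2
fold better than chance; after metric learning every class reaches the
maximum attainable CIF of 4.55 (every query's nearest same-class match
is rank 1).

## Command line

`facespace simulate | annotate | extract | build-space | cif | query |
average-face | morph | eval-svm | export-graph` — every subcommand
takes `--seed` and reads/writes TSV/CSV/PNG artifacts; see
`facespace --help`.

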