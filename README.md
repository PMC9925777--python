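# microholes

Topological quantification of "micro-hole" microstructure in 2-D greyscale
microscopy images — for example second harmonic generation (SHG) or
two-photon autofluorescence (TPaF) images of cortical bone, where the
low-signal regions correspond to structures such as osteocyte lacunae and
vascular canals.  The package measures the number, size, crowding and
arrangement of holes per image patch, tests group differences, and
classifies patches by condition.

## Method

1. **Binarize and patch.** Each whole image is thresholded with Otsu's
   method (maximising between-class variance), trimmed of empty borders,
   padded, and tiled into non-overlapping 300×300 binary patches; patches
   with no signal phase are discarded.
2. **Signed Euclidean distance transform (SEDT).** Every pixel gets the
   Euclidean distance to the nearest pixel of the opposite phase: positive
   in the signal ("bone") phase, negative inside holes.
3. **Cubical persistent homology.** The SEDT is filtered by sublevel sets
   (V-construction: pixels are vertices, orthogonal neighbours are joined,
   2×2 blocks filled).  H₀ tracks connected components, H₁ tracks loops;
   each feature is a point (b, d) with birth b < death d.  Exactly one H₀
   class never dies (the *essential* class); it is excluded from all
   statistics because it usually captures the exterior background.
4. **Quadrant interpretation.**  In the (birth, death) plane, quadrant 2 of
   H₀ (b < 0 < d) holds one point per disconnected micro-hole: |b| is the
   radius of the largest inscribed circle, d is half the distance to the
   nearest other hole.  Quadrant 1 of H₁ (0 ≤ b < d) holds loops of signal
   surrounding rings of holes.  H₀ cannot appear in quadrant 1, H₁ cannot
   appear in quadrant 3, quadrant 4 is empty — laws the code asserts.
5. **Persistence statistics.** Per patch, a panel of 28 named statistics
   over H₀-Q2 and H₁-Q1: point counts, persistent entropy
   ∑ −(pᵢ/P)·ln(pᵢ/P) with lifetimes pᵢ = dᵢ − bᵢ and P = ∑pᵢ, birth/death
   means, medians, quartiles, IQRs and standard deviations, and hole counts
   split at radius 2 px.
6. **Inference.** Unpaired permutation tests (10 000 shuffles, absolute
   difference of group means, pseudo p = proportion of shuffles at least as
   extreme) compare groups per statistic; paired sign-flip tests compare
   modalities; Benjamini–Hochberg step-up controls the FDR per family.
7. **Classification.** An RBF-kernel SVC (C = 3) on 10 (or 20) of the
   statistics, standardised inside each training fold, evaluated by
   stratified 10-fold cross-validation repeated with re-randomised folds.

A synthetic generator plants black disks with known radii, counts and
spacings on white canvases, so every stage can be validated against exact
ground truth without any imaging data.

## Worked example

```python
import numpy as np
from microholes import (HoleSpec, make_disk_field, signed_edt,
                        compute_persistence, split_quadrants, compute_panel)

spec = HoleSpec(
    centers=np.array([[60.0, 60.0], [60.0, 200.0], [200.0, 130.0]]),
    radii=np.array([4.0, 8.0, 15.0]),
    canvas=300,
)
patch, truth = make_disk_field(spec)
diagram = compute_persistence(signed_edt(patch))
quadrants = split_quadrants(diagram)

print("essential birth (largest hole):", round(diagram.essential_birth, 2))
print("H0 quadrant 2 points (birth, death):")
for b, d in quadrants[("h0", "q2")]:
    print(f"  ({b:7.2f}, {d:7.2f})")

panel = compute_panel(diagram)
for key in ("h0q2_n_points", "h0q2_mean_birth", "h0q2_mean_death",
            "h0q2_n_radius_ge_2", "h1q1_n_points"):
    print(f"{key}: {panel[key]:.3f}")
```

prints

```
essential birth (largest hole): -15.03
H0 quadrant 2 points (birth, death):
  (  -4.12,   64.00)
  (  -8.06,   66.64)
h0q2_n_points: 2.000
h0q2_mean_birth: -6.093
h0q2_mean_death: 65.320
h0q2_n_radius_ge_2: 2.000
h1q1_n_points: 26.000
```

The three planted holes of radii 4, 8 and 15 px appear as H₀ births near
−4.12, −8.06 and −15.03: |birth| recovers each hole's inscribed radius to
within a pixel (the overshoot is the lattice offset to the nearest white
pixel centre).  The largest hole is the essential class, so the finite
quadrant-2 count is 2; deaths near 65 reflect the holes' mutual distances
(half the nearest-hole gap).  The 26 H₁-quadrant-1 points are loops in the
signal phase; with isolated round holes most are lattice-scale ridge
features of the distance transform with near-zero persistence.

## Command line

```sh
microholes synth --preset ko-like --n-patches 10 --seed 0 --out patches/
microholes ph --patches patches/ --out diagrams.csv
microholes stats --diagrams diagrams.csv --out panel.csv
microholes test --panel panel.csv --seed 0 --out tests.csv
microholes classify --panel panel.csv --repeats 100 --seed 0
microholes run --synthetic contrast --out results/   # full pipeline
```

`microholes preprocess` handles real greyscale PNG/TIFF images, with labels
supplied via a manifest CSV (`path,sample,sex,genotype,modality`).

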