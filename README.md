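# nucarch

Quantitative analysis of 3D nuclear architecture for cohesin-depletion-style
experiments: chromatin-compaction classification of DAPI-stained nuclear
voxels, marker enrichment over compaction classes, replication-domain
segmentation and statistics, DNA-halo loop-size measurement,
degradation-kinetics trace filtering, and matrix-level Hi-C / Repli-Seq
compartment analysis. Every pipeline input can be generated synthetically
with exported ground truth, so each measurement is testable without any
microscope or sequencing data.

The intended users are imaging and genomics groups who quantify nuclear
organisation: the package turns raw multi-channel stacks (or synthetic
stand-ins) into per-nucleus compaction profiles, enrichment statistics,
object tables, and compartment tracks.

## The core model

Voxels inside a nuclear mask are classified into K = 7 intensity classes —
a proxy for local chromatin compaction, from the DNA-sparse interchromatin
compartment (class 1) to densely compacted heterochromatin (class 7) — by a
hidden Markov random field combining a finite Gaussian mixture with a Potts
spatial prior. The emission model has class means μ₁ < … < μ₇ and a single
shared standard deviation σ (equal intensity variance); labels x minimise

    U(x) = Σ_v [ (I_v − μ_{x_v})² / (2σ²) + log σ − log π_{x_v} ]
         + β Σ_{v∼w} 1[x_v ≠ x_w]

over the 6-connected voxel lattice. Inference is ICM with closed-form
M-steps; β = 0 reduces exactly to per-voxel mixture-MAP classification, so
the classification is threshold-independent. The classifier is exposed as a
scikit-learn-style estimator (`HMRFClassifier().fit(grid, mask)`).

Downstream statistics follow the field's standard definitions: marker
enrichment is the percentage-point difference Δ_k = 100·(m_k − f_k) between
the intensity-weighted marker share and the voxel share of each class
(ΣΔ_k = 0); replication domains are thresholded, watershed-separated and
size-filtered; DNA-halo radii follow R = √(Ah/π); Hi-C matrices are
Knight–Ruiz balanced, O/E-transformed, correlated, and decomposed into the
A/B compartment eigenvector; conditions are compared with two-sided
Mann–Whitney tests under Bonferroni–Holm correction.

## Worked example

Generate a synthetic nucleus with a speckle-like marker confined to the
interchromatin compartment, classify its voxels, and measure the marker's
enrichment:

```python
import numpy as np
from nucarch import (NucleusSceneSpec, MarkerSpec, generate_nucleus_scene,
                     HMRFClassifier, NucleusMask, segment_marker,
                     enrichment_profile)

spec = NucleusSceneSpec(
    grid_shape=(32, 128, 128),
    marker_specs=(MarkerSpec("SC35", class_weights=(6, 2, 1, 0.3, 0.1, 0, 0),
                             density=0.06),),
    seed=1,
)
channels, truth = generate_nucleus_scene(spec)

clf = HMRFClassifier(n_classes=7, beta=spec.potts_beta)
clf.fit(channels["DAPI"], truth.mask)
acc = (clf.labels_[truth.mask] == truth.label_field[truth.mask]).mean()
print(f"voxelwise accuracy vs truth: {acc:.3f}")
print("fitted class means:", np.round(clf.means_, 0))
print(f"fitted shared sigma: {clf.sigma_:.0f}  (generator: {spec.class_sigma:.0f})")

mask = NucleusMask(truth.mask, spec.voxel_size)
seg = segment_marker(channels["SC35"], mask)
prof = enrichment_profile(seg, clf.to_class_field())
for k, d in enumerate(prof.delta, start=1):
    print(f"class {k}: delta = {d:+6.2f} points")
```

Output:

```
voxelwise accuracy vs truth: 0.951
fitted class means: [ 7939. 15984. 24045. 32073. 40169. 48304. 56236.]
fitted shared sigma: 3941  (generator: 4000)
class 1: delta = +51.92 points
class 2: delta =  +7.80 points
class 3: delta =  -2.36 points
class 4: delta = -10.34 points
class 5: delta = -10.59 points
class 6: delta = -18.25 points
class 7: delta = -18.17 points
```

The classifier recovers 95% of the planted voxel labels at an emission noise
of half the inter-class mean gap, and the fitted means land within ~1% of
the generator's 8000…56000 ladder. The marker, planted preferentially in
class 1, shows the expected strong positive Δ in class 1 with spillover into
class 2 and depletion across the compacted classes — the signature of an
interchromatin-compartment marker such as a splicing-speckle protein.

A thin CLI mirrors the library (`nucarch classify`, `enrich`, `rds`,
`halo`, `traces`, `compartments`); run `nucarch --help`.

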