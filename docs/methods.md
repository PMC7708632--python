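# Methods

This note documents the models implemented in `nucarch`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know.

## Compaction classification (Gaussian mixture + Potts HMRF)

**Model.** In-mask DAPI intensities are modelled as a K-component Gaussian
mixture with strictly ascending means and one shared standard deviation σ
("equal intensity variance"), coupled by a K-state Potts prior on the
6-connected voxel lattice with coupling β ≥ 0. The posterior energy is

    U(x) = Σ_v [ (I_v − μ_{x_v})²/(2σ²) + log σ − log π_{x_v} ]
         + β Σ_{v∼w} 1[x_v ≠ x_w].

Out-of-mask voxels take label 0 and are excluded from both the emission fit
and the neighbour terms; mask-boundary voxels simply have fewer neighbours
(no padding). After fitting, classes are relabelled ascending in μ so that
class 1 is always the dimmest (interchromatin compartment) and class K the
brightest (most compacted chromatin), regardless of initialisation.

**Inference.** The emission model is initialised by 1D k-means on the
in-mask intensities (10 restarts on a deterministic ≤200k subsample)
followed by a short tied-variance soft-EM refinement; quantile-based label
initialisation was rejected because it merges overlapping components when
class fractions are unequal. Labels then start at the mixture-MAP argmax and
the fit alternates (i) ICM label updates and (ii) closed-form M-steps for
μ, π and the shared σ. ICM uses a fixed checkerboard (red/black) schedule:
for the 6-connected neighbourhood the two parities are mutually
non-adjacent, so each half-sweep is exact, vectorised coordinate descent
and the energy is non-increasing at every half-sweep (recorded in
`energy_trace_` and asserted in tests). The loop ends on an ICM pass, so
the reported labels are the MAP labelling under the reported parameters;
with β = 0 this makes the fit bit-identical to per-voxel mixture-MAP
classification, which the tests verify against an independent argmax
oracle.

**Parameters.** K = 7 (the standard compaction-class convention);
β defaults to 0.5 and should be raised toward the spatial coherence of the
data (the accuracy benchmarks use β matched to the generator, 1.2);
`max_iter` = 30 rounds; `tol` = 1e-4 on the fraction of labels changed.
σ is floored at 1e-6 × the intensity range so that noise-free data (where
the ML σ is 0) degenerate gracefully to nearest-mean classification; only
fully constant input is an error.

## Marker enrichment

For a marker segmentation (Otsu threshold on in-mask intensities times a
user factor, voxels strictly above retained), the per-class statistic is
Δ_k = 100·(m_k − f_k) percentage points, where f_k is the unweighted voxel
share of class k and m_k the intensity-weighted marker share (both sum
to 1, so ΣΔ_k = 0 exactly). Positive Δ_k means over-representation relative
to a random distribution over the nuclear volume. The marker side is
intensity-weighted by default because signal intensity carries information
about local marker density; `intensity_weighted=False` switches to plain
voxel counting (both conventions give identical results for binary
segmentations). Averaging across nuclei is mean ± SEM with SEM =
sd(ddof=1)/√n; single-nucleus summaries report SEM 0 with a flag.

## Nucleus segmentation, volume and DNA content

Gaussian smoothing (300 nm default, anisotropy-aware) → Otsu threshold →
connected components → dilate (15 iterations) → fill holes → erode (15
iterations) → drop objects under 200 µm³ and objects touching the XY image
border (Z truncation is normal in stacks and not penalised). The
dilate/erode cycle runs on a padded array so that objects at image faces
are not eaten asymmetrically by the erosion. Volume is voxel count ×
physical voxel volume; integrated DNA content subtracts the frame's modal
gray value (256-bin histogram mode) and clips at zero before summing.

## Degradation-kinetics traces

Traces sampled at Δt = 15 min are filtered in three steps: (1) cells whose
starting intensity is not above 50 counts are excluded; (2) retained traces
are normalised to their first value; (3) each cell's fluctuation is the
maximum relative deviation from its own centered rolling mean of 5
timepoints (window truncated at the trace ends — centered alignment
minimises phase bias), and cells strictly above the across-cell 90%
quantile of this statistic are excluded. The relative (not absolute)
deviation is used; with all-constant traces every fluctuation is 0 and
nothing is excluded, and the rule can never remove more than ⌈0.1·n⌉ cells.

## Replication domains

The RD channel is thresholded at 32/255 of the dtype maximum (floating
channels use the package's 0..65535 scale), restricted to the nuclear mask,
and touching objects are separated by a watershed on the Euclidean distance
transform. Seed candidates are local maxima of the lightly smoothed
(σ = 1 voxel, to break discrete plateaus on anisotropic grids) distance
map; seeds closer than the radius of a sphere of the "size guide" volume
(0.002 µm³ → 78 nm) are merged, preserving the guide's minimum-object-scale
semantics. Objects under 0.005 µm³ — the 3D-SIM resolution limit — are
excluded, so no returned volume is below the cutoff. Objects clipped at
the stack's Z faces are included. Boxplot summaries use inclusive (Tukey
hinge) quartiles and 1.5×IQR whiskers.

## Rank statistics

`mann_whitney_two_sided` uses the exact null distribution when
n_a + n_b ≤ 12 and the data are tie-free, otherwise the normal
approximation with tie and continuity corrections (both via scipy); the
exact path is validated against a brute-force permutation oracle in the
tests. Fully degenerate data (every value identical) return p = 1.
`holm_adjust` is the step-down Bonferroni–Holm adjustment (statsmodels),
input order preserved. The comparison family for condition contrasts is
the set of pairwise contrasts per metric.

## DNA halo

Scaffold and total areas come from two-level (three-class) Otsu
thresholding: the lower threshold separates background from halo (total
area At), the upper separates halo from scaffold (As); both regions are
hole-filled, and externally supplied masks can replace either threshold to
mimic manual outlining. The loop-size readout is R = √((At − As)/π); R
depends on the halo area only, not on At and As separately.

## Hi-C / Repli-Seq

- **Balancing.** Knight–Ruiz (inner-outer Newton with CG inner solves,
  written here because no installed package provides it) scales a symmetric
  matrix to unit row sums over non-masked bins; fully zero rows are masked.
  On failure it falls back to symmetric iterative proportional scaling with
  a warning. Verified against the rank-one closed form ([[1,2],[2,4]] →
  x = (1/√2, 1/(2√2))) and the row-sum postcondition (< 1e-6).
- **O/E.** Expected counts are per-diagonal means over non-masked bins (no
  smoothing — simplest defensible model at synthetic scale); zero-mean
  diagonals are masked. The transform is idempotent up to masking.
- **Compartments.** The Pearson map correlates O/E rows (zero-variance rows
  masked); the A/B vector is the leading eigenvector of the double-centred
  Pearson matrix, sign-anchored to an external reference track (early/late
  replication by default, since the A compartment replicates early);
  near-degenerate leading eigenvalues raise rather than returning an
  arbitrary vector.
- **Histone clusters.** Marks are z-scored per mark across bins, k-means
  with k = 6, 25 restarts and a fixed seed, clusters relabelled by
  descending size — the numbering is arbitrary, so determinism is imposed.
- **Contact ratios.** For cluster pairs (a,b), the mean contact over bin
  pairs (i∈a, j∈b, i≠j) in each matrix, reported as log2(post/pre);
  balanced counts are averaged (an O/E variant can be obtained by passing
  O/E matrices). Antisymmetric under swapping post/pre.
- **APA.** Sums (2w+1)² windows (w = 10 bins) centred on loop pixels; loops
  within w of the diagonal or edge are skipped and counted. Enrichment =
  centre value / mean of the lower-left (w/2)² corner block, the corner on
  the diagonal side where the distance-decay background is highest — the
  window size and corner convention are declared conventions, configurable,
  not reconstructions of any specific tool.
- **Replication timing.** log2((early+ε)/(late+ε)) with ε = 1, percentile
  transform over usable bins; preservation between conditions is the
  Spearman correlation of percentiles.

## Synthetic generators

The generators define the study conditions and export complete truth.

**Nucleus scenes.** The nuclear mask is a union of n overlapping ellipsoids
(n > 1 emulates the multilobulated nuclei formed after endomitosis),
smoothed by morphological closing; default lobe semi-axes 1.4/2.0/2.0 µm fit
a 128×128×32 grid at SIM sampling (40 nm lateral / 125 nm axial). Inside the
mask a 7-state Potts field is sampled by 30 checkerboard Gibbs sweeps at
β = 1.2, chosen so that label domains are a few hundred nm across
(neighbour agreement ≈ 0.83), the scale of chromatin domain clusters. A
peripheral rim (120 nm) is overridden to classes 6/7 in spatially coherent
patches — compacted heterochromatin at the lamina is contiguous, not
voxel-wise random — and a smooth random field is thresholded to carve
class-1 interchromatin channels up to a target share (default 0.15). DAPI
emissions are class mean + N(0, σ) with the default ladder 8000…56000 and
σ = 4000 (half the inter-mean gap); an optional separable Gaussian PSF
(FWHM 120 nm lateral / 300 nm axial, the SIM resolution limit) and
Gaussian/Poisson channel noise can be applied. Marker channels place signal
voxels with probability proportional to per-class weights at a target
density; RD channels render disjoint spheres in early (interior, classes
2–3), mid (near-rim), or late (compacted classes near the rim) patterns
with lognormal volumes and a minimum separation. Identical (spec, seed)
gives bit-identical scenes.

What the scenes do **not** emulate: raw structured-illumination frames and
reconstruction artifacts, optical aberrations, chromatic shifts, nucleoli,
replication fork kinetics, or polymer loop extrusion. Passing tests
therefore demonstrate correctness of the measurement code on data whose
generative model is known, not microscope-level realism.

**Halo scenes.** Hard-edged concentric discs (scaffold inside halo) on a
dark background with optional Gaussian noise; truth areas are the analytic
πr². **Decay traces.** Exponential responders (default half-life 35 min)
and a 4% non-responder fraction that stays at its start value. **Contact
data.** Expected counts follow 1/(1+d) distance decay, boosted ×1.6 within
same-sign compartment pairs (alternating 10-bin A/B blocks) and ×1.4 within
same-cluster pairs; loop pixels (≥25 bins off-diagonal, so APA windows
never touch the diagonal) are boosted ×4; the post matrix multiplies
within-strengthened-cluster contacts by a stated factor (default 2). With
`sampling_depth=None` the matrices are exact expected values, making
constructions like "factor 2 doubles contacts" hold to machine precision;
with a depth, counts are Poisson. Histone tracks are fixed per-cluster
archetype z-scores + N(0, 0.3); early/late tracks are tied to compartment
sign (A early).

## Problem sizes

Benchmarks run at sizes that exercise the algorithms while staying
desk-scale: 10 scenes of 128×128×32 voxels for classification accuracy,
100k marker voxels for the null calibration, 200-bin contact matrices,
n = 20 cells/arm for halo detection. These are the package's validation
conditions; real SIM stacks (~1024²×100) run with the same code, only
slower.

## Known limitations

- ICM is a greedy optimiser: labels near class boundaries depend on the
  (deterministic) sweep schedule, and a global MAP is not guaranteed.
- Classification-EM (hard assignments) biases σ slightly upward under
  strong spatial smoothing; means are anchored by the EM initialisation.
- The watershed size-guide separation approximates proprietary
  "separate touching objects" behaviour; heavily overlapping objects
  (centre distance below the guide radius) are merged by design.
- KR balancing assumes a connected non-zero support; matrices with several
  disconnected blocks may converge slowly and trigger the Sinkhorn
  fallback.
- The compartment eigenvector needs an external reference for sign; with
  no reference the global sign is arbitrary.
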