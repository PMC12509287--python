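# Methods

This note records the models, estimators, parameter choices and known
limitations behind `sxtmorph`, in the order data flows through the
package.

## Conventions

Volumes are isotropic 3D grids indexed `(z, y, x)`; the physical position
of voxel `(i, j, k)` is `index × voxel_um` from the volume origin. The
default voxel size is 0.033 µm, the midpoint of the 30–36 nm range
typical of full-rotation soft X-ray tomograms. Voxelization is by
voxel-center inclusion: a voxel belongs to a shape iff its center does —
unambiguous and directly checkable by brute-force oracles. Meshes live in
physical µm, never voxel indices. Semantic labels are fixed:
0 background, 1 cell (cytosol), 2 nucleus, 3 vacuole, 4 lipid droplet.

## Synthetic phantoms

The phantom module emulates the study conditions of whole-cell yeast SXT:
multi-cell scenes (optionally inside a cylindrical capillary, with
touching pairs), each cell a ball of radius 1.8–2.6 µm containing one
nucleus (2–5 µm³), 1–10 vacuoles (0.3–3 µm³ each) and 0–5 lipid droplets
(0.02–0.08 µm³), all strictly inside the cell. Per-voxel LAC is drawn
i.i.d. from the measured per-compartment Gaussians — vacuole
0.182 ± 0.039 µm⁻¹, nucleus 0.310 ± 0.020, lipid droplet 0.570 ± 0.111,
cytosol 0.346 ± 0.027 (mitochondria, 0.382 ± 0.018, are kept as a
reference value but not generated as a label) — truncated at zero.
Background noise is a half-normal with SD 0.005 µm⁻¹, a free choice since
the instrument noise is not characterized.

What the phantoms deliberately do *not* model: the imaging physics
(projection, reconstruction, PSF, reconstruction artifacts), non-spherical
organelle geometry, intra-organelle texture, and capillary walls. Tests
passing on phantoms therefore validate the measurement chain — given a
volume whose labels are recoverable from intensity, every downstream
quantity is computed correctly — not segmentation performance on real
tomograms.

Analytic fixtures: spheres and ellipsoids carry closed-form volume
(ellipsoid area by adaptive quadrature of the surface integral); lobed
shapes (unions of overlapping balls, pairwise attached at a fixed overlap
fraction) carry voxel-count volume and are guaranteed connected and
genus 0; the flat-contact pair (two plane-clipped balls facing across a
~20 nm gap) provides a geometrically flat membrane-contact interface.

## Presegmentation

Cells are detected by Otsu thresholding of the Gaussian-smoothed LAC
(σ = 0.1 µm), with a floor of 0.05 µm⁻¹ on the threshold so pure noise
never becomes foreground, followed by morphological closing and hole
filling. Touching cells are split by marker-based watershed on the
Euclidean distance transform, markers at distance-transform maxima
separated by ≥ 1 µm (a scale safely below the ~4 µm cell diameter);
instances below 2 µm³ are dropped as debris. These operators and
parameters are this package's choices; only the watershed-on-instances
strategy itself is fixed.

## Semantic segmentation

A symmetric 3D U-Net: per level two (3×3×3 conv → instance norm → ReLU)
blocks; 2× average-pool down, nearest-neighbor up with skip
concatenation; 1×1×1 head; softmax. The full-scale configuration is
depth 5 with 96 initial filters on 96³ blocks of 2×-binned input
(mean-pooled; labels strided; predictions upsampled back by nearest
neighbor). The loss is cross-entropy plus (1 − mean soft Dice over
foreground labels present in the target). Training uses Adam (lr 10⁻³
default, batch 2), random intensity scaling (0.9–1.1) and a shared
elastic warp (RMS displacement 0.5 voxels, correlation length 12 voxels —
gentle enough to distort a 16-voxel-radius sphere's volume by <10%),
k-fold splits with early stopping on the held-out fold's combined loss
(patience 50 epochs), and ensembling by voxel-wise softmax averaging.
Inference tiles the volume with 50% overlap and blends blocks with
separable triangular ramp weights, normalized per voxel so the weights
are an exact partition of unity (constant inputs fuse exactly).

The implementation is pure numpy with hand-derived backpropagation
(checked against finite differences), so throughput is CPU-bound:
desk-scale configurations (depth 3, 8 filters, 32³ blocks) overfit a
single phantom cell to F1 ≥ 0.9 in a few minutes, which is the supported
regime; the full-scale configuration is expressible but is a
multi-GPU-day workload not exercised by the tests. `n_folds=1` is the
degenerate overfitting mode with validation = training, for sanity
checks only.

## Evaluation and QC

Scores are voxel-wise per label: F1 (= Dice) `2|P∩T|/(|P|+|T|)`, reported
as undefined (not 0) when a label is absent from both volumes, and RelVol
`|P|/|T|`. Refinement selection returns cells worst-first by minimum
per-label F1, ties by cell id. QC fills internal holes per label
(claiming only background voxels), removes 26-connected components below
0.3 µm³ (vacuole), 0.4 µm³ (nucleus) and 0.02 µm³ (lipid droplet) —
reassigning their voxels to the dominant surrounding label so the filter
is idempotent — and drops foreground components touching the volume
boundary. Connectivity is 26-neighborhood throughout (a choice; the
alternative 6-connectivity changes component counts on thin structures).

## Voxel morphometrics

Volume is voxel count × voxel³. Voxel surface area counts exposed voxel
faces; on smooth objects this overestimates the true area by ≈1.5× (the
terracing inflation), so mesh areas should be preferred — the voxel
number is retained because it is the standard output of voxel-based
pipelines and the inflation is systematic. Sphericity is
π^⅓(6V)^⅔/A. Composition reports organelle volume fractions plus
"remaining cytoplasm" = 1 − Σ fractions; an organelle sum exceeding the
cell volume is rejected as an invalid segmentation. Per-structure records
include each 26-connected component and the per-cell aggregate.

## Mesh pipeline

Extraction is marching cubes at the 0.5 iso-level of the (zero-padded)
binary mask of the largest component, in physical µm, oriented outward.

Refinement follows the schedule: 15 smoothing iterations, 10 decimation
passes at threshold 1.5, 15 smoothing iterations, 10 decimation passes at
threshold 1.0, 10 smoothing iterations, and a final Taubin pass.
Smoothing is Taubin λ|µ (λ = 0.5, µ = −0.53). Two design choices make the
schedule robust:

- **Exact volume preservation.** Taubin smoothing is only approximately
  shrink-free; its residual drift (shrinkage on dense meshes, inflation
  on coarse ones) is removed by uniformly rescaling about the volume
  centroid back to the stage-entry volume after every stage. Refinement
  therefore preserves enclosed volume to machine precision by
  construction, and the pipeline's volume-change diagnostic measures only
  the (tiny) residual of this contract.
- **Selective decimation.** Decimation is quadric edge-collapse where a
  printed threshold t maps to a relative target edge length (t × mean
  edge length at stage entry): edges shorter than the target are
  collapse candidates, processed in increasing quadric-error order, and a
  collapse is refused when its error exceeds (0.025 × target)². Because
  quadric error vanishes on flat regions and grows with curvature, flat
  regions coarsen while curvature-dense regions keep proportionally more
  triangles; an already-smooth icosphere passes through refinement nearly
  unchanged. A final sliver pass (edges < 0.35 × target, error cap
  lifted) removes degenerate clusters that would otherwise concentrate
  spurious curvature. Link-condition and normal-flip checks protect
  manifoldness; any stage that breaks closedness raises an error naming
  the stage.

On voxelized spheres the schedule leaves volume unchanged (< 10⁻³ %) and
reduces surface area by ~7–8% — the removed terracing inflation of the
marching-cubes surface.

Curvature estimators: mean curvature from the cotangent-Laplacian
mean-curvature normal, signed positive-convex under outward normals;
Gaussian curvature from the angle deficit; both over mixed Voronoi vertex
areas. On refined icospheres the vertex means are within 0.2% (H) and
0.5% (K) of 1/R and 1/R². Boundary vertices are flagged NaN.
`curvature_summary` aggregates by unweighted vertex averaging (matching
the convention under which WED = ⟨H⟩² + SD(H)² − ⟨K⟩ converts vertex
statistics into surface integrals, exact for uniform triangle areas); an
area-weighted variant is provided because selective decimation makes
triangle areas non-uniform on convoluted surfaces, where the unweighted
convention is least accurate. The Gauss–Bonnet total Σ K·A_vertex equals
2πχ to machine precision for closed meshes — the residual against
4π(1−g) is reported with hole diagnostics as an integrity check.

Known limitation: SD(H) (and hence WED) retains some resolution
dependence — at very fine voxel sizes the fixed-iteration smoothing
removes proportionally less terracing noise, inflating curvature
variance. WED comparisons should be made at matched voxel size and
refinement settings; WED is a semiquantitative shape descriptor, not an
absolute physical energy.

## Interface geometry

Signed distances from the vertices of one closed mesh to the surface of
another are computed by exact point-to-triangle projection over KD-tree
candidates, signed by the angle-weighted pseudonormal of the nearest
feature (negative inside the reference). Interface regions are selected
either as overlap (distance < 0, meaningful only for interpenetrating
segmentations) or by an inter-membrane-distance threshold (default
0.030 µm, the characteristic contact-site gap) — parameterized, not
fixed, because segmentation error makes absolute IMD unreliable. An
optional erosion of selection-boundary rings isolates the flat interior
of a contact facet from its curved rim. Minimum IMD is the smaller of
the two directed vertex-sampled minima, symmetric to within one
vertex spacing.

## Cohort statistics

Two-sided Mann–Whitney U: exact null distribution for tie-free samples
with n_a + n_b ≤ 20, otherwise the normal approximation with tie and
continuity corrections (scipy backend; the test suite cross-checks the
exact branch against full enumeration). Reported p-values are raw;
Benjamini–Hochberg adjustment is available but off by default, matching
the reporting convention for this analysis style. Group summaries
(n, median, quartiles, variance) are deterministic and order-independent.

## Problem sizes used in tests

The suite runs phantom scenes at 0.06–0.1 µm voxels on grids ≤ 112³,
refinement fixtures at 0.04–0.06 µm, and the desk-scale training
configuration above; these sizes were chosen so the full chain (including
a complete training run) executes in minutes on one CPU while every
assertion remains at the tolerances stated for the full-scale quantities.
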