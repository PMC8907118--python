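# Methods

`corsurf` reconstructs cortical surfaces from T1-weighted MR volumes by
learning an implicit surface representation — a truncated signed Euclidean
distance ("level set") — with a 3D U-Net, then extracting an explicit,
genus-0 triangle mesh from the zero isocontour with digital-topology
guarantees. This note records the models, conventions, parameter choices and
numerical decisions, and what the synthetic validation does and does not
show.

## The level-set representation

A surface is encoded on a voxel grid as φ(x) = ±d(x, S) clamped to
±`truncation`, negative inside the surface and positive outside. Within the
band the value at each voxel center is the exact Euclidean distance (mm) to
the nearest point of the triangle mesh: candidate faces are prefiltered with
a k-d tree on triangle centroids using a provably sufficient search radius
(nearest-vertex upper bound plus the largest face circumradius), and the
point-to-triangle distance is the exact Voronoi-region closest-point
computation. Inside/outside is decided by ray-crossing parity; because all
voxel centers of one grid column are collinear, one ray classifies a whole
column, with a deterministic sub-voxel jitter of the column origin to avoid
edge-exact hits. Outside the band the nearest-vertex distance is a
sufficient bound because values clamp anyway.

**Truncation default: 8 mm.** Large enough to cover the cortical ribbon at
any plausible thickness, small enough to keep regression targets bounded.
Network targets are further scaled by 1/truncation into [−1, 1] and unscaled
before extraction.

Resampling between grids is trilinear; voxels outside the source domain are
assigned +truncation (outside). The same convention closes surfaces at the
grid border during extraction when `pad_boundary` is requested.

## Topology correction

The inside region of a predicted level set may contain handles, cavities or
spurious components. Correction rebuilds it by homotopic region growing:

1. enclosed background cavities are filled (they are unreachable by
   topology-preserving growth from outside their shell);
2. growth starts at the most-interior voxel (minimum φ) and admits candidate
   voxels in increasing-φ order (ties broken by lexicographic voxel index),
   each only when it is a *simple point* — its addition preserves the
   digital topology, tested via the topological numbers T6/T26 on the
   26-neighborhood for the configured connectivity pair ((6, 26) by
   default, (26, 6) available);
3. voxels the growth cannot admit are flipped to background; φ is kept
   wherever its sign already matches the corrected region, so sub-voxel
   zero-crossing positions survive wherever the region was already correct.

Flipped voxels are not set to a small epsilon: a removed voxel is given a
magnitude larger than any remaining-inside 26-neighbor, because the
trilinear saddle of a cell face with inside values −a, −b on one diagonal
separates them only if the cut values t satisfy t² > ab. With a small
uniform flip value the isosurface would tunnel diagonally through a
one-voxel cut and the extracted mesh would not be genus 0.

The procedure is idempotent at the region level and leaves an
already-spherical region bit-identical. Deeply buried defects (e.g. cutting
a solid torus) necessarily flip voxels with large |φ|; the correction is
therefore "minimal in growth order", not bounded in amplitude.

## Connectivity-consistent isosurface extraction

Classic marching cubes resolves ambiguous cell faces with per-cell
floating-point tests, which can contradict the digital topology the
correction just enforced. Here the 256-case triangle tables are *generated*
from the connectivity pair:

- on a checkerboard face the inside corners are separated for foreground
  connectivity 6 and connected for 26 — always, with no per-cell tests, so
  adjacent cells agree by construction;
- face segments are oriented with the inside region on the left (viewed
  from outside the cell) and linked into closed cycles;
- cycles are grouped by the inside-corner component they bound. A
  single-cycle component is a disk: 3-cycles become one triangle, longer
  cycles are fanned around a per-cell Steiner vertex at the cycle centroid.
  (A direct fan can place a chord inside a shared cell face which the
  neighboring cell duplicates, producing a non-manifold edge; the Steiner
  vertex cannot collide, and for planar level sets the pure centroid lies
  exactly in the plane, preserving linear-interpolation exactness.)
- a component bounded by two cycles is a tunnel: it is triangulated as a
  tube glued along an interior 3-vertex ring, preserving the digital genus.

The (26, 6) pair is handled by duality: the 26-connected foreground surface
of φ is the 6-connected foreground surface of −φ with reversed winding.
Vertices lie on grid edges at the linear-interpolation zero crossing (except
the rare interior Steiner points); grid values exactly zero are treated as
infinitesimally outside. The output is watertight, edge-manifold and
orientation-consistent for *arbitrary* input fields — the test suite checks
this on dense random binary fields for both connectivity pairs — and after
correction the Euler characteristic is exactly 2.

`smooth_surface` is a Taubin λ/μ alternation (default λ = 0.5, passband
0.1, so μ = 1/(passband − 1/λ) ≈ −0.526): shrink-resistant, topology- and
face-count-preserving, identity at 0 iterations.

## Networks and training

One encoder–decoder architecture serves both tasks. Encoder stages: two
3×3×3 convolutions each followed by a leaky ReLU (slope 0.01), then 2×2×2
max pooling; decoder stages: 2× nearest-neighbor upsampling followed by a
convolution, copy-and-concatenate of the same-resolution encoder features,
then two more conv+LReLU blocks. The segmentation head ends in a
channel-wise softmax trained with cross-entropy (3 classes: background,
left WM, right WM); the regression head is a plain 1×1×1 convolution
trained with mean squared error, leaving outputs unbounded. The engine is a
compact numpy layer stack with hand-derived backprop (im2col convolutions on
BLAS, verified against finite differences) and Adam.

Training schedule: batch size 2, initial learning rate 1e-3 decreasing by
1e-6 per epoch, at most 1000 epochs, stopping once the relative change of
the epoch-mean loss stays below 1e-4 for 50 consecutive epochs. Data
augmentation is off by default (regression fidelity). Patch sampling is
biased so at least half the patches contain a zero crossing of the target;
uniform sampling wastes most of the budget on clamped regions.

Full-scale defaults mirror the published configuration family (5 stages,
32 base channels, 128×160×112 patches, image+hemisphere-mask input for
regression). The desk-scale configuration used throughout the tests is
3 stages, 8 base channels, 32³ patches, trained on 16 phantoms for 60
epochs of 8 patches (regression) and 6 two-hemisphere phantoms for 40
epochs (segmentation) — sizes chosen so a full training + evaluation cycle
is a routine part of the test suite on a single CPU.

Sliding-window inference tiles the volume at half-patch stride and blends
overlapping patch outputs with a Gaussian window (σ = patch/8); blending
conserves constants, and a full-stride translation of the input translates
the prediction away from window-boundary voxels.

**Hemispheric masks.** The segmentation network is patch-based and hence
translation-invariant: it detects white matter reliably but cannot carry
left/right laterality within a patch. The hemispheric masks are therefore
derived from the predicted white-matter union geometrically — connected
components assigned left/right by world-x centroid (RAS, +x right), the
same rule as `hemisphere_split`. With a single component the side is chosen
by the centroid relative to the volume center and the other mask is empty
(with a warning).

## Phantoms

A phantom is a folded genus-0 "white" surface — an icosphere whose radius is
modulated by a random real spherical-harmonic series over degrees
2..`fold_degree`, scaled so the maximum radial excursion equals
`fold_amplitude` — plus a "pial" surface displaced outward along vertex
normals by a known `cortical_thickness_true`, the exact level sets of both,
tissue labels (background / GM / WM per hemisphere), and a T1-like image:
per-tissue mean intensity × a smooth multiplicative bias field (Gaussian-
filtered noise, amplitude as a fraction of the mean) + additive Gaussian
noise. Pial validity (no fold-back of the normal offset) is checked by
exact point-to-surface distance; on failure the amplitude is reduced by 30%
up to three times.

Defaults (the study conditions for all tests): 48³ grid at 1 mm, base
radius 14 mm, fold amplitude 3 mm, degree 6, thickness 2.5 mm (typical
human cortex), intensity means (10, 70, 110) for background/GM/WM
(T1w-like ordering), noise sd 5, bias amplitude 0.1, one hemisphere.
Two-hemisphere phantoms place two disjoint blobs along x on a 96×48×48
grid with a ≥ 4-voxel gap. Repeated "sessions" share all geometry and the
bias field (subject-level properties); only the noise realization differs.
One integer seed drives named substreams (harmonics / bias / noise /
parcellation) so each component is independently reproducible.

Surface parcellations are farthest-point seeded and assigned by geodesic
(graph) distance, giving contiguous, exhaustive regions.

What the phantoms do *not* emulate: MRI acquisition physics (no k-space,
Rician noise, partial voluming), skull/CSF compartments, midline contact
between hemispheres, lesions, or the non-star-shaped folding geometry of a
real cortex. Passing the suite demonstrates correctness of the geometry,
topology, learning and evaluation machinery under controlled conditions,
not clinical-grade accuracy on real MRI.

## Evaluation conventions

- **Mesh quality** Q = 4√3·A/(e₁²+e₂²+e₃²) per triangle (1 for equilateral,
  0 for degenerate; similarity-invariant); the summary is the unweighted
  mean over triangles.
- **Surface displacement** is vertex-to-surface (exact closest point on any
  triangle), one-directional by default with a symmetric-mean summary.
- **Cortical thickness** is the symmetric variant by default: white→pial
  distance averaged with the pial→white distance resampled onto the white
  surface; a one-directional flag exists.
- **Sulcal depth** is the signed distance to a "midsurface", positive in
  sulci. The midsurface is obtained by low-pass filtering the per-vertex
  *radius* about the shape centroid (50 umbrella-Laplacian iterations,
  λ = 0.5) with volume renormalization: a sphere is exactly its own
  midsurface, and a band-limited harmonic folding is attenuated by its
  graph-spectral factor. This radial construction assumes a roughly
  star-shaped closed surface (true for the phantoms, approximately true for
  a cortical hemisphere) and is a convention, not an equivalence to any
  specific neuroimaging tool's sulc map.
- **Dice** is 2|A∩B|/(|A|+|B|) per region over vertex sets; a region absent
  from both maps is reported missing, never 0.
- **Instability** is the per-vertex sample sd (ddof = 1) across sessions;
  for parcellations, the per-region sd of session Dice against the
  modal-label consensus parcellation.
- **Common space**: phantoms share ground-truth geometry, so cross-session
  maps are resampled by closest-point barycentric interpolation; spherical
  registration is out of scope.

## Numerical choices and degenerate inputs

- Exact-zero level-set values are nudged infinitesimally positive before
  extraction (a zero voxel is "outside"); encoding a mesh vertex exactly on
  a voxel center still yields φ = 0 there.
- Priority ties during homotopic growth break by lexicographic voxel index;
  extraction tables are deterministic; all randomness flows from named
  integer-seeded streams, and trained models round-trip through disk with
  bit-identical predictions.
- Degenerate mesh faces (repeated index) are rejected at construction;
  zero-area triangles in quality computation get Q = 0 with a warning.
- `normalize_intensity` (rescale to 0–255, then z-score) rejects constant
  images; it changes any unnormalized image but is a projection — z-scoring
  an increasing affine map of x equals z-scoring x, so reapplying it to an
  already-normalized image reproduces it.
- FreeSurfer binary surfaces are written big-endian without the volume-
  geometry footer; readers ignore one if present. OFF/PLY are ASCII at 17
  significant digits (exact float64 round trip).

## Known limitations

- The homotopic correction selects *a* minimal-in-growth-order genus-0
  region, not a globally optimal cut; deep defects are cut where the growth
  front meets.
- Tunnel cells and long cycles introduce interior Steiner vertices, so a
  few extracted vertices may not lie on grid edges (never for smooth,
  corrected level sets in practice).
- The desk-scale networks are intentionally tiny; they recover phantom
  surfaces to sub-voxel accuracy but say nothing about performance on real
  T1w images, scanner variability, or pathology.
- Sulcal depth's radial midsurface degrades on strongly non-star-shaped
  surfaces.
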