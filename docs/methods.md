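# Methods

This note records the models, parameter choices and numerical conventions
behind `tomocell`, and what the synthetic phantoms do and do not establish
about performance on real microtomography data.

## Conventions

Arrays are ordered (z, y, x) with 0-based voxel indices and half-open
extents. All physical quantities are micrometres; the coordinate of voxel
(i, j, k) is `origin_um + voxel_size_um * (i, j, k)`. Voxels are assumed
isotropic (default 0.65 µm). Downstream math runs on floats; the 8-bit
conversion and per-slice autocontrast (default tail fraction 0.0035) are
preprocessing conveniences for data exported from image tools, not
requirements. A constant volume maps to 0 under both, since degenerate
input carries no contrast. Centroid CSV tables use (x, y, z) column order,
converted at the I/O boundary only.

## Voxel classification

Features per Gaussian scale σ: gradient-of-Gaussian magnitude, difference
of Gaussians G_σ − G_{1.6σ} (1.6 is the standard scale-space ratio), and
the three descending eigenvalues of the structure tensor (outer product of
Gaussian gradients smoothed at 2σ). Default scales are 0.65, 1.3, 2.6 and
5.2 µm — one to eight voxels, spanning nucleus-edge to soma scale.
Boundaries are handled by reflection so that block-wise feature
computation agrees with in-place computation away from edges; the padded
prediction-equals-in-place property is tested.

Raw intensity is excluded from the default feature set: absolute
brightness drifts over millimetre-scale samples, and derivative-type
features are invariant to slowly varying offsets. It can be re-enabled
with `include_intensity=True`.

The classifier is a random forest (default 100 trees, unlimited depth,
seed required). Class order is fixed (cell, vessel, background, axon) so
serialized models are portable; prediction refuses a feature stack whose
manifest differs from the training manifest.

## Greedy cell detection

The spherical template of diameter d contains every voxel offset whose
Euclidean distance from the centre is ≤ d/2, normalized to unit sum, so
the correlation value at a voxel is the mean cell probability over the
ball — directly comparable to a probability threshold. Correlation is
computed by FFT with zero padding.

Detection is matching pursuit: argmax, record, zero out a ball (default:
the template's own diameter) centred on the detection, update the
correlation, repeat. The update subtracts the correlation of the removed
probability mass over its local support, which is numerically identical to
a full recompute. Stopping: correlation below `stop_threshold` (default
0.47, a tuned operating point for cortical µCT at 0.65 µm voxels) or an
iteration cap. The default template diameter 18 voxels corresponds to an
11.7 µm soma.

Determinism: correlation values are rounded to 10 decimals before each
argmax; exact ties then break to the smallest (z, y, x) index. The quantum
is far below any meaningful probability difference but makes the selected
sequence independent of whether the correlation was maintained by FFT
recomputation or local updates; equivalence with a direct-space
brute-force detector is tested exactly on random maps.

Detections whose centroid lies within a template radius of a volume face
are flagged `edge`; evaluation and block merging exclude or drop them,
since boundary objects are ambiguous for human and machine alike.

Cell size estimation grows the template at the fixed centroid from `d_min`
to `d_max` (1-voxel steps) and returns the diameter immediately before the
largest one-step correlation decrease — the last size at which the ball is
still inscribed in the soma. A profile with no drop (constant probability)
returns `d_min` flagged `degenerate`; balls truncated by the volume
boundary are renormalized and flagged.

## Vessel and axon segmentation

Vessels: binarize at ≥ threshold, dilate with a ball (default radius 8
voxels, the tuned operating point at 0.65 µm), label 26-connected
components, drop components below a voxel-count floor, renumber by
decreasing size. Axons: binarize at ≥ 0.3, morphological opening with a
ball of radius 4 voxels, then label. Two readings were possible for the
axon threshold ("below 0.3" vs "at least 0.3"); keeping p ≥ 0.3 is used
since the complement would segment background. "Structuring element of
size 4" is read as radius 4 voxels. Connectivity defaults to 26 for 3D
object continuity across diagonals and is configurable.

Vessel tuning uses the f₂ objective (recall-weighted), which matches how
vessel quality is judged by visual inspection; cell detection tunes by f₁.

## Spatial statistics

The kNN density estimator scores each grid bin centre v by
k / (N·ρ_k(v, V)) where ρ_k is the *squared* distance to the k-th nearest
centroid, normalizes scores into a probability mass function p, and
converts to cells/mm³ via p_d = p·N/Vol·10⁹. The conservation identity
Σ p_d·Vol·10⁻⁹ = N holds exactly by construction and is asserted. Two
guards: ρ_k is clamped below at (bin side / 2)², so a bin centre landing
exactly on a centroid cannot absorb all mass; and k (default 5) is a free
parameter — the estimate is insensitive to k for k ≪ N. The default bin
volume is 8.44 µm³ (side ≈ 2.035 µm, roughly one soma per bin); the side
length is the configurable primitive.

Because the estimator inverts a squared distance rather than a cubed one,
relative bin masses between regions of *different* density are compressed
(mass scales as density^(2/3)); the normalization step makes uniform-density
recovery exact, which is what the conservation and uniform-recovery tests
check. Distance statistics use centroid-to-voxel-centre geometry;
cell-to-vessel distances come from a Euclidean distance transform of the
vessel mask complement sampled at the nearest voxel, so they are accurate
to half a voxel.

## Evaluation

Centroid matching is globally-closest-first: repeatedly match the closest
remaining (detected, truth) pair within 10 µm and remove both. This is
deterministic, order-invariant, and never assigns a centroid twice. An
edge margin (default: template radius) removes boundary centroids from
both sets before matching.

SNR per cell is 20·log₁₀(s/n), with s and n the mean intensities of small
interior and just-exterior marker regions.

Effective resolution: radially averaged 2D power spectra of up to 256 xy
and xz planes from a signal region (SPS) and a background region (NPS); a
second-order polynomial is fitted to log₁₀ SPS over [0.05 µm⁻¹, Nyquist]
to smooth phase-retrieval artifacts (the fit band is a package choice);
the crossing where fitted SPS = 5 × NPS (Rose detectability criterion) is
interpolated linearly between frequency samples, and resolution is the
half-period 1/(2 f_c). The fit is exact for Gaussian-blurred noise, whose
log-spectrum is quadratic — the basis of the synthetic validation test.

## Blockwise processing

Cores tile the volume disjointly (final blocks truncated at high faces);
each core is read with padding for edge context. Merging applies two
deterministic rules in lexicographic block order: a detection belongs to
the block whose core contains its centroid, and a detection within 10 µm
of an already-accepted one is a duplicate. With pad ≥ one template
diameter the merged result equals the unblocked run exactly (tested); the
centroid-in-core ownership rule was chosen over an "touches a block edge"
heuristic precisely because it makes that invariance provable.

## Phantom generator

Phantoms emulate resin-embedded cortex under phase-contrast µCT at 0.65 µm
voxels: non-overlapping quasi-spherical somata (diameters normal 12 ± 2 µm
truncated at 6 µm, optional 1.2× brighter nucleus at 0.4× diameter),
tortuous vessels (swept spheres along correlated random walks, radius
2–5 µm, 1.25× brighter than cells), straight thin axon cylinders (1 µm),
a smooth multiplicative brightness field (10% amplitude, 40 µm correlation
length) and additive Gaussian noise (σ = 0.10 on a 0.35 background level).
All structure masks are pairwise disjoint by construction and all outputs
are a pure function of the spec and seed.

The cell/background contrast is calibrated empirically: after rendering,
the same interior/exterior marker protocol used on real data measures the
realized SNR, and the cell level (with the vessel level tracking it) is
rescaled until the measurement hits the target (default 4.6 dB) within
0.05 dB. Calibration acts on the contrast rather than the noise scale
because the SNR is a ratio of mean intensities, which zero-mean noise
leaves essentially unchanged; the noise realization is drawn once and
reused, so calibration preserves determinism.

What phantoms do not emulate: reconstruction artifacts (rings, beam
hardening, phase-retrieval halos), anisotropic or spatially varying noise,
non-spherical or touching somata, vessel branching, and real annotation
noise. Passing the recovery tests therefore demonstrates the correctness
and stability of the algorithms under the stated contrast and noise
conditions, not segmentation accuracy on arbitrary tissue.

## Problem sizes in the shipped tests

The end-to-end recovery test trains on a 144³ phantom (18 cells), tunes
over a 3 × 3 grid (template diameter × stopping threshold), and tests on
an independent 200³ phantom (30 cells); blocking invariance uses 120³ with
2 × 2 × 2 cores; oracle equivalence uses 100 random maps up to 32³. These
sizes exercise every code path, including block merging, at full
algorithmic fidelity.

## Known limitations

- The fixed-size spherical template under-detects somata well below the
  template diameter (see the worked example in the README) and cannot
  separate touching cells of very different sizes.
- Size estimation is quantized to whole-voxel diameters and biased near
  volume faces despite renormalization.
- The kNN density field is a smoothed visualization-grade estimate;
  bin-level values depend on k and the bin side near sharp density edges.
- Axon segmentation assumes near-straight, well-separated myelinated
  fibres; it does not trace across gaps or junctions.
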