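# tomocell

Quantitative mesoscale neuroanatomy from 3D X-ray microtomography (µCT).

Synchrotron µCT of resin-embedded brain tissue resolves cell bodies, blood
vessels and large myelinated axons at micron, isotropic resolution across
millimetre-scale samples — far too many objects to annotate by hand.
`tomocell` provides the full analysis chain for such volumes: per-voxel
classification, template-based cell detection with size estimation,
morphological vessel/axon segmentation, nonparametric density estimation,
distance statistics, an evaluation suite, and a synthetic phantom generator
so that every stage is testable without beamline data. It is aimed at
neuroanatomists and imaging scientists working with reconstructed µCT
volumes (typical voxel size 0.65 µm).

## Method

1. **Probability maps.** A random forest is trained on sparse voxel
   annotations using multi-scale 3D features — gradient-of-Gaussian
   magnitude, difference of Gaussians, structure-tensor eigenvalues — and
   produces per-voxel class probabilities P = {P_cell, P_vessel, P_bg}
   summing to 1.
2. **Cell detection.** Somata are quasi-spherical, so P_cell is correlated
   (via FFT) with a unit-sum spherical template of diameter ≈ one soma
   (default 18 voxels). Detection is greedy matching pursuit: take the
   global correlation maximum as the next centroid, zero the probability
   map in a ball around it, update the correlation, and repeat until the
   best remaining correlation falls below a stopping threshold (default
   0.47). Growing the template at a fixed centroid until the correlation
   drops sharply estimates each cell's diameter.
3. **Vessel / axon segmentation.** Threshold the probability map, dilate
   (vessels) or open (axons) with a spherical structuring element, label
   connected components, and remove small components.
4. **Spatial statistics.** Cell density on a 3D grid via k-nearest-neighbour
   estimation, p(v) ∝ k / (N ρ_k(v, V)) with ρ_k the squared distance to
   the k-th nearest centroid, normalized over bins and converted to
   cells/mm³ as p_d(v) = p(v)·N/Vol·10⁹; plus nearest-neighbour
   cell-to-cell and distance-transform cell-to-vessel distances.
5. **Evaluation.** Voxelwise and object-level precision/recall/f_β;
   object matching pairs detected and true centroids globally-closest-first
   within 10 µm; grid search tunes detection by f₁ and vessels by f₂; SNR
   is 20·log10 of the interior/exterior mean-intensity ratio; effective
   resolution is the half-period 1/(2f) of the Rose-criterion (5×) crossing
   between signal and noise power spectra.

Everything scales to larger-than-memory volumes through disjoint core
blocks read with padding, processed independently, and merged with
deterministic duplicate elimination.

## Worked example

```python
import numpy as np
from tomocell import (
    PhantomSpec, generate_phantom, probabilities_from_truth,
    DetectionParams, detect_cells, match_centroids, CentroidSet,
    estimate_density, cell_to_cell_distances, summarize_distances,
)

spec = PhantomSpec(shape_vox=(100, 100, 100), n_cells=15, n_vessels=1, seed=3)
phantom = generate_phantom(spec)
print(f"phantom SNR: {phantom.measured_snr_db:.2f} dB")

maps = probabilities_from_truth(phantom.truth_masks, blur_sigma=1.0, flip_noise=0.02)
dets = detect_cells(maps.cell, DetectionParams(cell_size_vox=18, stop_threshold=0.47),
                    voxel_size_um=0.65)
print(f"detected {len(dets)} cells (truth: {len(phantom.truth_cells)})")

res = match_centroids(CentroidSet.from_detections(dets), phantom.truth_cells,
                      max_dist_um=10.0)
print(f"precision {res.p:.3f}, recall {res.r:.3f}")

cells = CentroidSet.from_detections(dets)
density = estimate_density(cells, k=5)
print(f"mean kNN density: {density.mean_density:.3g} cells/mm^3")
mean, sd, mode = summarize_distances(cell_to_cell_distances(cells))
print(f"cell-to-cell distance: {mean:.1f} +/- {sd:.1f} um (mode {mode:.1f} um)")
```

Output:

```
phantom SNR: 4.61 dB
detected 14 cells (truth: 15)
precision 1.000, recall 0.933
mean kNN density: 1.15e+05 cells/mm^3
cell-to-cell distance: 18.0 +/- 3.7 um (mode 16.5 um)
```

The phantom is calibrated so that cell interiors are 4.6 dB brighter than
their surround (the contrast regime of real tissue). The one missed cell
is an unusually small soma (6.9 µm, near the 6 µm truncation floor of the
diameter distribution) whose mean probability under the 11.7 µm template
stays below the 0.47 stopping threshold — the expected failure mode of a
fixed-size template. The
recovered density (1.15 × 10⁵ cells/mm³) is in the range reported for
mouse neocortex.

A command-line interface mirrors the library: `tomocell phantom`,
`tomocell classify`, `tomocell detect-cells`, `tomocell segment-vessels`,
`tomocell segment-axons`, `tomocell density`, `tomocell stats`,
`tomocell evaluate`, and `tomocell run --config pipeline.yaml` for the full
blockwise pipeline.

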