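"""Blockwise processing for volumes larger than memory, plus the pipeline.

A large volume is tiled into disjoint core cuboids; each core is read with
surrounding padding for edge context, processed independently, and the
per-block detections merged. Ownership is unambiguous: a detection belongs
to the block whose core contains its centroid, and near-duplicates arising
from padded overlap are removed against already-accepted detections. With
padding of at least one template diameter, the merged result equals an
unblocked run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from tomocell.cell_detection import (
    CellDetection,
    DetectionParams,
    detect_cells,
    estimate_sizes,
    make_template,
)
from tomocell.spatial_analysis import (
    CentroidSet,
    cell_to_cell_distances,
    cell_to_vessel_distances,
    estimate_density,
    summarize_distances,
)
from tomocell.structure_segmentation import MorphParams, segment_vessels, vascular_fraction
from tomocell.volume_io import ImageVolume, extract_block, write_centroids, write_volume


@dataclass
class BlockPlan:
    """Disjoint core cuboids tiling a volume, processed in listed order."""

    volume_shape: tuple[int, int, int]
    cores: list[tuple[tuple[int, int, int], tuple[int, int, int]]]  # (origin, shape)
    pad_vox: int


def plan_blocks(volume_shape, block_shape, pad_vox: int = 0) -> BlockPlan:
    """Regular tiling of a volume into half-open core blocks.

    Blocks at the high faces are truncated so every voxel belongs to
    exactly one core. Processing order is lexicographic in (z, y, x).
    """
    volume_shape = tuple(int(n) for n in volume_shape)
    block_shape = tuple(int(b) for b in block_shape)
    if min(block_shape) < 1:
        raise ValueError("block dimensions must be >= 1")
    if any(b > n for b, n in zip(block_shape, volume_shape)):
        raise ValueError("block_shape exceeds volume_shape")
    if pad_vox < 0:
        raise ValueError("pad must be >= 0")
    starts = [range(0, n, b) for n, b in zip(volume_shape, block_shape)]
    cores = []
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                origin = (z0, y0, x0)
                shape = tuple(
                    min(b, n - o) for b, n, o in zip(block_shape, volume_shape, origin)
                )
                cores.append((origin, shape))
    return BlockPlan(volume_shape, cores, pad_vox)


def merge_detections(
    per_block: list[tuple[tuple[int, int, int], tuple[int, int, int], list[CellDetection]]],
    plan: BlockPlan,
    overlap_dist_um: float = 10.0,
) -> list[CellDetection]:
    """Merge per-block detections into a single deduplicated list.

    ``per_block`` pairs each core (origin, shape) with its detections in
    *global* coordinates. Rules, applied in plan order: a detection whose
    centroid falls outside its block's core is dropped (the neighbour that
    owns it reports it); a detection within ``overlap_dist_um`` of an
    already-accepted one is dropped as a duplicate. The result is
    independent of the chosen blocking whenever the pad covers the
    detector's template diameter.
    """
    order = {core: i for i, (core, _shape) in enumerate(plan.cores)}
    for core, _shape, _dets in per_block:
        if tuple(core) not in order:
            raise ValueError(f"block core {core} not in plan")
    merged: list[CellDetection] = []
    accepted_um: list[np.ndarray] = []
    for core, shape, dets in sorted(per_block, key=lambda e: order[tuple(e[0])]):
        lo = np.asarray(core)
        hi = lo + np.asarray(shape)
        for det in dets:
            c = np.asarray(det.centroid_vox)
            if ((c < lo) | (c >= hi)).any():
                continue
            if any(
                np.linalg.norm(det.centroid_um - a) <= overlap_dist_um
                for a in accepted_um
            ):
                continue
            merged.append(det)
            accepted_um.append(np.asarray(det.centroid_um, float))
    return merged


def detect_cells_blockwise(
    p_cell: np.ndarray,
    params: DetectionParams,
    plan: BlockPlan,
    voxel_size_um: float = 0.65,
    origin_um=(0.0, 0.0, 0.0),
    overlap_dist_um: float = 10.0,
) -> list[CellDetection]:
    """Run the greedy detector per padded block and merge the results.

    Each block is extracted with the plan's padding, detected independently
    with zero-padded correlation, and its detections lifted to global
    coordinates; edge flags are recomputed against the full volume.
    """
    vol = ImageVolume(np.asarray(p_cell), voxel_size_um=voxel_size_um,
                      origin_um=np.asarray(origin_um, float))
    tmpl_r = make_template(params.cell_size_vox).radius_vox
    shape = np.array(p_cell.shape)
    per_block = []
    for core_origin, core_shape in plan.cores:
        block = extract_block(vol, core_origin, core_shape, plan.pad_vox)
        dets = detect_cells(block.volume.data, params,
                            voxel_size_um=voxel_size_um,
                            origin_um=block.volume.origin_um)
        offset = vol.um_to_voxel(block.volume.origin_um)
        lifted = []
        for d in dets:
            g = d.shifted(offset, np.asarray(origin_um, float), voxel_size_um)
            c = np.asarray(g.centroid_vox)
            g.edge = bool((c < tmpl_r).any() or (shape - 1 - c < tmpl_r).any())
            g.flags = ["edge"] if g.edge else []
            lifted.append(g)
        per_block.append((core_origin, core_shape, lifted))
    return merge_detections(per_block, plan, overlap_dist_um)


def run_pipeline(config, output_dir=None) -> dict:
    """Execute the full pipeline from a config dict or YAML path.

    Stages (each switchable from config): phantom generation or volume
    loading, probability-map computation (trained classifier or idealized
    maps from truth), blockwise cell detection with merging, per-cell size
    estimation, vessel segmentation, density estimation, and distance
    statistics. Writes ``cells.csv``, ``vessel_mask.h5``, ``density.h5``,
    ``stats.json`` and a run manifest to the output directory and returns
    the in-memory results. Deterministic given config + seed.
    """
    from tomocell import phantom as ph
    from tomocell.pixel_classifier import (
        SparseAnnotation,
        compute_features,
        predict_probabilities,
        train_classifier,
    )

    if not isinstance(config, dict):
        with open(config) as f:
            config = yaml.safe_load(f)
    seed = int(config.get("seed", 0))
    out = Path(output_dir or config.get("output_dir", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)

    results: dict = {}
    if "phantom" in config:
        spec = ph.PhantomSpec(**{**config["phantom"], "seed": seed})
        pvol = ph.generate_phantom(spec)
        vol = pvol.intensity
        results["phantom"] = pvol
    else:
        from tomocell.volume_io import read_volume

        vcfg = config["input"]
        vol = read_volume(vcfg["volume"], dataset=vcfg.get("dataset", "exchange/data"),
                          voxel_size_um=vcfg.get("voxel_size_um", 0.65))

    ccfg = config.get("classifier", {})
    if ccfg.get("mode", "train") == "truth_maps":
        maps = ph.probabilities_from_truth(
            results["phantom"].truth_masks,
            blur_sigma=ccfg.get("blur_sigma", 1.0),
            flip_noise=ccfg.get("flip_noise", 0.0),
            seed=seed,
        )
    else:
        annot = ph.sparse_training_annotation(
            results["phantom"], per_class=ccfg.get("per_class", 8000), seed=seed
        )
        feats = compute_features(vol, ccfg.get("scales_um", (0.65, 1.3, 2.6, 5.2)))
        clf = train_classifier(feats, annot, n_trees=ccfg.get("n_trees", 100), seed=seed)
        maps = predict_probabilities(clf, vol, features=feats)
    results["prob_maps"] = maps

    dcfg = config.get("detection", {})
    params = DetectionParams(
        cell_size_vox=dcfg.get("cell_size_vox", 18),
        stop_threshold=dcfg.get("stop_threshold", 0.47),
        max_iterations=dcfg.get("max_iterations", 10_000),
    )
    bcfg = config.get("blocks")
    if bcfg:
        plan = plan_blocks(vol.shape, bcfg["block_shape"], bcfg.get("pad_vox", 2 * params.cell_size_vox))
        dets = detect_cells_blockwise(maps.cell, params, plan,
                                      voxel_size_um=vol.voxel_size_um,
                                      origin_um=vol.origin_um)
    else:
        dets = detect_cells(maps.cell, params, voxel_size_um=vol.voxel_size_um,
                            origin_um=vol.origin_um)
    if dcfg.get("estimate_sizes", True):
        estimate_sizes(maps.cell, dets, voxel_size_um=vol.voxel_size_um)
    results["detections"] = dets
    write_centroids(dets, out / "cells.csv")

    vcfg = config.get("vessels", {})
    vessels = segment_vessels(
        maps.vessel,
        MorphParams(
            threshold=vcfg.get("threshold", 0.47),
            dilation_radius_vox=vcfg.get("dilation_radius_vox", 8),
            min_component_vox=vcfg.get("min_component_vox", 0),
        ),
        voxel_size_um=vol.voxel_size_um,
        origin_um=vol.origin_um,
    )
    results["vessels"] = vessels
    write_volume(vessels, out / "vessel_mask.h5", dataset="labels")

    stats: dict = {"n_cells": len(dets), "vascular_fraction_pct": vascular_fraction(vessels)}
    interior = [d for d in dets if not d.edge]
    if len(interior) > config.get("density", {}).get("k", 5):
        cells = CentroidSet.from_detections(interior)
        den = estimate_density(
            cells,
            bin_volume_um3=config.get("density", {}).get("bin_volume_um3", 8.44),
            k=config.get("density", {}).get("k", 5),
        )
        results["density"] = den
        _write_density(den, out / "density.h5")
        stats["mean_density_per_mm3"] = den.mean_density
        if len(cells) >= 2:
            c2c = cell_to_cell_distances(cells)
            m, sd, mode = summarize_distances(c2c)
            stats["cell_to_cell_um"] = {"mean": m, "sd": sd, "mode": mode}
        if vessels.mask.any():
            c2v = cell_to_vessel_distances(cells, vessels)
            m, sd, mode = summarize_distances(c2v)
            stats["cell_to_vessel_um"] = {"mean": m, "sd": sd, "mode": mode}
    results["stats"] = stats
    with open(out / "stats.json", "w") as f:
        json.dump(stats, f, indent=2)
    manifest = {
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "output_dir"},
        "n_detections": len(dets),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return results


def _write_density(den, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("p", data=den.p)
        f.create_dataset("p_d", data=den.p_d)
        f.attrs["origin_um"] = den.origin_um
        f.attrs["bin_side_um"] = den.bin_side_um
        f.attrs["k"] = den.k
        f.attrs["n_cells"] = den.n_cells
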