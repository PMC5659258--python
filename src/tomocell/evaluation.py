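"""Evaluation machinery: f-beta scores, centroid matching, SNR, tuning,
and effective-resolution estimation.

Object-level cell detection is scored by greedy centroid matching: the
globally closest unmatched (detected, truth) pair is matched repeatedly
while its distance stays within a tolerance (10 µm by default), and
precision/recall follow from the match count. Pixel-level segmentations are
scored voxelwise. SNR between a structure and its surround is
``20 log10(s/n)`` on mean intensities. Effective image resolution follows
the Rose criterion: the finest spatial frequency at which the (smoothed)
signal power spectrum still exceeds five times the noise power spectrum,
reported as the half-period 1/(2 f).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from tomocell.cell_detection import DetectionParams, detect_cells
from tomocell.spatial_analysis import CentroidSet
from tomocell.volume_io import ImageVolume, LabelVolume


def fbeta(p: float, r: float, beta: float = 1.0) -> float:
    """Weighted harmonic mean of precision and recall.

    ``f_beta = (1 + beta²) p r / (beta² p + r)``; beta=2 weights recall more
    heavily. Returns 0 when both p and r are 0.
    """
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("p and r must lie in [0, 1]")
    denom = beta**2 * p + r
    if denom == 0:
        return 0.0
    return (1 + beta**2) * p * r / denom


@dataclass
class PixelEval:
    """Voxelwise confusion counts with precision, recall and f-beta."""

    tp: int
    fp: int
    fn: int
    p: float
    r: float
    f: dict[float, float] = field(default_factory=dict)


def pixel_eval(pred: LabelVolume, truth: LabelVolume, betas=(1.0, 2.0)) -> PixelEval:
    """Voxel-level precision/recall/f-beta between binarized masks.

    Predicted voxels absent from the truth count as false positives; truth
    voxels missed by the prediction count as false negatives.
    """
    a = np.asarray(pred.data) > 0
    b = np.asarray(truth.data) > 0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(a & ~b))
    fn = int(np.count_nonzero(~a & b))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return PixelEval(tp, fp, fn, p, r, {beta: fbeta(p, r, beta) for beta in betas})


@dataclass
class MatchResult:
    """Outcome of centroid matching between detected and truth sets."""

    pairs: list[tuple[int, int, float]]
    unmatched_detected: list[int]
    unmatched_truth: list[int]
    excluded_edge_detected: int
    excluded_edge_truth: int
    p: float
    r: float

    @property
    def n_matches(self) -> int:
        return len(self.pairs)


def _edge_filter(pos: np.ndarray, bounds_um, margin: float) -> np.ndarray:
    lo, hi = (np.asarray(b, float) for b in bounds_um)
    keep = ((pos >= lo + margin) & (pos <= hi - margin)).all(axis=1)
    return keep


def match_centroids(
    detected: CentroidSet,
    truth: CentroidSet,
    max_dist_um: float = 10.0,
    edge_margin_um: float = 0.0,
    bounds_um=None,
) -> MatchResult:
    """Greedy globally-closest-first matching of detected to truth centroids.

    Repeatedly pairs the closest remaining (detected, truth) centroids while
    their distance is within ``max_dist_um``, removing both from play; the
    result is independent of input ordering. Centroids within
    ``edge_margin_um`` of the bounding box (``bounds_um``, default the union
    box of both sets) are excluded from both sets beforehand, since objects
    at volume faces are ambiguous for human and machine alike. Precision is
    matches/|detected| and recall matches/|truth| over the surviving sets.
    """
    if max_dist_um < 0:
        raise ValueError("max_dist_um must be >= 0")
    det = detected.positions_um
    tru = truth.positions_um
    det_keep = np.ones(len(det), dtype=bool)
    tru_keep = np.ones(len(tru), dtype=bool)
    if edge_margin_um > 0:
        if bounds_um is None:
            allpos = np.vstack([det, tru]) if len(det) + len(tru) else np.zeros((1, 3))
            bounds_um = (allpos.min(axis=0), allpos.max(axis=0))
        if len(det):
            det_keep = _edge_filter(det, bounds_um, edge_margin_um)
        if len(tru):
            tru_keep = _edge_filter(tru, bounds_um, edge_margin_um)
    det_idx = np.flatnonzero(det_keep)
    tru_idx = np.flatnonzero(tru_keep)

    pairs: list[tuple[int, int, float]] = []
    if len(det_idx) and len(tru_idx):
        dist = cdist(det[det_idx], tru[tru_idx])
        free_d = np.ones(len(det_idx), dtype=bool)
        free_t = np.ones(len(tru_idx), dtype=bool)
        big = np.inf
        work = dist.copy()
        while True:
            i, j = np.unravel_index(np.argmin(work), work.shape)
            if work[i, j] > max_dist_um or not np.isfinite(work[i, j]):
                break
            pairs.append((int(det_idx[i]), int(tru_idx[j]), float(dist[i, j])))
            free_d[i] = free_t[j] = False
            work[i, :] = big
            work[:, j] = big
        unmatched_d = [int(k) for k in det_idx[free_d]]
        unmatched_t = [int(k) for k in tru_idx[free_t]]
    else:
        unmatched_d = [int(k) for k in det_idx]
        unmatched_t = [int(k) for k in tru_idx]

    n_d, n_t = len(det_idx), len(tru_idx)
    p = len(pairs) / n_d if n_d else 0.0
    r = len(pairs) / n_t if n_t else 0.0
    return MatchResult(
        pairs=pairs,
        unmatched_detected=unmatched_d,
        unmatched_truth=unmatched_t,
        excluded_edge_detected=int(np.count_nonzero(~det_keep)),
        excluded_edge_truth=int(np.count_nonzero(~tru_keep)),
        p=p,
        r=r,
    )


@dataclass
class SNRSample:
    """Contrast of one cell against its immediate surround, in dB."""

    cell_id: int
    s: float
    n: float
    snr_db: float


def compute_snr(
    vol: ImageVolume,
    interior: LabelVolume,
    exterior: LabelVolume,
) -> tuple[list[SNRSample], float, float]:
    """Per-cell SNR ``20 log10(s_i / n_i)`` from paired marker labels.

    ``s_i``/``n_i`` are the mean intensities of the voxels labelled ``i`` in
    the interior and exterior marker volumes respectively. Returns the
    per-cell samples plus the mean and sample SD over cells.
    """
    data = np.asarray(vol.data, dtype=float)
    ids_in = set(np.unique(interior.data)) - {0}
    ids_out = set(np.unique(exterior.data)) - {0}
    ids = sorted(ids_in & ids_out)
    if not ids:
        raise ValueError("no shared labels between interior and exterior markers")
    samples = []
    for i in ids:
        s = float(data[interior.data == i].mean())
        n = float(data[exterior.data == i].mean())
        if s <= 0 or n <= 0:
            raise ValueError(f"non-positive mean intensity for cell {i}")
        samples.append(SNRSample(int(i), s, n, 20.0 * np.log10(s / n)))
    vals = np.array([smp.snr_db for smp in samples])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return samples, float(vals.mean()), sd


def grid_search(
    param_grid: dict[str, list],
    prob_maps,
    truth,
    objective: str = "f1_cells",
    match_dist_um: float = 10.0,
    edge_margin_um: float = 0.0,
    voxel_size_um: float | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search over detection or vessel parameters.

    ``objective="f1_cells"`` scores each grid point by running the greedy
    detector (grid keys are :class:`DetectionParams` fields) and matching
    centroids against a truth :class:`CentroidSet` with f1.
    ``objective="f2_vessels"`` scores vessel segmentation (grid keys are
    :class:`~tomocell.structure_segmentation.MorphParams` fields) by
    voxelwise f2 against a truth :class:`LabelVolume` — recall-weighted,
    which matches how vessel quality is judged visually.

    Ties break to the smallest threshold, then the smallest cell size.
    Returns (best parameter dict, full score table).
    """
    from tomocell.structure_segmentation import MorphParams, segment_vessels

    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("param_grid must be non-empty")
    keys = list(param_grid)
    rows = []
    for combo in itertools.product(*(param_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        if objective == "f1_cells":
            vs = voxel_size_um or getattr(prob_maps, "voxel_size_um", 0.65)
            dp = DetectionParams(**params)
            dets = detect_cells(prob_maps.cell, dp, voxel_size_um=vs,
                                origin_um=getattr(prob_maps, "origin_um", (0, 0, 0)))
            det_set = CentroidSet.from_detections(dets) if dets else CentroidSet(
                np.zeros((0, 3)))
            res = match_centroids(det_set, truth, max_dist_um=match_dist_um,
                                  edge_margin_um=edge_margin_um,
                                  bounds_um=_prob_bounds(prob_maps, vs))
            score = fbeta(res.p, res.r, 1.0)
            rows.append({**params, "p": res.p, "r": res.r, "score": score})
        elif objective == "f2_vessels":
            mp = MorphParams(**params)
            seg = segment_vessels(prob_maps.vessel, mp,
                                  voxel_size_um=getattr(prob_maps, "voxel_size_um", 0.65))
            ev = pixel_eval(seg, truth, betas=(2.0,))
            rows.append({**params, "p": ev.p, "r": ev.r, "score": ev.f[2.0]})
        else:
            raise ValueError(f"unknown objective {objective!r}")
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["score"]
        + [c for c in ("threshold", "stop_threshold") if c in table]
        + [c for c in ("cell_size_vox",) if c in table],
        ascending=[False] + [True] * (
            sum(c in table for c in ("threshold", "stop_threshold", "cell_size_vox"))
        ),
        kind="stable",
    )
    best = ranked.iloc[0]
    if best["score"] == 0:
        warnings.warn("all grid points scored 0; returning the first point")
        best = table.iloc[0]
    best_params = {k: best[k] for k in keys}
    return best_params, table


def _prob_bounds(prob_maps, voxel_size_um):
    origin = np.asarray(getattr(prob_maps, "origin_um", (0.0, 0.0, 0.0)), float)
    shape = np.array(prob_maps.cell.shape)
    return origin, origin + voxel_size_um * (shape - 1)


def half_period_resolution(f_c_per_um: float) -> float:
    """Half-period resolution (µm) of a crossing frequency f (µm⁻¹): 1/(2f)."""
    if f_c_per_um <= 0:
        raise ValueError("crossing frequency must be positive")
    return 1.0 / (2.0 * f_c_per_um)


def _radial_average_power(planes: np.ndarray, voxel_size_um: float):
    """Mean radially averaged 2D power spectrum over a stack of planes.

    Returns (frequencies µm⁻¹, mean power per radial bin).
    """
    n0, n1 = planes.shape[1:]
    power = np.zeros((n0, n1))
    for pl in planes:
        spec = np.fft.fftshift(np.fft.fft2(pl - pl.mean()))
        power += np.abs(spec) ** 2
    power /= len(planes)
    f0 = np.fft.fftshift(np.fft.fftfreq(n0, d=voxel_size_um))
    f1 = np.fft.fftshift(np.fft.fftfreq(n1, d=voxel_size_um))
    ff0, ff1 = np.meshgrid(f0, f1, indexing="ij")
    fr = np.hypot(ff0, ff1)
    nyquist = 1.0 / (2.0 * voxel_size_um)
    n_bins = min(n0, n1) // 2
    edges = np.linspace(0, nyquist, n_bins + 1)
    which = np.digitize(fr.ravel(), edges) - 1
    valid = (which >= 0) & (which < n_bins)
    sums = np.bincount(which[valid], weights=power.ravel()[valid], minlength=n_bins)
    counts = np.bincount(which[valid], minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    good = counts > 0
    return centers[good], sums[good] / counts[good]


def estimate_resolution(
    vol: ImageVolume,
    signal_region: tuple[slice, slice, slice],
    background_region: tuple[slice, slice, slice],
    n_planes: int = 256,
    rose_factor: float = 5.0,
    fit_band_per_um: tuple[float, float] | None = None,
) -> dict:
    """Effective image resolution from signal vs noise power spectra.

    Averages radial power spectra of up to ``n_planes`` xy (transverse) and
    xz (vertical) planes from the signal region (SPS) and the background
    region (NPS); fits a second-order polynomial to log-SPS to smooth
    reconstruction artifacts; and finds the lowest frequency where the
    fitted SPS drops to ``rose_factor`` (default 5, the Rose detectability
    criterion) times the NPS. Reports the half-period resolution 1/(2 f_c)
    per orientation.

    Returns a dict with ``f_c_xy``, ``f_c_xz`` (µm⁻¹), ``res_xy_um``,
    ``res_xz_um`` and the sampled spectra.
    """
    sig = np.asarray(vol.data[signal_region], dtype=float)
    bg = np.asarray(vol.data[background_region], dtype=float)
    out: dict = {}
    for name, axis in (("xy", 0), ("xz", 1)):
        sig_planes = np.moveaxis(sig, axis, 0)[: n_planes]
        bg_planes = np.moveaxis(bg, axis, 0)[: n_planes]
        if len(sig_planes) == 0 or len(bg_planes) == 0:
            raise ValueError("regions too small for the requested planes")
        f_s, sps = _radial_average_power(sig_planes, vol.voxel_size_um)
        f_n, nps = _radial_average_power(bg_planes, vol.voxel_size_um)
        nps_i = np.interp(f_s, f_n, nps)
        band = fit_band_per_um or (0.05, 1.0 / (2.0 * vol.voxel_size_um))
        in_band = (f_s >= band[0]) & (f_s <= band[1]) & (sps > 0)
        if in_band.sum() < 3:
            raise ValueError("too few spectral samples in the fit band")
        coeffs = np.polyfit(f_s[in_band], np.log10(sps[in_band]), 2)
        fitted = 10.0 ** np.polyval(coeffs, f_s[in_band])
        gap = fitted - rose_factor * nps_i[in_band]
        below = np.flatnonzero(gap <= 0)
        if len(below) == 0 or below[0] == 0:
            raise ValueError(f"no Rose-criterion crossing found in band for {name}")
        j = below[0]
        fb = f_s[in_band]
        # linear interpolation of the crossing between the bracketing samples
        f_c = fb[j - 1] + (fb[j] - fb[j - 1]) * gap[j - 1] / (gap[j - 1] - gap[j])
        out[f"f_c_{name}"] = float(f_c)
        out[f"res_{name}_um"] = half_period_resolution(float(f_c))
        out[f"sps_{name}"] = (f_s, sps)
        out[f"nps_{name}"] = (f_s, nps_i)
    return out


def dilation_sweep(pred: LabelVolume, truth: LabelVolume, max_steps: int = 10,
                   beta: float = 1.0) -> pd.DataFrame:
    """f score of ``pred`` against ``truth`` as pred is isotropically dilated.

    Utility for comparing a conservative annotation against a saturated one:
    sweeping dilation steps shows whether disagreement is a boundary
    (thickness) effect rather than missed objects.
    """
    from scipy import ndimage

    mask = np.asarray(pred.data) > 0
    rows = []
    struct = ndimage.generate_binary_structure(3, 3)
    for step in range(max_steps + 1):
        cur = mask if step == 0 else ndimage.binary_dilation(mask, struct, iterations=step)
        ev = pixel_eval(pred.with_data(cur.astype(np.int32)), truth, betas=(beta,))
        rows.append({"dilation_steps": step, "p": ev.p, "r": ev.r, "f": ev.f[beta]})
    return pd.DataFrame(rows)
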