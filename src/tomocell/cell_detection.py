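"""Greedy spherical-template cell detection on cell probability maps.

Most cortical somata are well approximated by spheres, so cell-like
neighbourhoods are scored by the mean cell probability inside a ball.
Detection proceeds as a matching-pursuit loop: correlate the probability
map with a unit-sum spherical template (via FFT), pick the global maximum
as the next centroid, zero the map inside a ball around it so the same cell
is not selected twice, and repeat until the best remaining correlation
drops below a stopping threshold or an iteration cap is reached.

After detection, per-cell size is estimated by growing the template at the
fixed centroid: the correlation stays flat while the ball remains inscribed
in the soma and drops sharply once it pokes out, so the diameter just before
the largest one-step drop is the size estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from tomocell.volume_io import DEFAULT_VOXEL_SIZE_UM

#: correlation values are rounded to this many decimals before each argmax,
#: so tie-breaking and the stopping test are identical whether the
#: correlation is maintained by full FFT recomputes or local updates
SCORE_DECIMALS = 10


@dataclass(frozen=True)
class SphericalTemplate:
    """Binary ball of a given voxel diameter, normalized to unit sum.

    A voxel offset belongs to the support iff its Euclidean distance from
    the centre voxel is at most ``diameter/2``.
    """

    diameter_vox: int
    weights: np.ndarray
    support_offsets: np.ndarray

    @property
    def radius_vox(self) -> float:
        return self.diameter_vox / 2.0

    @property
    def grid_radius(self) -> int:
        """Half-width of the cubic weight grid."""
        return (self.weights.shape[0] - 1) // 2


def make_template(diameter_vox: int) -> SphericalTemplate:
    """Build the unit-sum spherical template of a given voxel diameter."""
    diameter_vox = int(diameter_vox)
    if diameter_vox < 1:
        raise ValueError("diameter must be >= 1")
    r = diameter_vox / 2.0
    R = int(np.floor(r))
    ax = np.arange(-R, R + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = zz**2 + yy**2 + xx**2 <= r**2
    weights = inside.astype(np.float64)
    weights /= weights.sum()
    offsets = np.argwhere(inside) - R
    return SphericalTemplate(diameter_vox, weights, offsets)


@dataclass
class DetectionParams:
    """Tuning knobs of the greedy detector.

    ``cell_size_vox`` is the template diameter in voxels (default 18, i.e.
    11.7 µm at 0.65 µm voxels — a typical mouse soma). ``stop_threshold``
    compares against the raw template correlation, a mean probability in
    [0, 1]. ``zero_out_diameter_vox`` defaults to the template's own
    diameter. ``pre_threshold`` optionally zeroes probability below a cutoff
    before correlation.
    """

    cell_size_vox: int = 18
    stop_threshold: float = 0.47
    max_iterations: int = 10_000
    zero_out_diameter_vox: int | None = None
    pre_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.cell_size_vox < 1:
            raise ValueError("cell_size_vox must be >= 1")
        if not 0 < self.stop_threshold < 1:
            raise ValueError("stop_threshold must be in (0, 1)")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.zero_out_diameter_vox is None:
            self.zero_out_diameter_vox = self.cell_size_vox
        if self.zero_out_diameter_vox < 1:
            raise ValueError("zero_out_diameter_vox must be >= 1")


@dataclass
class CellDetection:
    """One detected cell: centroid, correlation score, optional size."""

    centroid_vox: tuple[int, int, int]
    centroid_um: np.ndarray
    score: float
    diameter_um: float | None = None
    edge: bool = False
    flags: list[str] = field(default_factory=list)

    def shifted(self, offset_vox, origin_um, voxel_size_um) -> "CellDetection":
        """Detection re-expressed in a parent volume's coordinate frame."""
        cz, cy, cx = (int(a + b) for a, b in zip(self.centroid_vox, offset_vox))
        return replace(
            self,
            centroid_vox=(cz, cy, cx),
            centroid_um=np.asarray(origin_um, float)
            + voxel_size_um * np.array([cz, cy, cx], float),
        )


def correlate(p_cell: np.ndarray, tmpl: SphericalTemplate) -> np.ndarray:
    """FFT correlation of a probability map with a spherical template.

    The value at each voxel is the template-weighted mean of the map over
    the ball centred there, with zero padding outside the volume; since the
    ball is symmetric, convolution and correlation coincide. Output is
    clipped to [0, 1] to absorb FFT round-off.
    """
    p_cell = np.asarray(p_cell)
    if any(w > n for w, n in zip(tmpl.weights.shape, p_cell.shape)):
        raise ValueError(
            f"template of grid shape {tmpl.weights.shape} larger than volume {p_cell.shape}"
        )
    out = fftconvolve(p_cell.astype(np.float64), tmpl.weights, mode="same")
    np.clip(out, 0.0, 1.0, out=out)
    return out


def _argmax_lex(arr: np.ndarray) -> tuple[int, int, int]:
    """Global argmax; exact ties break to the smallest (z, y, x) index.

    ``np.argmax`` already returns the first maximum in C order, which is
    lexicographically smallest.
    """
    return tuple(int(i) for i in np.unravel_index(int(np.argmax(arr)), arr.shape))


def detect_cells(
    p_cell: np.ndarray,
    params: DetectionParams | None = None,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
    origin_um=(0.0, 0.0, 0.0),
) -> list[CellDetection]:
    """Run the greedy matching-pursuit detector on a cell probability map.

    Each iteration takes the global correlation maximum as the next
    centroid, then zeroes the probability map in a ball of
    ``zero_out_diameter_vox`` around it and updates the correlation locally
    (numerically identical to a full recompute). Stops when the maximum
    falls below ``stop_threshold`` or after ``max_iterations`` detections.
    Detections whose centroid lies within a template radius of a volume
    face are flagged ``"edge"``.

    Returns detections in selection order; scores are non-increasing.
    """
    params = params or DetectionParams()
    p = np.asarray(p_cell, dtype=np.float64)
    if p.size == 0:
        return []
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probability map values must lie in [0, 1]")
    p = p.copy()
    if params.pre_threshold is not None:
        p[p < params.pre_threshold] = 0.0
    origin_um = np.asarray(origin_um, dtype=float)

    tmpl = make_template(params.cell_size_vox)
    zero_tmpl = make_template(params.zero_out_diameter_vox)
    corr = correlate(p, tmpl)

    detections: list[CellDetection] = []
    shape = np.array(p.shape)
    for _ in range(params.max_iterations):
        rounded = np.round(corr, SCORE_DECIMALS)
        idx = _argmax_lex(rounded)
        score = float(rounded[idx])
        if score < params.stop_threshold:
            break
        centroid = np.array(idx)
        edge = bool(
            (centroid < tmpl.radius_vox).any()
            or (shape - 1 - centroid < tmpl.radius_vox).any()
        )
        detections.append(
            CellDetection(
                centroid_vox=idx,
                centroid_um=origin_um + voxel_size_um * centroid.astype(float),
                score=score,
                edge=edge,
                flags=["edge"] if edge else [],
            )
        )
        _zero_out_and_update(p, corr, idx, zero_tmpl, tmpl)
    return detections


def _zero_out_and_update(
    p: np.ndarray,
    corr: np.ndarray,
    center: tuple[int, int, int],
    zero_tmpl: SphericalTemplate,
    tmpl: SphericalTemplate,
) -> None:
    """Zero p inside the zero-out ball and subtract its correlation locally.

    Removing probability mass inside the ball changes the correlation only
    within a window of (zero-out grid + template grid) around the centre, so
    the update convolves just the removed patch with the template.
    """
    Rz = zero_tmpl.grid_radius
    lo = [max(0, c - Rz) for c in center]
    hi = [min(n, c + Rz + 1) for c, n in zip(center, p.shape)]
    patch_slices = tuple(slice(l, h) for l, h in zip(lo, hi))
    ball = zero_tmpl.weights > 0
    ball_slices = tuple(
        slice(l - (c - Rz), (2 * Rz + 1) - ((c + Rz + 1) - h))
        for l, h, c in zip(lo, hi, center)
    )
    removed = np.zeros(tuple(h - l for l, h in zip(lo, hi)))
    local_ball = ball[ball_slices]
    patch = p[patch_slices]
    removed[local_ball] = patch[local_ball]
    patch[local_ball] = 0.0

    # corr contribution of the removed mass, full (linear) convolution
    delta = fftconvolve(removed, tmpl.weights, mode="full")
    Rt = tmpl.grid_radius
    dlo = [l - Rt for l in lo]
    dhi = [h + Rt for h in hi]
    src = tuple(
        slice(max(0, -dl), (dh - dl) - max(0, dh - n))
        for dl, dh, n in zip(dlo, dhi, corr.shape)
    )
    dst = tuple(
        slice(max(0, dl), min(n, dh)) for dl, dh, n in zip(dlo, dhi, corr.shape)
    )
    corr[dst] -= delta[src]
    np.clip(corr[dst], 0.0, 1.0, out=corr[dst])


def _ball_mean_at(
    p: np.ndarray, centroid: tuple[int, int, int], tmpl: SphericalTemplate
) -> tuple[float, bool]:
    """Template-weighted mean of p at a fixed centroid.

    If the ball extends outside the volume it is truncated and renormalized;
    the second return value reports whether truncation occurred.
    """
    offs = tmpl.support_offsets + np.asarray(centroid)
    inside = ((offs >= 0) & (offs < np.array(p.shape))).all(axis=1)
    truncated = not inside.all()
    offs = offs[inside]
    if len(offs) == 0:
        return 0.0, True
    return float(p[tuple(offs.T)].mean()), truncated


def estimate_cell_size(
    p_cell: np.ndarray,
    centroid_vox,
    d_min: int = 4,
    d_max: int = 24,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> tuple[float, list[str]]:
    """Estimate a cell's diameter by template growth at a fixed centroid.

    Computes the ball-mean correlation ``c(d)`` for template diameters
    ``d_min..d_max`` (1-voxel steps) and returns the diameter with the
    largest forward decrease ``c(d) - c(d+1)`` — the last size before the
    sharpest drop — in µm. Flags: ``"degenerate"`` when no real drop exists
    (e.g. constant probability), ``"truncated"`` when any ball left the
    volume and was renormalized.

    Returns (diameter_um, flags).
    """
    if not 0 < d_min < d_max:
        raise ValueError("need 0 < d_min < d_max")
    centroid = tuple(int(c) for c in centroid_vox)
    p = np.asarray(p_cell, dtype=np.float64)
    if any(not 0 <= c < n for c, n in zip(centroid, p.shape)):
        raise ValueError("centroid outside volume")
    flags: list[str] = []
    diams = np.arange(d_min, d_max + 1)
    c = np.empty(len(diams))
    any_trunc = False
    for i, d in enumerate(diams):
        c[i], trunc = _ball_mean_at(p, centroid, make_template(int(d)))
        any_trunc = any_trunc or trunc
    if any_trunc:
        flags.append("truncated")
    drops = c[:-1] - c[1:]
    if drops.max() <= 1e-12:
        flags.append("degenerate")
        return float(d_min) * voxel_size_um, flags
    d_star = diams[int(np.argmax(drops))]
    return float(d_star) * voxel_size_um, flags


def estimate_sizes(
    p_cell: np.ndarray,
    detections: list[CellDetection],
    d_min: int = 4,
    d_max: int = 24,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> list[CellDetection]:
    """Attach diameter estimates to each detection (in place; also returned)."""
    for det in detections:
        diameter_um, flags = estimate_cell_size(
            p_cell, det.centroid_vox, d_min, d_max, voxel_size_um
        )
        det.diameter_um = diameter_um
        det.flags.extend(f for f in flags if f not in det.flags)
    return detections
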