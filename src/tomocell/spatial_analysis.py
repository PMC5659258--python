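"""Spatial statistics of detected cells: kNN density and distance measures.

Cell density is estimated nonparametrically: the empirical probability of a
grid bin at centre v is proportional to ``k / (N * rho_k(v, V))`` where
``rho_k`` is the squared distance to the k-th nearest detected centroid.
Normalizing over bins gives a probability mass function p; per-bin density
in cells/mm³ follows as ``p_d(v) = p(v) * N / Vol * 1e9`` with Vol the bin
volume in µm³ (default 8.44, side ≈ 2.035 µm — roughly one cell per bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from tomocell.volume_io import LabelVolume

DEFAULT_BIN_VOLUME_UM3 = 8.44
DEFAULT_K = 5  # free parameter; the estimator only needs k << N


@dataclass
class CentroidSet:
    """N centroid positions in (z, y, x) µm with their bounding box."""

    positions_um: np.ndarray
    bounds_um: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        if pos.size == 0:
            pos = pos.reshape(0, 3)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        self.positions_um = pos
        if self.bounds_um is None:
            if len(pos):
                self.bounds_um = (pos.min(axis=0), pos.max(axis=0))
            else:
                self.bounds_um = (np.zeros(3), np.zeros(3))
        else:
            lo, hi = (np.asarray(b, float) for b in self.bounds_um)
            self.bounds_um = (lo, hi)
            if len(pos) and ((pos < lo - 1e-9).any() or (pos > hi + 1e-9).any()):
                raise ValueError("positions outside stated bounding box")

    def __len__(self) -> int:
        return len(self.positions_um)

    @classmethod
    def from_detections(cls, detections, bounds_um=None) -> "CentroidSet":
        pos = np.array([d.centroid_um for d in detections], dtype=float).reshape(-1, 3)
        return cls(pos, bounds_um)


@dataclass
class DensityField:
    """kNN density estimate on a regular 3D grid.

    ``p`` sums to 1 over bins; ``p_d`` is in cells/mm³ and satisfies the
    conservation identity ``sum(p_d) * Vol * 1e-9 == N``.
    """

    origin_um: np.ndarray
    grid_shape: tuple[int, int, int]
    bin_side_um: float
    p: np.ndarray
    p_d: np.ndarray
    k: int
    n_cells: int
    bin_volume_um3: float = field(init=False)

    def __post_init__(self) -> None:
        self.origin_um = np.asarray(self.origin_um, float)
        self.bin_volume_um3 = float(self.bin_side_um) ** 3

    def bin_centers(self) -> np.ndarray:
        """(M, 3) array of bin-centre coordinates in (z, y, x) µm."""
        axes = [
            self.origin_um[d] + self.bin_side_um * (np.arange(self.grid_shape[d]) + 0.5)
            for d in range(3)
        ]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        return np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)

    @property
    def mean_density(self) -> float:
        """Mean per-bin density over bins, cells/mm³."""
        return float(self.p_d.mean())


def knn_sq_distance(x, A: CentroidSet, k: int) -> float:
    """Squared Euclidean distance (µm²) from x to its k-th nearest point of A.

    If x coincides exactly with a point of A, that point is excluded.
    """
    pos = A.positions_um
    if k < 1 or k > len(pos):
        raise ValueError(f"k={k} out of range for N={len(pos)} points")
    x = np.asarray(x, dtype=float)
    tree = cKDTree(pos)
    d, _ = tree.query(x, k=min(k + 1, len(pos)))
    d = np.atleast_1d(d)
    if d[0] == 0.0:  # x is a member of A; skip the self match
        if k + 1 > len(pos):
            raise ValueError("k exceeds the number of other points")
        return float(d[k] ** 2)
    return float(d[k - 1] ** 2)


def estimate_density(
    cells: CentroidSet,
    bin_volume_um3: float = DEFAULT_BIN_VOLUME_UM3,
    k: int = DEFAULT_K,
    bounds_um=None,
    bin_side_um: float | None = None,
) -> DensityField:
    """kNN density estimate of a centroid set over a regular grid.

    The grid covers ``bounds_um`` (default: the set's bounding box) with
    cubic bins of side ``bin_side_um`` (default: cube root of
    ``bin_volume_um3``). The squared k-th-neighbour distance at each bin
    centre is clamped below at (half the bin side)² so a bin centre landing
    exactly on a centroid cannot absorb all probability mass.
    """
    n = len(cells)
    if n <= k:
        raise ValueError(f"need N > k (N={n}, k={k})")
    if bin_side_um is None:
        bin_side_um = float(bin_volume_um3) ** (1.0 / 3.0)
    if bounds_um is None:
        lo, hi = cells.bounds_um
    else:
        lo, hi = (np.asarray(b, float) for b in bounds_um)
    span = np.maximum(hi - lo, bin_side_um)
    grid_shape = tuple(int(np.ceil(s / bin_side_um)) for s in span)

    axes = [lo[d] + bin_side_um * (np.arange(grid_shape[d]) + 0.5) for d in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)

    tree = cKDTree(cells.positions_um)
    dist, _ = tree.query(centers, k=k)
    dk = dist[:, -1] if k > 1 else dist
    rho = np.maximum(dk**2, (bin_side_um / 2.0) ** 2)

    score = k / (n * rho)
    p = (score / score.sum()).reshape(grid_shape)
    vol = bin_side_um**3
    p_d = p * n / vol * 1e9
    return DensityField(
        origin_um=lo,
        grid_shape=grid_shape,
        bin_side_um=bin_side_um,
        p=p,
        p_d=p_d,
        k=k,
        n_cells=n,
    )


def cell_to_cell_distances(cells: CentroidSet) -> np.ndarray:
    """Nearest-neighbour distance (µm) from each cell to any other cell."""
    if len(cells) < 2:
        raise ValueError("need at least 2 cells")
    tree = cKDTree(cells.positions_um)
    d, _ = tree.query(cells.positions_um, k=2)
    return d[:, 1]


def cell_to_vessel_distances(cells: CentroidSet, vessels: LabelVolume) -> np.ndarray:
    """Distance (µm) from each centroid to the nearest vessel voxel centre.

    Computed via the Euclidean distance transform of the vessel mask's
    complement, sampled at each centroid's voxel with trilinear
    interpolation disabled (nearest voxel), then scaled by the voxel size.
    """
    mask = vessels.mask
    if not mask.any():
        raise ValueError("empty vessel mask")
    edt = ndimage.distance_transform_edt(~mask)
    idx = np.rint(
        (cells.positions_um - vessels.origin_um) / vessels.voxel_size_um
    ).astype(int)
    idx = np.clip(idx, 0, np.array(mask.shape) - 1)
    return edt[tuple(idx.T)] * vessels.voxel_size_um


def summarize_distances(
    distances, bin_width_um: float = 1.0
) -> tuple[float, float, float]:
    """Mean, sample SD and histogram mode of a distance sample.

    The mode is the centre of the tallest histogram bin at the stated bin
    width (bins anchored at 0). Returns (mean, sd, mode) in µm.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    n_bins = max(1, int(np.ceil((d.max() + 1e-9) / bin_width_um)))
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, n_bins * bin_width_um))
    mode = float((edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2.0)
    return mean, sd, mode
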