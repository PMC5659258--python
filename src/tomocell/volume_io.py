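"""Reading, writing and preprocessing of 3D image volumes.

Volumes are stored in (z, y, x) array order with 0-based voxel indices and
half-open extents. All physical quantities are micrometres; the physical
coordinate of voxel (i, j, k) is ``origin_um + voxel_size_um * (i, j, k)``.
The default voxel size is 0.65 µm isotropic, typical of synchrotron µCT of
resin-embedded brain tissue.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import h5py

DEFAULT_VOXEL_SIZE_UM = 0.65
DEFAULT_HDF5_DATASET = "exchange/data"

#: columns of a centroid table, in file order (x fastest axis)
CENTROID_COLUMNS = ["x_um", "y_um", "z_um", "diameter_um", "score"]


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with isotropic physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensity values in (z, y, x) order.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres.
    origin_um : ndarray, shape (3,)
        Physical position of voxel (0, 0, 0) in (z, y, x) µm.
    """

    data: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        if self.origin_um.shape != (3,):
            raise ValueError("origin_um must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_um(self, index) -> np.ndarray:
        """Physical (z, y, x) µm coordinate of a voxel index (broadcasts)."""
        return self.origin_um + self.voxel_size_um * np.asarray(index, dtype=float)

    def um_to_voxel(self, position_um) -> np.ndarray:
        """Nearest voxel index of a physical (z, y, x) µm position."""
        rel = (np.asarray(position_um, dtype=float) - self.origin_um) / self.voxel_size_um
        return np.rint(rel).astype(int)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Copy of this volume's geometry carrying new voxel data."""
        return dataclasses.replace(self, data=data)


@dataclass
class LabelVolume(ImageVolume):
    """Integer-labelled segmentation mask sharing ImageVolume geometry.

    Label 0 is background; positive labels identify objects. ``label_names``
    optionally maps label ids (or the whole class) to names.
    """

    label_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelVolume data must be integer-typed")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        return self.data > 0

    def matches_geometry(self, other: ImageVolume, atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_size_um - other.voxel_size_um) <= atol
            and np.allclose(self.origin_um, other.origin_um, atol=atol)
        )


@dataclass
class Block:
    """A padded block extracted from a larger volume.

    ``volume`` covers the core region plus up to ``pad`` voxels on each face
    (truncated at the parent volume's boundary). ``core_origin``/``core_shape``
    are global voxel coordinates of the core; ``pad_before``/``pad_after`` are
    the pads actually achieved per face.
    """

    volume: ImageVolume
    core_origin: tuple[int, int, int]
    core_shape: tuple[int, int, int]
    pad_before: tuple[int, int, int]
    pad_after: tuple[int, int, int]

    @property
    def core_slices_local(self) -> tuple[slice, ...]:
        """Slices selecting the core region inside the padded block array."""
        return tuple(
            slice(pb, pb + cs) for pb, cs in zip(self.pad_before, self.core_shape)
        )


def read_volume(
    path,
    format: str | None = None,
    dataset: str = DEFAULT_HDF5_DATASET,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
    origin_um=(0.0, 0.0, 0.0),
) -> ImageVolume:
    """Read a 3D volume from a multi-page TIFF stack or an HDF5 file.

    Slice order in the file becomes the z axis. ``format`` may be
    ``"tiff_stack"`` or ``"hdf5"``; when omitted it is inferred from the
    file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = _infer_format(path)
    if format == "tiff_stack":
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) > 1:
                raise ValueError(
                    f"inconsistent slice shapes in TIFF stack: {sorted(shapes)}"
                )
            data = tif.asarray()
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise KeyError(f"dataset {dataset!r} not found in {path}")
            data = f[dataset][()]
    else:
        raise ValueError(f"unknown format {format!r}")
    if data.ndim == 2:
        data = data[None]
    return ImageVolume(data, voxel_size_um=voxel_size_um, origin_um=np.asarray(origin_um, float))


def write_volume(vol: ImageVolume, path, format: str | None = None,
                 dataset: str = DEFAULT_HDF5_DATASET) -> None:
    """Write a volume as a multi-page TIFF stack or an HDF5 dataset."""
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format == "tiff_stack":
        tifffile.imwrite(path, np.asarray(vol.data))
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=np.asarray(vol.data))
            ds.attrs["voxel_size_um"] = vol.voxel_size_um
            ds.attrs["origin_um"] = vol.origin_um
    else:
        raise ValueError(f"unknown format {format!r}")


def read_label_volume(path, **kwargs) -> LabelVolume:
    """Read an integer label stack (TIFF/HDF5) as a LabelVolume."""
    vol = read_volume(path, **kwargs)
    data = np.asarray(vol.data)
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    return LabelVolume(data, voxel_size_um=vol.voxel_size_um, origin_um=vol.origin_um)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "tiff_stack"
    if suffix in {".h5", ".hdf5", ".hdf"}:
        return "hdf5"
    raise ValueError(f"cannot infer format from suffix {suffix!r}")


def to_uint8(vol: ImageVolume) -> ImageVolume:
    """Linearly rescale intensities onto [0, 255] and round to uint8.

    The global minimum maps to 0 and the global maximum to 255. A constant
    volume carries no contrast and maps to all zeros.
    """
    data = np.asarray(vol.data, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("volume contains NaN or Inf")
    lo, hi = data.min(), data.max()
    if hi == lo:
        out = np.zeros(data.shape, dtype=np.uint8)
    else:
        out = np.rint((data - lo) * (255.0 / (hi - lo))).astype(np.uint8)
    return vol.with_data(out)


def autocontrast(vol: ImageVolume, saturate_frac: float = 0.0035) -> ImageVolume:
    """Per-slice percentile contrast stretch to uint8.

    Each z slice is clipped at its (saturate_frac, 1 - saturate_frac)
    quantiles and the clipped range rescaled to [0, 255]. With
    ``saturate_frac=0`` this reduces to a per-slice linear min-max stretch.
    A fraction of ~0.35% per tail is the conventional autocontrast default.
    """
    if not 0 <= saturate_frac < 0.5:
        raise ValueError("saturate_frac must be in [0, 0.5)")
    data = np.asarray(vol.data, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("volume contains NaN or Inf")
    out = np.empty(data.shape, dtype=np.uint8)
    for i in range(data.shape[0]):
        sl = data[i]
        lo = np.quantile(sl, saturate_frac)
        hi = np.quantile(sl, 1.0 - saturate_frac)
        if hi == lo:
            out[i] = 0
        else:
            out[i] = np.rint(np.clip((sl - lo) * (255.0 / (hi - lo)), 0, 255)).astype(np.uint8)
    return vol.with_data(out)


def to_float(vol: ImageVolume) -> ImageVolume:
    """Normalize intensities to floats in [0, 1] (constant volumes map to 0)."""
    data = np.asarray(vol.data, dtype=np.float32)
    if not np.isfinite(data).all():
        raise ValueError("volume contains NaN or Inf")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return vol.with_data(np.zeros(data.shape, dtype=np.float32))
    return vol.with_data((data - lo) / (hi - lo))


def extract_block(vol: ImageVolume, core_origin, core_shape, pad: int) -> Block:
    """Extract a core region plus ``pad`` voxels of context on every face.

    Pads are truncated at the volume boundary; the achieved pad per face is
    recorded on the returned :class:`Block`. The block's ``origin_um``
    reflects its global position.
    """
    core_origin = tuple(int(c) for c in core_origin)
    core_shape = tuple(int(c) for c in core_shape)
    if pad < 0:
        raise ValueError("pad must be >= 0")
    for o, s, n in zip(core_origin, core_shape, vol.shape):
        if o < 0 or s < 1 or o + s > n:
            raise ValueError(
                f"core region origin={core_origin} shape={core_shape} "
                f"outside volume of shape {vol.shape}"
            )
    lo = tuple(max(0, o - pad) for o in core_origin)
    hi = tuple(min(n, o + s + pad) for o, s, n in zip(core_origin, core_shape, vol.shape))
    pad_before = tuple(o - l for o, l in zip(core_origin, lo))
    pad_after = tuple(h - (o + s) for h, o, s in zip(hi, core_origin, core_shape))
    data = vol.data[tuple(slice(l, h) for l, h in zip(lo, hi))]
    sub = ImageVolume(
        data,
        voxel_size_um=vol.voxel_size_um,
        origin_um=vol.voxel_to_um(lo),
    )
    return Block(sub, core_origin, core_shape, pad_before, pad_after)


def write_centroids(detections, path) -> None:
    """Write detections to a CSV centroid table (x_um,y_um,z_um,diameter_um,score).

    Accepts a list of :class:`~tomocell.cell_detection.CellDetection` or a
    DataFrame already in table form. An empty list yields a header-only file.
    """
    df = detections_to_dataframe(detections)
    df.to_csv(path, index=False, float_format="%.6g")


def detections_to_dataframe(detections) -> pd.DataFrame:
    if isinstance(detections, pd.DataFrame):
        return detections[CENTROID_COLUMNS]
    rows = []
    for d in detections:
        z, y, x = np.asarray(d.centroid_um, dtype=float)
        rows.append(
            {
                "x_um": x,
                "y_um": y,
                "z_um": z,
                "diameter_um": np.nan if d.diameter_um is None else d.diameter_um,
                "score": d.score,
            }
        )
    return pd.DataFrame(rows, columns=CENTROID_COLUMNS)


def read_centroids(path) -> pd.DataFrame:
    """Read a CSV centroid table, validating columns and numeric values."""
    df = pd.read_csv(path)
    missing = [c for c in CENTROID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"centroid table missing columns: {missing}")
    for col in CENTROID_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df[CENTROID_COLUMNS]
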