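"""Per-voxel classification into cell / vessel / background probability maps.

Multi-scale 3D image features (gradient-of-Gaussian magnitude, difference of
Gaussians, structure-tensor eigenvalues) feed a random-forest classifier
trained from sparse voxel annotations. Raw intensity is excluded from the
default feature set because absolute brightness drifts across large µCT
samples; it can be re-enabled with ``include_intensity=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from tomocell.volume_io import ImageVolume, LabelVolume

#: fixed class order; label encoding used everywhere in the package
CLASS_ORDER = ("cell", "vessel", "background", "axon")
CLASS_IDS = {name: i + 1 for i, name in enumerate(CLASS_ORDER)}

#: default Gaussian scales, µm (1–8 voxels at 0.65 µm): nucleus edge to soma
DEFAULT_SCALES_UM = (0.65, 1.3, 2.6, 5.2)

#: DoG outer/inner sigma ratio (standard scale-space choice)
DOG_RATIO = 1.6


@dataclass
class FeatureStack:
    """Per-voxel feature vectors for a source volume.

    ``features`` has shape (nz, ny, nx, n_features); ``feature_names`` pairs
    each channel with its (feature type, scale).
    """

    features: np.ndarray
    feature_names: list[str]
    scales_um: tuple[float, ...]
    voxel_size_um: float

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.features.shape[:3]

    @property
    def n_features(self) -> int:
        return self.features.shape[3]

    def flat(self) -> np.ndarray:
        return self.features.reshape(-1, self.n_features)


@dataclass
class SparseAnnotation:
    """Sparse training labels: voxel indices paired with class ids.

    ``indices`` is (N, 3) in (z, y, x); ``labels`` holds ids from
    :data:`CLASS_IDS` (1=cell, 2=vessel, 3=background, 4=axon).
    """

    indices: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.indices.ndim != 2 or self.indices.shape[1] != 3:
            raise ValueError("indices must be (N, 3)")
        if len(self.labels) != len(self.indices):
            raise ValueError("indices and labels length mismatch")

    def validate_against(self, shape: tuple[int, int, int]) -> None:
        if len(self.indices) and (
            (self.indices < 0).any() or (self.indices >= np.array(shape)).any()
        ):
            raise ValueError("annotation indices out of bounds")

    @classmethod
    def from_label_volumes(cls, class_masks: dict[str, LabelVolume],
                           max_per_class: int | None = None,
                           rng: np.random.Generator | None = None,
                           ) -> "SparseAnnotation":
        """Collect (index, label) pairs from per-class label volumes.

        Optionally subsamples each class to ``max_per_class`` voxels, which
        keeps forest training tractable on dense ground truth.
        """
        idx_parts, lab_parts = [], []
        for name, vol in class_masks.items():
            if name not in CLASS_IDS:
                raise ValueError(f"unknown class {name!r}")
            ij = np.argwhere(np.asarray(vol.data) > 0)
            if max_per_class is not None and len(ij) > max_per_class:
                if rng is None:
                    rng = np.random.default_rng(0)
                sel = rng.choice(len(ij), size=max_per_class, replace=False)
                ij = ij[np.sort(sel)]
            idx_parts.append(ij)
            lab_parts.append(np.full(len(ij), CLASS_IDS[name], dtype=int))
        if not idx_parts:
            return cls(np.empty((0, 3), dtype=int), np.empty(0, dtype=int))
        return cls(np.concatenate(idx_parts), np.concatenate(lab_parts))


@dataclass
class ProbabilityMaps:
    """Per-voxel class probabilities; sums to 1 at every voxel."""

    cell: np.ndarray
    vessel: np.ndarray
    background: np.ndarray
    axon: np.ndarray | None = None
    voxel_size_um: float = 0.65
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        shapes = {m.shape for m in self.maps().values()}
        if len(shapes) != 1:
            raise ValueError("probability maps must share one shape")

    def maps(self) -> dict[str, np.ndarray]:
        out = {"cell": self.cell, "vessel": self.vessel, "background": self.background}
        if self.axon is not None:
            out["axon"] = self.axon
        return out

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cell.shape

    def total(self) -> np.ndarray:
        return sum(self.maps().values())


@dataclass
class TrainedClassifier:
    """A fitted random forest plus the feature manifest it was trained with.

    Prediction refuses feature stacks whose manifest (names, scales, voxel
    size) differs from the training manifest, so serialized models stay
    portable across volumes but cannot silently be applied to mismatched
    feature configurations.
    """

    forest: RandomForestClassifier
    feature_names: list[str]
    scales_um: tuple[float, ...]
    voxel_size_um: float
    classes: tuple[str, ...]
    include_intensity: bool = False

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, TrainedClassifier):
            raise TypeError("file does not contain a TrainedClassifier")
        return obj


def _sigma_vox(scale_um: float, voxel_size_um: float) -> float:
    sigma = scale_um / voxel_size_um
    if sigma < 0.5:
        warnings.warn(
            f"scale {scale_um} µm is below half a voxel ({voxel_size_um} µm); "
            "features at this scale are noise-dominated",
            stacklevel=3,
        )
    return sigma


def compute_features(
    vol: ImageVolume,
    scales_um=DEFAULT_SCALES_UM,
    include_intensity: bool = False,
    dtype=np.float32,
) -> FeatureStack:
    """Compute the multi-scale 3D feature stack for voxel classification.

    Per scale sigma (in µm, converted to voxels): gradient-of-Gaussian
    magnitude; difference of Gaussians ``G_sigma - G_{1.6 sigma}``; and the
    three eigenvalues (sorted descending) of the structure tensor, i.e. the
    outer product of Gaussian gradients smoothed at ``2 sigma``. Boundaries
    are handled by reflection, which keeps block-wise feature computation
    consistent with in-place computation away from edges.
    """
    scales_um = tuple(float(s) for s in scales_um)
    if not scales_um or min(scales_um) <= 0:
        raise ValueError("scales_um must be non-empty and positive")
    data = np.asarray(vol.data, dtype=dtype)
    if min(data.shape) < 4:
        raise ValueError(f"volume of shape {data.shape} too thin for 3D features")

    channels: list[np.ndarray] = []
    names: list[str] = []
    if include_intensity:
        channels.append(data)
        names.append("intensity")
    for s in scales_um:
        sigma = _sigma_vox(s, vol.voxel_size_um)
        grads = [
            ndimage.gaussian_filter(data, sigma, order=tuple(int(a == ax) for a in range(3)),
                                    mode="reflect", output=dtype)
            for ax in range(3)
        ]
        gradmag = np.sqrt(grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2)
        channels.append(gradmag)
        names.append(f"gradient_magnitude@{s:g}um")

        smooth1 = ndimage.gaussian_filter(data, sigma, mode="reflect", output=dtype)
        smooth2 = ndimage.gaussian_filter(data, DOG_RATIO * sigma, mode="reflect", output=dtype)
        channels.append(smooth1 - smooth2)
        names.append(f"dog@{s:g}um")

        eigs = _structure_tensor_eigenvalues(grads, 2.0 * sigma, dtype)
        for rank in range(3):
            channels.append(eigs[..., rank])
            names.append(f"structure_tensor_eig{rank}@{s:g}um")

    features = np.stack(channels, axis=-1)
    return FeatureStack(features, names, scales_um, vol.voxel_size_um)


def _structure_tensor_eigenvalues(grads, smooth_sigma: float, dtype) -> np.ndarray:
    """Eigenvalues (descending) of the Gaussian-smoothed gradient outer product."""
    shape = grads[0].shape
    tensor = np.empty(shape + (3, 3), dtype=dtype)
    for a in range(3):
        for b in range(a, 3):
            prod = ndimage.gaussian_filter(grads[a] * grads[b], smooth_sigma,
                                           mode="reflect", output=dtype)
            tensor[..., a, b] = prod
            tensor[..., b, a] = prod
    eigs = np.linalg.eigvalsh(tensor)  # ascending
    return eigs[..., ::-1].astype(dtype)


def train_classifier(
    features: FeatureStack,
    labels: SparseAnnotation,
    n_trees: int = 100,
    seed: int | None = None,
    max_depth: int | None = None,
    n_jobs: int = 1,
) -> TrainedClassifier:
    """Fit a random forest on sparsely annotated voxels.

    ``seed`` is required for reproducible training; identical seeds yield
    identical forests and hence identical probability maps.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible training")
    labels.validate_against(features.spatial_shape)
    present = np.unique(labels.labels)
    if len(present) < 2:
        raise ValueError("need annotations from at least 2 classes")
    unknown = set(present) - set(CLASS_IDS.values())
    if unknown:
        raise ValueError(f"unknown label ids {sorted(unknown)}")
    X = features.features[tuple(labels.indices.T)]
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        random_state=int(seed),
        n_jobs=n_jobs,
    )
    forest.fit(X, labels.labels)
    classes = tuple(name for name in CLASS_ORDER if CLASS_IDS[name] in present)
    return TrainedClassifier(
        forest=forest,
        feature_names=list(features.feature_names),
        scales_um=features.scales_um,
        voxel_size_um=features.voxel_size_um,
        classes=classes,
        include_intensity="intensity" in features.feature_names,
    )


def predict_probabilities(
    clf: TrainedClassifier,
    vol: ImageVolume,
    features: FeatureStack | None = None,
    chunk_voxels: int = 4_000_000,
) -> ProbabilityMaps:
    """Apply a trained classifier, returning normalized probability maps.

    Features are recomputed from the volume with the classifier's manifest
    unless a matching precomputed stack is supplied. Prediction is chunked
    to bound peak memory on large volumes. Classes absent from training get
    all-zero maps, so per-voxel probabilities still sum to 1.
    """
    if features is None:
        features = compute_features(vol, clf.scales_um,
                                    include_intensity=clf.include_intensity)
    if features.feature_names != clf.feature_names:
        raise ValueError(
            "feature manifest mismatch between classifier and feature stack"
        )
    X = features.flat()
    proba = np.empty((X.shape[0], len(clf.forest.classes_)), dtype=np.float32)
    for start in range(0, X.shape[0], chunk_voxels):
        stop = min(start + chunk_voxels, X.shape[0])
        proba[start:stop] = clf.forest.predict_proba(X[start:stop])
    shape = features.spatial_shape

    by_name: dict[str, np.ndarray] = {}
    id_to_name = {v: k for k, v in CLASS_IDS.items()}
    for col, class_id in enumerate(clf.forest.classes_):
        by_name[id_to_name[int(class_id)]] = proba[:, col].reshape(shape)
    zeros = np.zeros(shape, dtype=np.float32)
    return ProbabilityMaps(
        cell=by_name.get("cell", zeros),
        vessel=by_name.get("vessel", zeros),
        background=by_name.get("background", zeros),
        axon=by_name.get("axon"),
        voxel_size_um=vol.voxel_size_um,
        origin_um=vol.origin_um,
    )
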