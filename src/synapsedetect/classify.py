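"""Random Forest voxel classification: sparse-label training, whole-volume
and blockwise probability-map prediction.

The classifier is trained on feature vectors at a handful of brush-stroke
labeled voxels (typically well under 1% of the volume) and applied to every
voxel, producing a per-class probability map.  The forest has two tunable
parameters — the number of trees and the number of features considered at
each split — and is robust to both; defaults are 100 trees and sqrt(38)≈6
features per split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureSpec, FeatureStack, compute_feature_stack
from .volume import SparseLabels, Volume3D

MODEL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    pass


class ChannelMismatchError(ValueError):
    pass


@dataclass
class ForestConfig:
    """Random Forest hyperparameters.

    ``mtry`` is the number of features considered per split; the string
    ``"sqrt"`` selects floor(sqrt(n_channels)).
    """

    n_trees: int = 100
    mtry: int | str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry != "sqrt" and (not isinstance(self.mtry, int) or self.mtry < 1):
            raise ValueError("mtry must be a positive integer or 'sqrt'")


@dataclass
class ProbabilityMap:
    """Per-voxel class distribution as a (class, z, y, x) array in [0, 1]."""

    data: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("probability map must be 4D (class, z, y, x)")
        if self.data.shape[0] != len(self.class_names):
            raise ValueError("class count does not match class_names")
        self.class_names = tuple(self.class_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def class_map(self, class_name: str) -> np.ndarray:
        if class_name not in self.class_names:
            raise ValueError(f"unknown class {class_name!r}; have {self.class_names}")
        return self.data[self.class_names.index(class_name)]


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata required for safe reuse."""

    forest: RandomForestClassifier
    class_names: tuple[str, ...]
    channel_names: list[str]
    metadata: dict = field(default_factory=dict)

    def feature_importances(self) -> dict[str, float]:
        """Gini importance per channel (diagnostic report only)."""
        return dict(zip(self.channel_names, map(float, self.forest.feature_importances_)))


def extract_training_matrix(stack: FeatureStack, labels: SparseLabels) -> tuple[np.ndarray, np.ndarray]:
    """Build the (n_samples, n_channels) training matrix and class vector.

    Duplicate identical labels are deduplicated (brush strokes overlap);
    the same voxel labeled with two different classes is an error.
    """
    labels.validate_against(stack.source_shape)
    if len(labels) == 0:
        raise TrainingError("no labeled voxels")
    key = np.ravel_multi_index(labels.coords.T, stack.source_shape)
    order = np.argsort(key, kind="stable")
    key_s, ids_s = key[order], labels.class_ids[order]
    keep = np.ones(len(key_s), dtype=bool)
    same = key_s[1:] == key_s[:-1]
    if same.any():
        conflict = same & (ids_s[1:] != ids_s[:-1])
        if conflict.any():
            z, y, x = np.unravel_index(key_s[1:][conflict][0], stack.source_shape)
            raise TrainingError(
                f"voxel ({z}, {y}, {x}) labeled with more than one class"
            )
        keep[1:] = ~same
    key_u, ids_u = key_s[keep], ids_s[keep]
    if len(np.unique(ids_u)) < 2:
        raise TrainingError("training requires labels in at least 2 classes")
    flat = stack.data.reshape(stack.n_channels, -1)
    X = flat[:, key_u].T.astype(np.float32)
    return X, ids_u


def _resolve_mtry(cfg: ForestConfig, n_channels: int) -> int:
    if cfg.mtry == "sqrt":
        return max(1, int(np.sqrt(n_channels)))
    if cfg.mtry > n_channels:
        raise ValueError(f"mtry={cfg.mtry} exceeds channel count {n_channels}")
    return cfg.mtry


def train(stack: FeatureStack, labels: SparseLabels, cfg: ForestConfig | None = None) -> TrainedModel:
    """Fit a Random Forest on the labeled voxels.

    Deterministic given the data and ``cfg.seed``.  The out-of-bag accuracy
    estimate is stored in the model metadata.
    """
    if cfg is None:
        cfg = ForestConfig()
    X, y = extract_training_matrix(stack, labels)
    mtry = _resolve_mtry(cfg, stack.n_channels)
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=mtry,
        random_state=cfg.seed,
        oob_score=True,
        bootstrap=True,
        n_jobs=1,
    )
    import warnings

    with warnings.catch_warnings():
        # tiny training sets can leave some samples never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        forest.fit(X, y)
        oob = float(forest.oob_score_)
    counts = {name: int((y == i).sum()) for i, name in enumerate(labels.class_names, start=1)}
    meta = {
        "oob_accuracy": oob,
        "label_counts": counts,
        "n_trees": cfg.n_trees,
        "mtry": mtry,
        "seed": cfg.seed,
        "n_training_samples": int(len(y)),
    }
    return TrainedModel(forest, labels.class_names, list(stack.channel_names), meta)


def predict(model: TrainedModel, stack: FeatureStack) -> ProbabilityMap:
    """Predict the per-voxel class distribution for a feature stack.

    Probabilities are averaged over trees and sum to 1 per voxel.  Classes
    absent from the training labels get probability 0 everywhere.
    """
    if list(stack.channel_names) != list(model.channel_names):
        raise ChannelMismatchError(
            "feature stack channels do not match the channels the model was trained on"
        )
    X = stack.as_matrix()
    probs = model.forest.predict_proba(X).astype(np.float32)
    n_classes = len(model.class_names)
    full = np.zeros((X.shape[0], n_classes), dtype=np.float32)
    for col, cls in enumerate(model.forest.classes_):
        full[:, int(cls) - 1] = probs[:, col]
    out = full.T.reshape((n_classes,) + tuple(stack.source_shape))
    return ProbabilityMap(out, model.class_names)


def predict_volume(model: TrainedModel, vol: Volume3D, spec: FeatureSpec) -> ProbabilityMap:
    """Compute features for a whole volume and predict in one pass."""
    return predict(model, compute_feature_stack(vol, spec))


def predict_blockwise(
    model: TrainedModel,
    vol: Volume3D,
    spec: FeatureSpec,
    block_shape: tuple[int, int, int] = (64, 128, 128),
) -> ProbabilityMap:
    """Blockwise prediction with a filter halo, for volumes whose feature
    stack would not fit in memory.

    Blocks overlap by the 4*max(sigma) kernel support so that features at
    block interiors are identical to the whole-volume computation; the
    result matches :func:`predict_volume` to within float rounding.
    """
    block_shape = tuple(int(b) for b in block_shape)
    if any(b < 1 for b in block_shape):
        raise ValueError("block_shape entries must be >= 1")
    halo = spec.halo_vox()
    shape = vol.shape
    n_classes = len(model.class_names)
    out = np.empty((n_classes,) + tuple(shape), dtype=np.float32)
    starts = [range(0, shape[d], block_shape[d]) for d in range(3)]
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                hi = (
                    min(z0 + block_shape[0], shape[0]),
                    min(y0 + block_shape[1], shape[1]),
                    min(x0 + block_shape[2], shape[2]),
                )
                lo_pad = (max(0, z0 - halo), max(0, y0 - halo), max(0, x0 - halo))
                hi_pad = (
                    min(shape[0], hi[0] + halo),
                    min(shape[1], hi[1] + halo),
                    min(shape[2], hi[2] + halo),
                )
                sub = Volume3D(
                    vol.data[lo_pad[0] : hi_pad[0], lo_pad[1] : hi_pad[1], lo_pad[2] : hi_pad[2]],
                    vol.spacing_nm,
                )
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pm = predict(model, compute_feature_stack(sub, spec))
                crop = (
                    slice(z0 - lo_pad[0], hi[0] - lo_pad[0]),
                    slice(y0 - lo_pad[1], hi[1] - lo_pad[1]),
                    slice(x0 - lo_pad[2], hi[2] - lo_pad[2]),
                )
                out[:, z0 : hi[0], y0 : hi[1], x0 : hi[2]] = pm.data[(slice(None),) + crop]
    return ProbabilityMap(out, model.class_names)


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model to a single file (versioned joblib archive)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "forest": model.forest,
        "class_names": tuple(model.class_names),
        "channel_names": list(model.channel_names),
        "metadata": dict(model.metadata),
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such model file: {path}")
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('format_version')}")
    return TrainedModel(
        payload["forest"], payload["class_names"], payload["channel_names"], payload["metadata"]
    )
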