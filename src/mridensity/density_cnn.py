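"""3D regression CNN for volumetric breast density.

Architecture: five strided convolutional layers (kernel 3x3x3, stride 2x2x2,
'same' padding, PReLU activations, 50% dropout), the filter count doubling
in the second and third layer and held constant after that, followed by two
fully connected layers of 128 units each and a linear scalar output.  The
model is trained with mean-absolute-error loss and Adam against the
ground-truth density percentage, with on-the-fly translation/rotation
augmentation, and the split over ranked ids keeps training, validation and
hold-out sets disjoint.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Adam, Conv3D, Dense, Dropout, Flatten, PReLU, Sequential
from .preprocess import NormalizationSpec
from .volume import Volume

__all__ = [
    "CNNConfig",
    "AugmentationSpec",
    "DatasetSplit",
    "TrainedModel",
    "build_model",
    "conv_output_sizes",
    "filter_schedule",
    "augment",
    "train",
    "predict",
    "make_split",
    "sample_search_space",
    "search_hyperparameters",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and optimization settings.

    ``input_shape`` is (128, 128, 128) in the production setting; the
    package's tested desk setting is (32, 32, 32).  ``base_filters`` and
    ``learning_rate`` span the hyperparameter search space (4..32 and
    1e-8..1e-2).
    """

    input_shape: tuple[int, int, int] = (32, 32, 32)
    base_filters: int = 8
    n_conv_layers: int = 5
    kernel: int = 3
    stride: int = 2
    dense_width: int = 128
    dense_layers: int = 2
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    # step decay: every `lr_decay_every` epochs the rate is multiplied by
    # `lr_decay_factor` (0 disables)
    lr_decay_every: int = 0
    lr_decay_factor: float = 0.5
    batch_size: int = 8
    epochs: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class AugmentationSpec:
    """Random rigid augmentation.

    Integer translations up to ``max_translation_voxels`` on the left-right
    and superior-inferior axes only (none anterior-posterior: the chest wall
    anchors that direction), and rotations up to ``max_rotation_deg`` about
    the sagittal (left-right) and transversal (superior-inferior) axes.
    Voxels exposed by the transform are filled with ``fill_value``.
    """

    max_translation_voxels: int = 20
    max_rotation_deg: float = 10.0
    fill_value: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split partitions must be pairwise disjoint")


@dataclass
class TrainedModel:
    """Weights + architecture + normalization provenance in one object."""

    network: Sequential
    config: CNNConfig
    history: pd.DataFrame
    normalization: NormalizationSpec | None = None


def conv_output_sizes(input_shape, n_layers: int, stride: int = 2):
    """Spatial size per axis after each stride-s 'same' convolution."""
    sizes = []
    dims = list(input_shape)
    for _ in range(n_layers):
        dims = [-(-d // stride) for d in dims]
        sizes.append(tuple(dims))
    return sizes


def filter_schedule(base_filters: int, n_layers: int) -> list[int]:
    """(f0, 2f0, 4f0, 4f0, ...): doubling in layers 2-3, constant after."""
    return [base_filters * min(2**i, 4) for i in range(n_layers)]


def build_model(config: CNNConfig) -> TrainedModel:
    """Assemble the (untrained) regression network for the given config."""
    min_dim = 2 ** (config.n_conv_layers - 1)
    for axis, d in enumerate(config.input_shape):
        if d < min_dim:
            raise ValueError(
                f"input dimension {d} on axis {axis} too small for "
                f"{config.n_conv_layers} stride-{config.stride} layers (need >= {min_dim})"
            )
    rng = np.random.default_rng(config.seed)
    filters = filter_schedule(config.base_filters, config.n_conv_layers)
    layers = []
    cin = 1
    for f in filters:
        layers.append(Conv3D(cin, f, kernel=config.kernel, stride=config.stride, rng=rng))
        layers.append(PReLU(f, channel_axis=1))
        layers.append(Dropout(config.dropout_rate))
        cin = f
    final_spatial = conv_output_sizes(config.input_shape, config.n_conv_layers, config.stride)[-1]
    flat = filters[-1] * int(np.prod(final_spatial))
    layers.append(Flatten())
    width_in = flat
    for _ in range(config.dense_layers):
        layers.append(Dense(width_in, config.dense_width, rng=rng))
        layers.append(PReLU(config.dense_width, channel_axis=1))
        layers.append(Dropout(config.dropout_rate))
        width_in = config.dense_width
    layers.append(Dense(width_in, 1, rng=rng))  # linear output head
    history = pd.DataFrame(columns=["epoch", "train_mae", "val_mae"])
    return TrainedModel(network=Sequential(layers), config=config, history=history)


# -- augmentation ---------------------------------------------------------

def draw_augmentation(spec: AugmentationSpec, rng: np.random.Generator) -> dict:
    """Sample one transform: integer LR/SI offsets, two rotation angles."""
    t = spec.max_translation_voxels
    return {
        "translation": (
            int(rng.integers(-t, t + 1)) if t > 0 else 0,
            0,  # anterior-posterior axis is never translated
            int(rng.integers(-t, t + 1)) if t > 0 else 0,
        ),
        "rot_sagittal_deg": float(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)),
        "rot_transversal_deg": float(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg)),
    }


def apply_augmentation(values: np.ndarray, params: dict, fill_value: float = 0.0) -> np.ndarray:
    """Rigid transform with linear interpolation.

    Rotation about axis 0 (sagittal) acts in the (AP, SI) plane, rotation
    about axis 2 (transversal) in the (LR, AP) plane; both about the volume
    center, followed by the integer translation.
    """
    th0 = np.deg2rad(params["rot_sagittal_deg"])
    th2 = np.deg2rad(params["rot_transversal_deg"])
    r0 = np.array([[1, 0, 0], [0, np.cos(th0), -np.sin(th0)], [0, np.sin(th0), np.cos(th0)]])
    r2 = np.array([[np.cos(th2), -np.sin(th2), 0], [np.sin(th2), np.cos(th2), 0], [0, 0, 1]])
    rot = r0 @ r2
    center = (np.asarray(values.shape) - 1) / 2.0
    t = np.asarray(params["translation"], dtype=float)
    matrix = rot.T  # output coord -> input coord
    offset = center - matrix @ (center + t)
    return ndimage.affine_transform(
        values, matrix, offset=offset, order=1, mode="constant", cval=fill_value
    )


def augment(volume: Volume, spec: AugmentationSpec, rng: np.random.Generator | None = None) -> Volume:
    """One random rigid augmentation of a model-input volume.

    The density label of an augmented volume is unchanged — the transform
    moves tissue, it does not create or destroy it (up to interpolation at
    the boundary).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    params = draw_augmentation(spec, rng)
    out = apply_augmentation(np.asarray(volume.values), params, spec.fill_value)
    return volume.with_values(out, f"augment:{params}")


# -- training -------------------------------------------------------------

def _forward_batch(network: Sequential, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
    return network.forward(x[:, None, :, :, :], training=training, rng=rng)[:, 0]


def _mae(pred, y) -> float:
    return float(np.mean(np.abs(pred - y)))


def train(
    volumes: dict[str, np.ndarray],
    labels: dict[str, float],
    split: DatasetSplit,
    config: CNNConfig,
    aug: AugmentationSpec | None = None,
    normalization: NormalizationSpec | None = None,
) -> TrainedModel:
    """Fit the density regressor by MAE/Adam with best-validation weights.

    ``volumes`` maps id -> preprocessed array of shape ``config.input_shape``
    and ``labels`` maps id -> density percent in [0, 100].  Training samples
    are augmented on the fly each epoch when ``aug`` is given; validation is
    never augmented.  The weights retained are those of the epoch with the
    lowest validation MAE.  Fully seeded: weight init, batch order, dropout
    and augmentation all derive from ``config.seed``.
    """
    if len(split.train_ids) == 0 or len(split.val_ids) == 0:
        raise ValueError("train and validation partitions must be nonempty")
    for pid in (*split.train_ids, *split.val_ids):
        if labels[pid] < 0 or labels[pid] > 100:
            raise ValueError(f"label for {pid} outside [0, 100]")
        if tuple(volumes[pid].shape) != tuple(config.input_shape):
            raise ValueError(
                f"volume {pid} has shape {volumes[pid].shape}, expected {config.input_shape}"
            )
    tm = build_model(config)
    net = tm.network
    opt = Adam(net, lr=config.learning_rate)
    master = np.random.SeedSequence([config.seed, 1])
    order_rng, drop_rng, aug_rng = (np.random.default_rng(s) for s in master.spawn(3))
    xval = np.stack([volumes[i] for i in split.val_ids])
    yval = np.asarray([labels[i] for i in split.val_ids], dtype=float)
    train_ids = list(split.train_ids)
    best_val, best_weights = np.inf, net.get_weights()
    rows = []
    for epoch in range(config.epochs):
        if (
            config.lr_decay_every > 0
            and epoch > 0
            and epoch % config.lr_decay_every == 0
        ):
            opt.lr *= config.lr_decay_factor
        order_rng.shuffle(train_ids)
        epoch_abs_err, n_seen = 0.0, 0
        for start in range(0, len(train_ids), config.batch_size):
            batch = train_ids[start : start + config.batch_size]
            if aug is not None:
                xb = np.stack([
                    apply_augmentation(volumes[i], draw_augmentation(aug, aug_rng), aug.fill_value)
                    for i in batch
                ])
            else:
                xb = np.stack([volumes[i] for i in batch])
            yb = np.asarray([labels[i] for i in batch], dtype=float)
            net.zero_grads()
            pred = _forward_batch(net, xb, training=True, rng=drop_rng)
            resid = pred - yb
            loss = float(np.mean(np.abs(resid)))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {start // config.batch_size}: "
                    f"predictions {pred}"
                )
            dpred = np.sign(resid) / len(batch)
            net.backward(dpred[:, None])
            opt.step()
            epoch_abs_err += loss * len(batch)
            n_seen += len(batch)
        val_pred = _forward_batch(net, xval, training=False)
        val_mae = _mae(val_pred, yval)
        rows.append({"epoch": epoch, "train_mae": epoch_abs_err / n_seen, "val_mae": val_mae})
        if val_mae < best_val:
            best_val = val_mae
            best_weights = net.get_weights()
    net.set_weights(best_weights)
    tm.history = pd.DataFrame(rows)
    tm.normalization = normalization
    return tm


def predict(model: TrainedModel, volume: Volume | np.ndarray, clamp: bool = False) -> float:
    """Estimated density percent for one preprocessed volume.

    Inference is deterministic (dropout off).  The raw regression output is
    returned; ``clamp=True`` clips it to [0, 100].
    """
    values = np.asarray(volume.values if isinstance(volume, Volume) else volume)
    if tuple(values.shape) != tuple(model.config.input_shape):
        raise ValueError(
            f"volume shape {tuple(values.shape)} does not match model input "
            f"{tuple(model.config.input_shape)}"
        )
    out = float(_forward_batch(model.network, values[None], training=False)[0])
    return float(np.clip(out, 0.0, 100.0)) if clamp else out


def make_split(ids, sizes: tuple[int, int, int]) -> DatasetSplit:
    """Split on ranked id: first block train, then validation, then test."""
    ranked = sorted(ids)
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test != len(ranked):
        raise ValueError(
            f"split sizes {sizes} sum to {n_train + n_val + n_test}, cohort has {len(ranked)}"
        )
    return DatasetSplit(
        train_ids=tuple(ranked[:n_train]),
        val_ids=tuple(ranked[n_train : n_train + n_val]),
        test_ids=tuple(ranked[n_train + n_val :]),
    )


# -- hyperparameter search ------------------------------------------------

def sample_search_space(rng: np.random.Generator) -> dict:
    """One draw from the search space: f0 uniform in {4..32}, lr log-uniform
    in [1e-8, 1e-2]."""
    return {
        "base_filters": int(rng.integers(4, 33)),
        "learning_rate": float(10.0 ** rng.uniform(-8.0, -2.0)),
    }


def search_hyperparameters(
    volumes: dict[str, np.ndarray],
    labels: dict[str, float],
    split: DatasetSplit,
    base_config: CNNConfig,
    budget: int,
    seed: int,
    aug: AugmentationSpec | None = None,
):
    """Seeded random search; returns (best config, trials table).

    Each trial trains with the sampled base_filters/learning_rate and is
    scored by its best validation MAE; ties are broken toward the
    first-sampled trial (strict improvement required).
    """
    if budget < 1:
        raise ValueError("search budget must be >= 1")
    rng = np.random.default_rng(seed)
    best_config, best_val = None, np.inf
    rows = []
    for trial in range(budget):
        draw = sample_search_space(rng)
        cfg = replace(base_config, **draw)
        tm = train(volumes, labels, split, cfg, aug=aug)
        val = float(tm.history["val_mae"].min())
        rows.append({"trial": trial, **draw, "val_mae": val})
        if val < best_val:
            best_val, best_config = val, cfg
    return best_config, pd.DataFrame(rows)


# -- checkpointing --------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    """Single-file checkpoint: weights + config + normalization + history."""
    arrays = {}
    for (li, name), p, _ in model.network.parameters():
        arrays[f"layer{li}__{name}"] = p
    meta = {
        "config": asdict(model.config),
        "normalization": asdict(model.normalization) if model.normalization else None,
        "history_csv": model.history.to_csv(index=False),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> TrainedModel:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_dict = meta["config"]
    cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
    config = CNNConfig(**cfg_dict)
    tm = build_model(config)
    for (li, name), p, _ in tm.network.parameters():
        p[...] = data[f"layer{li}__{name}"]
    tm.history = pd.read_csv(io.StringIO(meta["history_csv"])) if meta["history_csv"].strip() else pd.DataFrame()
    if meta["normalization"]:
        tm.normalization = NormalizationSpec(**meta["normalization"])
    return tm
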