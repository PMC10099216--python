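"""First-level CNN assessors: spectrogram image → class-probability vector.

Each assessor handles one (modality, task) pair — e.g. the EEG
sleep-stage classifier — and is trained from scratch with plain SGD on
cross-entropy.  Two backbones are provided:

* ``vgg16``: the classic 13-convolution / 3-fully-connected stack with
  ReLU activations and a softmax head, the fidelity configuration;
* ``small_test``: a 3-convolution reduction with the identical I/O
  contract, sized so the whole system trains on one CPU in minutes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nets
from .labels import task_classes, validate_modality
from .preprocessing import SpectrogramImage

__all__ = [
    "CnnConfig",
    "ProbabilityVector",
    "CnnModel",
    "build_cnn",
    "train_classifier",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]

# VGG16 convolutional plan: channel width per conv layer, "P" = 2x2 max-pool.
_VGG16_PLAN = [64, 64, "P", 128, 128, "P", 256, 256, 256, "P",
               512, 512, 512, "P", 512, 512, 512, "P"]


@dataclass(frozen=True)
class CnnConfig:
    architecture: str = "small_test"
    n_classes: int = 6
    input_size: int = 64
    learning_rate: float = 0.001
    batch_size: int = 10
    max_epochs: int = 100
    early_stopping_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("vgg16", "small_test"):
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                "expected 'vgg16' or 'small_test'"
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass(frozen=True)
class ProbabilityVector:
    """One assessor's softmax output for one window, with provenance and truth."""

    classifier_id: str
    task: str
    modality: str
    probs: np.ndarray
    record_id: str
    epoch_index: int
    offset_s: float
    stage: str
    disorder: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be non-negative and sum to 1 (±1e-6)")
        object.__setattr__(self, "probs", p)

    @property
    def key(self) -> tuple[str, int, float]:
        return (self.record_id, self.epoch_index, self.offset_s)


class CnnModel:
    """A backbone network plus its task/modality identity and training state."""

    def __init__(self, cfg: CnnConfig, task: str, modality: str):
        self.cfg = cfg
        self.task = task
        self.modality = validate_modality(modality)
        self.classes = task_classes(task)
        if cfg.n_classes != len(self.classes):
            raise ValueError(
                f"task {task!r} has {len(self.classes)} classes but config asks "
                f"for {cfg.n_classes}"
            )
        self.net = _build_backbone(cfg)
        self.trained = False
        self.history: nets.TrainingHistory | None = None

    @property
    def classifier_id(self) -> str:
        return f"{self.task}-{self.modality}"

    def layer_census(self) -> dict[str, int]:
        return self.net.layer_census()


def _build_backbone(cfg: CnnConfig) -> nets.Sequential:
    rng = np.random.default_rng(cfg.seed)
    layers: list[nets.Layer] = []
    size = cfg.input_size
    if cfg.architecture == "vgg16":
        c_in = 3
        for item in _VGG16_PLAN:
            if item == "P":
                layers.append(nets.MaxPool2D(2))
                size //= 2
            else:
                layers.append(nets.Conv2D(c_in, int(item), 3, rng))
                layers.append(nets.ReLU())
                c_in = int(item)
        layers.append(nets.Flatten())
        layers.append(nets.Dense(c_in * size * size, 4096, rng))
        layers.append(nets.ReLU())
        layers.append(nets.Dense(4096, 4096, rng))
        layers.append(nets.ReLU())
        layers.append(nets.Dense(4096, cfg.n_classes, rng))
    else:  # small_test: 3 conv + 2 dense, same I/O contract
        plan = [(3, 8, 4), (8, 16, 2), (16, 32, 2)]
        for c_in, c_out, pool in plan:
            layers.append(nets.Conv2D(c_in, c_out, 3, rng))
            layers.append(nets.ReLU())
            layers.append(nets.MaxPool2D(pool))
            size //= pool
        layers.append(nets.Flatten())
        layers.append(nets.Dense(32 * size * size, 64, rng))
        layers.append(nets.ReLU())
        layers.append(nets.Dense(64, cfg.n_classes, rng))
    return nets.Sequential(layers)


def build_cnn(cfg: CnnConfig, task: str = "stage", modality: str = "EEG") -> CnnModel:
    """Construct an untrained assessor for a (task, modality) pair."""
    return CnnModel(cfg, task, modality)


def _images_to_arrays(
    model: CnnModel, images: list[SpectrogramImage]
) -> tuple[np.ndarray, np.ndarray]:
    label_index = {c: i for i, c in enumerate(model.classes)}
    x = np.empty((len(images), 3, model.cfg.input_size, model.cfg.input_size),
                 dtype=np.float32)
    y = np.empty(len(images), dtype=np.int64)
    for i, img in enumerate(images):
        if img.pixels.shape[:2] != (model.cfg.input_size, model.cfg.input_size):
            raise ValueError(
                f"image {img.key} has size {img.pixels.shape[:2]}, model expects "
                f"{model.cfg.input_size}"
            )
        x[i] = (img.pixels.astype(np.float32) / 255.0 - 0.5).transpose(2, 0, 1)
        label = img.stage if model.task == "stage" else img.disorder
        if label not in label_index:
            raise ValueError(
                f"image {img.key} carries label {label!r} outside the "
                f"{model.task} class set {model.classes}"
            )
        y[i] = label_index[label]
    return x, y


def train_classifier(
    model: CnnModel,
    train_images: list[SpectrogramImage],
    val_images: list[SpectrogramImage],
    cfg: CnnConfig | None = None,
) -> tuple[CnnModel, nets.TrainingHistory]:
    """SGD training on cross-entropy with validation-loss early stopping."""
    cfg = cfg or model.cfg
    train_keys = {img.key for img in train_images}
    if train_keys & {img.key for img in val_images}:
        raise ValueError("train and validation image sets overlap")
    x_tr, y_tr = _images_to_arrays(model, train_images)
    x_va, y_va = _images_to_arrays(model, val_images)
    rng = np.random.default_rng(cfg.seed + 1)
    history = nets.train_network(
        model.net, x_tr, y_tr, x_va, y_va,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.early_stopping_patience,
        rng=rng,
    )
    model.trained = True
    model.history = history
    return model, history


def predict_proba(
    model: CnnModel, images: list[SpectrogramImage]
) -> list[ProbabilityVector]:
    """One probability vector per image, in input order, provenance copied."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    x, _ = _images_to_arrays(model, images)
    probs = model.net.predict_proba(x)
    # renormalise away float32 round-off so downstream invariants hold exactly
    probs = probs / probs.sum(axis=1, keepdims=True)
    return [
        ProbabilityVector(
            classifier_id=model.classifier_id,
            task=model.task,
            modality=model.modality,
            probs=probs[i],
            record_id=img.record_id,
            epoch_index=img.epoch_index,
            offset_s=img.offset_s,
            stage=img.stage,
            disorder=img.disorder,
        )
        for i, img in enumerate(images)
    ]


def save_checkpoint(model: CnnModel, path: str | Path) -> Path:
    """Persist weights plus config/seed/identity as a .npz checkpoint."""
    path = Path(path)
    meta = {"cfg": asdict(model.cfg), "task": model.task, "modality": model.modality,
            "trained": model.trained}
    weights = model.net.get_weights()
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )
    return path


def load_checkpoint(path: str | Path) -> CnnModel:
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    model = CnnModel(CnnConfig(**meta["cfg"]), meta["task"], meta["modality"])
    weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    model.net.set_weights(weights)
    model.trained = bool(meta["trained"])
    return model
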