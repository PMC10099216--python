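"""Decision-level fusion of the first-level assessors.

Per-classifier probability vectors are aligned on their window key
(record, epoch, offset), concatenated classifier-by-classifier into one
feature vector (classifier outer, class inner), and arbitrated either by
a shallow fully connected network (input → 128 → 128 → K, ReLU hidden,
softmax output) or by one of three classical rules:

* **maximum probability (MP)** — the class holding the single largest
  entry across all classifiers;
* **majority vote (MV)** — each classifier votes its argmax, strict
  plurality wins; when all votes differ, fall back to MP; when several
  classes tie for the top vote count, MP restricted to the tied classes;
* **average probability (AP)** — argmax of the element-wise mean vector.

All exact ties resolve toward the lowest class index, so every rule is
deterministic.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nets
from .classifiers import ProbabilityVector

__all__ = [
    "AlignedRow",
    "ConcatenatedFeature",
    "DecisionNnConfig",
    "DecisionNn",
    "align_multimodal",
    "concatenate_probabilities",
    "decide_max_probability",
    "decide_majority_vote",
    "decide_average_probability",
    "train_decision_nn",
    "decide_nn",
    "save_nn_checkpoint",
    "load_nn_weights",
]


@dataclass(frozen=True)
class AlignedRow:
    """One window evaluated by every contributing classifier, plus ground truth."""

    key: tuple[str, int, float]
    vectors: dict[str, ProbabilityVector]
    stage: str
    disorder: str


@dataclass(frozen=True)
class ConcatenatedFeature:
    """The concatenated probability feature: classifier-major, class-minor order."""

    values: np.ndarray
    blocks: tuple[tuple[str, int], ...]  # (classifier_id, K) in concatenation order
    key: tuple[str, int, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size != sum(k for _, k in self.blocks):
            raise ValueError("feature length does not match block sizes")
        pos = 0
        for cid, k in self.blocks:
            if abs(v[pos : pos + k].sum() - 1.0) > 1e-6:
                raise ValueError(f"block {cid!r} does not sum to 1 (±1e-6)")
            pos += k
        object.__setattr__(self, "values", v)


def align_multimodal(
    prob_sets: dict[str, list[ProbabilityVector]],
    seed: int = 0,
    max_rows: int | None = None,
) -> list[AlignedRow]:
    """Inner-join per-classifier vectors on window keys.

    Only windows evaluated by *all* classifiers survive; when classifier
    counts differ the join equalises them, and ``max_rows`` applies an
    additional seeded subsample.  Rows come back in sorted key order.
    """
    if not prob_sets:
        raise ValueError("no probability sets supplied")
    keyed = {
        cid: {v.key: v for v in vectors} for cid, vectors in prob_sets.items()
    }
    common: set | None = None
    for keys in (set(d) for d in keyed.values()):
        common = keys if common is None else common & keys
    if not common:
        for cid, d in keyed.items():
            others = set().union(*(set(o) for c, o in keyed.items() if c != cid))
            if others and not set(d) & others:
                raise ValueError(
                    f"classifier {cid!r} shares no window keys with the others"
                )
        raise ValueError("window-key intersection across classifiers is empty")
    keys = sorted(common)
    if max_rows is not None and len(keys) > max_rows:
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(keys), size=max_rows, replace=False)
        keys = [keys[i] for i in sorted(picked)]
    rows = []
    for key in keys:
        vectors = {cid: keyed[cid][key] for cid in keyed}
        first = next(iter(vectors.values()))
        for v in vectors.values():
            if (v.stage, v.disorder) != (first.stage, first.disorder):
                raise ValueError(f"inconsistent ground-truth labels at key {key}")
        rows.append(
            AlignedRow(key=key, vectors=vectors, stage=first.stage,
                       disorder=first.disorder)
        )
    return rows


def concatenate_probabilities(
    row: AlignedRow, order: list[str]
) -> ConcatenatedFeature:
    """Concatenate a row's vectors in the given fixed classifier order."""
    missing = [cid for cid in order if cid not in row.vectors]
    if missing:
        raise KeyError(
            f"classifier(s) {missing} absent from aligned row; present: "
            f"{sorted(row.vectors)}"
        )
    parts = [row.vectors[cid].probs for cid in order]
    blocks = tuple((cid, p.size) for cid, p in zip(order, parts))
    return ConcatenatedFeature(
        values=np.concatenate(parts), blocks=blocks, key=row.key
    )


def _stack(vectors: list[np.ndarray]) -> np.ndarray:
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    sizes = {a.size for a in arrs}
    if len(sizes) != 1:
        raise ValueError(f"probability vectors have unequal lengths: {sorted(sizes)}")
    return np.stack(arrs)


def decide_max_probability(vectors: list[np.ndarray]) -> int:
    """Class index of the single largest probability across all classifiers."""
    p = _stack(vectors)
    return int(np.argmax(p.max(axis=0)))  # first max -> lowest class index on ties


def decide_majority_vote(vectors: list[np.ndarray]) -> int:
    """Plurality vote over per-classifier argmaxes with MP tie handling."""
    p = _stack(vectors)
    votes = [int(np.argmax(row)) for row in p]
    counts = Counter(votes)
    top = max(counts.values())
    if top == 1:  # all assessors disagree -> maximum-probability fallback
        return decide_max_probability(vectors)
    tied = sorted(c for c, n in counts.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    scores = p.max(axis=0)  # MP restricted to the tied classes
    best = max(tied, key=lambda c: (scores[c], -c))
    return int(best)


def decide_average_probability(vectors: list[np.ndarray]) -> int:
    """Argmax of the element-wise mean probability vector."""
    p = _stack(vectors)
    return int(np.argmax(p.mean(axis=0)))


@dataclass(frozen=True)
class DecisionNnConfig:
    input_dim: int
    output_dim: int
    hidden_layers: int = 2
    hidden_width: int = 128
    learning_rate: float = 0.001
    batch_size: int = 3
    max_epochs: int = 10
    early_stopping_patience: int = 2
    init: str = "scratch"  # or a checkpoint path
    seed: int = 0


class DecisionNn:
    """Shallow arbitration network with recorded config and widths."""

    def __init__(self, cfg: DecisionNnConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = [cfg.input_dim] + [cfg.hidden_width] * cfg.hidden_layers + [
            cfg.output_dim
        ]
        layers: list[nets.Layer] = []
        for i in range(len(dims) - 1):
            layers.append(nets.Dense(dims[i], dims[i + 1], rng))
            if i < len(dims) - 2:
                layers.append(nets.ReLU())
        self.net = nets.Sequential(layers)
        self.widths = dims
        if cfg.init != "scratch":
            self.net.set_weights(load_nn_weights(cfg.init))
        self.trained = False
        self.history: nets.TrainingHistory | None = None


def _features_to_arrays(
    features: list[ConcatenatedFeature], labels: list[int], input_dim: int
) -> tuple[np.ndarray, np.ndarray]:
    if len(features) != len(labels):
        raise ValueError("features and labels differ in length")
    x = np.empty((len(features), input_dim), dtype=np.float32)
    for i, f in enumerate(features):
        if f.values.size != input_dim:
            raise ValueError(
                f"feature {f.key} has length {f.values.size}, NN expects {input_dim}"
            )
        x[i] = f.values
    return x, np.asarray(labels, dtype=np.int64)


def train_decision_nn(
    features: list[ConcatenatedFeature],
    labels: list[int],
    cfg: DecisionNnConfig,
    val_features: list[ConcatenatedFeature] | None = None,
    val_labels: list[int] | None = None,
) -> tuple[DecisionNn, nets.TrainingHistory]:
    """SGD training of the arbitration NN on cross-entropy.

    If no validation split is supplied, a seeded 10% holdout monitors
    early stopping.
    """
    if any(not 0 <= y < cfg.output_dim for y in labels):
        raise ValueError(f"labels must lie in [0, {cfg.output_dim})")
    x, y = _features_to_arrays(features, list(labels), cfg.input_dim)
    if val_features is None:
        rng = np.random.default_rng(cfg.seed + 7)
        order = rng.permutation(len(x))
        n_val = max(1, len(x) // 10)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        x_tr, y_tr, x_va, y_va = x[tr_idx], y[tr_idx], x[val_idx], y[val_idx]
    else:
        x_tr, y_tr = x, y
        x_va, y_va = _features_to_arrays(val_features, list(val_labels), cfg.input_dim)
    nn = DecisionNn(cfg)
    history = nets.train_network(
        nn.net, x_tr, y_tr, x_va, y_va,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.early_stopping_patience,
        rng=np.random.default_rng(cfg.seed + 13),
    )
    nn.trained = True
    nn.history = history
    return nn, history


def decide_nn(nn: DecisionNn, feature: ConcatenatedFeature) -> tuple[int, np.ndarray]:
    """Final label index and softmax probability vector for one feature."""
    if feature.values.size != nn.cfg.input_dim:
        raise ValueError(
            f"feature length {feature.values.size} does not match NN input "
            f"{nn.cfg.input_dim}"
        )
    probs = nn.net.predict_proba(feature.values[None, :].astype(np.float32))[0]
    probs = probs / probs.sum()
    return int(np.argmax(probs)), probs


def predict_nn_batch(nn: DecisionNn, features: list[ConcatenatedFeature]) -> np.ndarray:
    """Vectorised label prediction for many features (row per feature)."""
    x = np.stack([f.values for f in features]).astype(np.float32)
    if x.shape[1] != nn.cfg.input_dim:
        raise ValueError("feature length does not match NN input dimension")
    return np.argmax(nn.net.predict_proba(x), axis=1)


def save_nn_checkpoint(nn: DecisionNn, path: str | Path) -> Path:
    path = Path(path)
    meta = {"widths": nn.widths}
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"w{i}": w for i, w in enumerate(nn.net.get_weights())},
    )
    return path


def load_nn_weights(path: str | Path) -> list[np.ndarray]:
    data = np.load(path)
    return [data[f"w{i}"] for i in range(len(data.files) - 1)]
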