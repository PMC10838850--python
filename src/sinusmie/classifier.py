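"""3D convolutional sinus classifiers: configuration, training, inference.

The training protocol mirrors the study design: Adam, batch size 16,
learning rate 1e-4, up to 100 epochs, and a reduce-on-plateau schedule that
divides the learning rate by 10 whenever the validation loss fails to
improve for 5 consecutive epochs.  The checkpoint with the best validation
loss is returned.

Three architecture families are provided, all built from the same numpy
layer primitives and all operating on 64^3 instances through a fixed
stride-4 average-pooling stem (so the trainable network sees 16^3):

* ``tiny3d`` — two conv/pool stages, global average pooling, 2-way head.
* ``resnet3d`` — the tiny stem followed by residual blocks; the published
  depths (18/50/101/152/200) map to progressively more blocks at reduced
  width, keeping CPU training tractable.
* ``densenet3d`` — densely connected blocks, depths 121/169/201/264 mapped
  the same way.

Inputs are min-max normalized to [0, 1] per instance before the network.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from . import layers as L
from .sampling import MODEL_INPUT_SIZE, SinusInstance

STEM_POOL = 4   # 64^3 -> 16^3 fixed average-pool stem

RESNET_DEPTHS = {18: 2, 50: 3, 101: 4, 152: 5, 200: 6}     # depth -> blocks
DENSENET_DEPTHS = {121: 2, 169: 3, 201: 4, 264: 5}         # depth -> layers


@dataclass(frozen=True)
class ClassifierConfig:
    family: str = "tiny3d"          # tiny3d | resnet3d | densenet3d
    depth: int | None = None
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-4
    plateau_patience: int = 5
    plateau_factor: float = 10.0    # lr <- lr / factor
    min_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("tiny3d", "resnet3d", "densenet3d"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "resnet3d" and self.depth not in RESNET_DEPTHS:
            raise ValueError(f"resnet3d depth must be one of {sorted(RESNET_DEPTHS)}")
        if self.family == "densenet3d" and self.depth not in DENSENET_DEPTHS:
            raise ValueError(f"densenet3d depth must be one of {sorted(DENSENET_DEPTHS)}")
        for name in ("epochs", "batch_size", "plateau_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0 or self.plateau_factor <= 1:
            raise ValueError("learning_rate > 0 and plateau_factor > 1 required")


def build_network(config: ClassifierConfig) -> L.Sequential:
    """Trainable part of the network (applied after the pooling stem)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0]))
    if config.family == "tiny3d":
        net = [L.Conv3d(1, 8, rng=rng), L.ReLU(), L.MaxPool3d(2),
               L.Conv3d(8, 16, rng=rng), L.ReLU(), L.MaxPool3d(2),
               L.GlobalAvgPool(), L.Linear(16, 2, rng=rng)]
    elif config.family == "resnet3d":
        blocks = RESNET_DEPTHS[config.depth]
        net = [L.Conv3d(1, 8, rng=rng), L.ReLU(), L.MaxPool3d(2)]
        net += [L.ResidualBlock(L.Sequential(
            [L.Conv3d(8, 8, rng=rng), L.ReLU(), L.Conv3d(8, 8, rng=rng)]))
            for _ in range(blocks)]
        net += [L.MaxPool3d(2), L.Conv3d(8, 16, rng=rng), L.ReLU(),
                L.GlobalAvgPool(), L.Linear(16, 2, rng=rng)]
    else:  # densenet3d
        n_layers = DENSENET_DEPTHS[config.depth]
        net = [L.Conv3d(1, 8, rng=rng), L.ReLU(), L.MaxPool3d(2)]
        block = L.DenseBlock(8, n_layers=n_layers, growth=8, rng=rng)
        net += [block, L.ReLU(), L.MaxPool3d(2),
                L.Conv3d(block.c_out, 16, k=1, rng=rng), L.ReLU(),
                L.GlobalAvgPool(), L.Linear(16, 2, rng=rng)]
    return L.Sequential(net)


class ReduceLROnPlateau:
    """Divide lr by ``factor`` after ``patience`` epochs without validation
    improvement (strict improvement beyond ``min_delta``)."""

    def __init__(self, lr: float, patience: int = 5, factor: float = 10.0,
                 min_delta: float = 0.0) -> None:
        self.lr = lr
        self.patience = patience
        self.factor = factor
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> float:
        """Record one epoch's validation loss; returns the lr to use next."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr /= self.factor
                self.bad_epochs = 0
        return self.lr


@dataclass
class TrainedClassifier:
    net: L.Sequential
    config: ClassifierConfig
    history: list[dict]            # per epoch: train_loss, val_loss, lr
    best_epoch: int

    def __post_init__(self) -> None:
        lrs = [h["lr"] for h in self.history]
        if any(b > a for a, b in zip(lrs, lrs[1:])):
            raise ValueError("learning-rate sequence must be non-increasing")


def normalize_instance(data: np.ndarray) -> np.ndarray:
    """Per-instance min-max normalization to [0, 1] (constant cubes -> 0)."""
    data = np.asarray(data, dtype=np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 0:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def _pool_stem(x: np.ndarray) -> np.ndarray:
    f = STEM_POOL
    s = x.shape
    return x.reshape(s[0], s[1], s[2] // f, f, s[3] // f, f, s[4] // f, f) \
            .mean(axis=(3, 5, 7), dtype=np.float32)


def prepare_inputs(cubes: Iterable[np.ndarray]) -> np.ndarray:
    """Normalize and stem-pool 64^3 cubes into the (B, 1, 16, 16, 16)
    network input, one cube at a time to bound memory."""
    pooled = []
    for cube in cubes:
        if cube.shape != (MODEL_INPUT_SIZE,) * 3:
            raise ValueError(f"expected {MODEL_INPUT_SIZE}^3 cube, got {cube.shape}")
        x = normalize_instance(cube)[None, None]
        pooled.append(_pool_stem(x)[0])
    if not pooled:
        return np.zeros((0, 1) + (MODEL_INPUT_SIZE // STEM_POOL,) * 3,
                        dtype=np.float32)
    return np.stack(pooled)


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Accept a labeled-instance table (DataFrame with 'instance'/'label'
    columns) or a sequence of (SinusInstance | ndarray, label) pairs."""
    if hasattr(dataset, "columns"):
        cubes = [inst.data for inst in dataset["instance"]]
        y = dataset["label"].to_numpy(dtype=int)
    else:
        cubes, ys = [], []
        for inst, label in dataset:
            cubes.append(inst.data if isinstance(inst, SinusInstance) else inst)
            ys.append(int(label))
        y = np.array(ys, dtype=int)
    return prepare_inputs(cubes), y


def train_classifier(train_set, val_set,
                     config: ClassifierConfig) -> TrainedClassifier:
    """Train a classifier by mini-batch cross-entropy minimization.

    ``train_set``/``val_set`` are labeled-instance tables (from
    build_labeled_instances) or sequences of (instance, label) pairs.
    Returns the best-validation-loss checkpoint with the full history.
    Deterministic for a fixed config seed.
    """
    Xtr, ytr = _as_arrays(train_set)
    Xval, yval = _as_arrays(val_set)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set must contain both classes")
    if len(yval) == 0:
        raise ValueError("validation set is empty; the plateau schedule and "
                         "checkpoint selection need validation instances")
    net = build_network(config)
    opt = L.Adam(net, lr=config.learning_rate)
    sched = ReduceLROnPlateau(config.learning_rate, config.plateau_patience,
                              config.plateau_factor, config.min_delta)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 1]))
    n = len(ytr)
    history: list[dict] = []
    best_state = L.get_state(net)
    best_val = np.inf
    best_epoch = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(Xtr[idx], train=True)
            loss, grad = L.cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={opt.lr:g}); aborting")
            net.backward(grad)
            opt.step()
            losses.append(loss)
        val_logits = _forward_batched(net, Xval)
        val_loss, _ = L.cross_entropy(val_logits, yval)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        lr_used = opt.lr
        opt.lr = sched.step(val_loss)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": float(val_loss), "lr": lr_used})
        if val_loss < best_val:
            best_val = val_loss
            best_state = L.get_state(net)
            best_epoch = epoch
    L.set_state(net, best_state)
    return TrainedClassifier(net=net, config=config, history=history,
                             best_epoch=best_epoch)


def _forward_batched(net: L.Sequential, X: np.ndarray,
                     batch: int = 64) -> np.ndarray:
    outs = [net.forward(X[i:i + batch], train=False)
            for i in range(0, len(X), batch)]
    return np.concatenate(outs) if outs else np.zeros((0, 2), dtype=np.float32)


def predict_proba(model: TrainedClassifier,
                  instance: SinusInstance | np.ndarray) -> np.ndarray:
    """Class probabilities (p_normal, p_anomalous) for one 64^3 instance."""
    data = instance.data if isinstance(instance, SinusInstance) else instance
    data = np.asarray(data)
    if data.shape != (MODEL_INPUT_SIZE,) * 3:
        raise ValueError(f"expected a {MODEL_INPUT_SIZE}^3 instance, "
                         f"got shape {data.shape}")
    x = prepare_inputs([data])
    logits = model.net.forward(x, train=False)
    return L.softmax(logits.astype(np.float64))[0]


def predict_proba_batch(model: TrainedClassifier,
                        instances: Sequence[SinusInstance | np.ndarray]
                        ) -> np.ndarray:
    cubes = [i.data if isinstance(i, SinusInstance) else i for i in instances]
    X = prepare_inputs(cubes)
    logits = _forward_batched(model.net, X)
    return L.softmax(logits.astype(np.float64))


def save_checkpoint(model: TrainedClassifier, path: str | os.PathLike) -> None:
    state = L.get_state(model.net)
    arrays = {f"layer{i}.{k}": v for i, st in enumerate(state)
              for k, v in st.items()}
    np.savez(path if str(path).endswith(".npz") else f"{path}.npz",
             _config=json.dumps(asdict(model.config)),
             _history=json.dumps(model.history),
             _best_epoch=model.best_epoch, **arrays)


def load_checkpoint(path: str | os.PathLike) -> TrainedClassifier:
    with np.load(path, allow_pickle=False) as z:
        config = ClassifierConfig(**json.loads(str(z["_config"])))
        history = json.loads(str(z["_history"]))
        best_epoch = int(z["_best_epoch"])
        net = build_network(config)
        state = L.get_state(net)
        for i, st in enumerate(state):
            for k in st:
                st[k] = z[f"layer{i}.{k}"]
        L.set_state(net, state)
    return TrainedClassifier(net=net, config=config, history=history,
                             best_epoch=best_epoch)
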