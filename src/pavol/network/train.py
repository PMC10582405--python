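"""Training loop for the volumetric enhancer: Adam on per-batch MSE with
early stopping, plus a bounded-memory streaming loader for paired cubes.

Paired cubes live on disk as ``<id>_input.npy`` / ``<id>_target.npy`` files;
:func:`stream_batches` shuffles identifiers with a seeded generator and loads
one batch at a time, so at no point are more than two batches of volumes
resident regardless of dataset size.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import EnhancerModel

__all__ = ["TrainingConfig", "Adam", "stream_batches", "train", "mse_loss"]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (defaults follow the full-scale recipe)."""

    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 300
    patience: int = 10
    split_ratio: float = 0.8
    lr_decay: float = 1.0
    warmup_epochs: int = 0
    seed: int = 0
    mixed_precision: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must lie in (0, 1]")


class Adam:
    """Adam optimizer over a model's parameter registry."""

    def __init__(self, model: EnhancerModel, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for name, layer, pname in self.model.parameters():
            g = layer.grads.get(pname)
            if g is None:
                continue
            m = self.m.setdefault(name, np.zeros_like(layer.params[pname]))
            v = self.v.setdefault(name, np.zeros_like(layer.params[pname]))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[pname] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[pname].dtype
            )


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared intensity error and its gradient w.r.t. the prediction."""
    diff = (pred - target).astype(np.float32)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad


def _dataset_ids(dataset_dir: Path) -> list[str]:
    dataset_dir = Path(dataset_dir)
    inputs = {p.name[: -len("_input.npy")] for p in dataset_dir.glob("*_input.npy")}
    targets = {p.name[: -len("_target.npy")] for p in dataset_dir.glob("*_target.npy")}
    odd = inputs.symmetric_difference(targets)
    if odd:
        raise ValueError(f"unpaired cube identifiers: {sorted(odd)!r}")
    if not inputs:
        raise ValueError(f"no paired cubes found in {dataset_dir}")
    return sorted(inputs)


class stream_batches:
    """Iterable over (input, target) batches with a seeded per-epoch shuffle.

    Each iteration pass (epoch) visits every pair exactly once in the order
    given by ``numpy.random.default_rng(seed)``; re-iterating with the same
    seed reproduces the same order. Batches have shape
    ``(batch, 1, D, H, W)`` and only the current batch is held in memory.
    """

    def __init__(self, dataset_dir, batch_size: int, seed: int = 0, ids=None) -> None:
        self.dataset_dir = Path(dataset_dir)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self.ids = list(ids) if ids is not None else _dataset_ids(self.dataset_dir)

    def __len__(self) -> int:
        return (len(self.ids) + self.batch_size - 1) // self.batch_size

    def with_seed(self, seed: int) -> "stream_batches":
        """Same dataset, different shuffle seed (used for per-epoch reshuffles)."""
        return stream_batches(self.dataset_dir, self.batch_size, seed=seed, ids=self.ids)

    def n_pairs(self) -> int:
        return len(self.ids)

    def __iter__(self):
        order = np.random.default_rng(self.seed).permutation(len(self.ids))
        for b0 in range(0, len(order), self.batch_size):
            chunk = [self.ids[i] for i in order[b0:b0 + self.batch_size]]
            xs, ys = [], []
            for cid in chunk:
                xs.append(np.load(self.dataset_dir / f"{cid}_input.npy"))
                ys.append(np.load(self.dataset_dir / f"{cid}_target.npy"))
            x = np.stack(xs)[:, None].astype(np.float32)
            y = np.stack(ys)[:, None].astype(np.float32)
            yield x, y


def train(
    model: EnhancerModel,
    train_data,
    val_data,
    tc: TrainingConfig,
    verbose: bool = False,
) -> tuple[EnhancerModel, dict]:
    """Minimize per-batch MSE with Adam; early-stop on validation loss.

    Stops when validation loss has not improved for ``patience`` consecutive
    epochs (or at ``max_epochs``) and restores the best-validation weights.
    Returns the model and a history dict with per-epoch train/val losses.
    """
    opt = Adam(model, lr=tc.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    bad_epochs = 0
    for epoch in range(tc.max_epochs):
        opt.lr = tc.learning_rate * tc.lr_decay**epoch
        # fresh batch composition per epoch when the loader supports it
        epoch_data = (
            train_data.with_seed(tc.seed + epoch)
            if hasattr(train_data, "with_seed")
            else train_data
        )
        n_steps = len(epoch_data) if hasattr(epoch_data, "__len__") else None
        train_losses = []
        for i, (x, y) in enumerate(epoch_data):
            if epoch < tc.warmup_epochs and n_steps:
                # linear ramp across the warmup epochs
                frac = (epoch * n_steps + i + 1) / (tc.warmup_epochs * n_steps)
                opt.lr = tc.learning_rate * tc.lr_decay**epoch * frac
            pred = model.forward(x, training=True)
            loss, grad = mse_loss(pred, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf training loss at epoch {epoch + 1}; lower the "
                    "learning rate or check the input normalization"
                )
            model.backward(grad)
            opt.step()
            train_losses.append(loss)
        val_losses = []
        for x, y in val_data:
            pred = model.forward(x, training=False)
            val_losses.append(mse_loss(pred, y)[0])
        tl = float(np.mean(train_losses)) if train_losses else np.nan
        vl = float(np.mean(val_losses)) if val_losses else tl
        history["train_loss"].append(tl)
        history["val_loss"].append(vl)
        if verbose:
            print(f"epoch {epoch + 1}: train {tl:.3e}  val {vl:.3e}", flush=True)
        if vl < best_val - 1e-12:
            best_val = vl
            best_state = copy.deepcopy(model.state_arrays())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= tc.patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    history["best_val_loss"] = best_val
    history["stopped_epoch"] = len(history["train_loss"])
    return model, history
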