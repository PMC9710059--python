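"""Training protocol: l1 objective, Adam, early stopping, multi-resolution
supervision for the LRN family, and seeded reproducibility.

The objective is the mean absolute error between predictions and
ground-truth segments, summed over target leads.  For the LRN family each
auxiliary decoder output is additionally compared (weighted, equal weights
by default) against the target average-pooled to that resolution.
Validation loss is monitored after every epoch; training stops once it has
not improved for ``patience`` epochs, and the parameters of the best
validation epoch are restored before the model is returned.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import ConversionModel, ModelConfig, OneToAllModel, build_model
from .nn import Adam, DTYPE
from .preprocess import SegmentDataset

__all__ = [
    "TrainConfig", "TrainHistory", "l1_loss", "multi_lead_loss",
    "EarlyStopper", "fit", "train_one_to_all",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    Defaults follow the conversion training protocol: Adam at an initial
    learning rate of 1e-3, at most 500 epochs, batch size 32 for the shared
    scheme (16 for individual encoders), early-stopping patience of 50
    epochs, l1 objective.
    """

    lr: float = 1e-3
    max_epochs: int = 500
    batch_size: int = 32
    patience: int = 50
    loss: str = "l1"
    lrn_level_weights: tuple[float, ...] | None = None
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if self.loss != "l1":
            raise ValueError("only the l1 objective is supported")
        if self.lrn_level_weights is not None:
            w = self.lrn_level_weights
            if any(x < 0 for x in w) or not any(x > 0 for x in w):
                raise ValueError("level weights must be >= 0 and not all zero")


@dataclass
class TrainHistory:
    """Per-epoch record of a fit."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss", "seconds"])
            for i, (tr, va, sec) in enumerate(
                    zip(self.train_loss, self.val_loss, self.epoch_seconds), 1):
                w.writerow([i, f"{tr:.8f}", f"{va:.8f}", f"{sec:.3f}"])


def l1_loss(predicted: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute difference over all samples and batch entries."""
    predicted = np.asarray(predicted)
    target = np.asarray(target)
    if predicted.shape != target.shape:
        raise ValueError(
            f"shape mismatch: {predicted.shape} vs {target.shape}")
    return float(np.mean(np.abs(predicted - target)))


def _l1_grad(predicted: np.ndarray, target: np.ndarray) -> np.ndarray:
    return (np.sign(predicted - target) / predicted.size).astype(DTYPE)


def pool_target(target: np.ndarray, out_length: int) -> np.ndarray:
    """Average-pool a (batch, length) target to a coarser resolution (the
    ground truth for LRN auxiliary heads)."""
    n, length = target.shape
    if length % out_length:
        raise ValueError(f"cannot pool length {length} to {out_length}")
    f = length // out_length
    return target.reshape(n, out_length, f).mean(axis=2)


def multi_lead_loss(
    outputs: dict[str, np.ndarray],
    targets: dict[str, np.ndarray],
    lrn_aux: dict[str, list[np.ndarray]] | None = None,
    weights: tuple[float, ...] | None = None,
    aux_targets: dict[str, list[np.ndarray]] | None = None,
) -> float:
    """Sum of per-lead l1 losses, plus weighted auxiliary-resolution terms
    when LRN per-level predictions are given."""
    total = 0.0
    for lead, target in targets.items():
        if lead not in outputs:
            raise KeyError(f"prediction for lead {lead} is missing")
        total += l1_loss(outputs[lead], target)
    if lrn_aux:
        for lead, aux_list in lrn_aux.items():
            if not aux_list:
                continue
            w = weights if weights is not None else (1.0,) * len(aux_list)
            for level, a in enumerate(aux_list):
                a2 = a[0] if a.ndim == 3 else a
                if aux_targets is not None:
                    tgt = aux_targets[lead][level]
                else:
                    tgt = pool_target(targets[lead], a2.shape[1])
                total += w[level] * l1_loss(a2, tgt)
    return total


class EarlyStopper:
    """Patience-based early stopping on a monitored loss.

    ``update`` returns True when the epoch is a new best; ``should_stop``
    becomes True once ``epoch - best_epoch >= patience``.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0  # 1-based
        self.last_epoch = 0

    def update(self, loss: float, epoch: int) -> bool:
        self.last_epoch = epoch
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            return True
        return False

    @property
    def should_stop(self) -> bool:
        return self.best_epoch > 0 and (
            self.last_epoch - self.best_epoch >= self.patience)


def _dataset_arrays(dataset: SegmentDataset, config: ModelConfig):
    x = dataset.X[config.reference_lead].astype(DTYPE)
    targets = {lead: dataset.X[lead].astype(DTYPE)
               for lead in config.target_leads}
    return x, targets


def _aux_targets_for(model: ConversionModel, targets: dict[str, np.ndarray],
                     aux: dict[str, list[np.ndarray]]):
    """Pool (padded) targets to the auxiliary resolutions."""
    if not isinstance(model, OneToAllModel):
        return None
    out = {}
    for lead, aux_list in aux.items():
        if not aux_list:
            return None
        padded = model._pad(targets[lead])
        out[lead] = [pool_target(padded, a.shape[2]) for a in aux_list]
    return out


def _epoch_losses(model, x, targets, config: TrainConfig, optimiser, rng):
    """One optimisation epoch; returns mean per-batch loss."""
    n = len(x)
    order = rng.permutation(n)
    losses = []
    for start in range(0, n, config.batch_size):
        idx = order[start:start + config.batch_size]
        xb = x[idx]
        tb = {lead: t[idx] for lead, t in targets.items()}
        preds, aux = model.forward(xb, train=True)
        aux_t = _aux_targets_for(model, tb, aux)
        loss = multi_lead_loss(preds, tb, aux if aux_t else None,
                               config.lrn_level_weights, aux_t)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss ({loss}); aborting. Inspect the "
                "learning rate and input normalisation.")
        losses.append(loss)
        dpred = {lead: _l1_grad(preds[lead], tb[lead]) for lead in tb}
        daux = None
        if aux_t:
            w = config.lrn_level_weights
            daux = {}
            for lead, aux_list in aux.items():
                ww = w if w is not None else (1.0,) * len(aux_list)
                daux[lead] = [
                    ww[j] * _l1_grad(a[0], aux_t[lead][j])[None]
                    for j, a in enumerate(aux_list)]
        optimiser.zero_grad()
        model.backward(dpred, daux)
        optimiser.step()
    return float(np.mean(losses))


def evaluate_loss(model, dataset: SegmentDataset, batch_size: int = 64) -> float:
    """Inference-mode multi-lead l1 loss on a dataset (the early-stopping
    monitor)."""
    x, targets = _dataset_arrays(dataset, model.config)
    losses, counts = [], []
    for start in range(0, len(x), batch_size):
        xb = x[start:start + batch_size]
        tb = {lead: t[start:start + batch_size] for lead, t in targets.items()}
        preds, _ = model.forward(xb, train=False)
        losses.append(multi_lead_loss(preds, tb))
        counts.append(len(xb))
    return float(np.average(losses, weights=counts))


def fit(
    model: ConversionModel,
    train_set: SegmentDataset,
    val_set: SegmentDataset,
    config: TrainConfig = TrainConfig(),
) -> tuple[ConversionModel, TrainHistory]:
    """Train a conversion model with Adam, early stopping and best-epoch
    parameter restoration."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    x, targets = _dataset_arrays(train_set, model.config)
    optimiser = Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    stopper = EarlyStopper(config.patience)
    history = TrainHistory()
    best_params: list[np.ndarray] | None = None
    best_state: dict | None = None
    for epoch in range(1, config.max_epochs + 1):
        t0 = time.perf_counter()
        train_loss = _epoch_losses(model, x, targets, config, optimiser, rng)
        val_loss = evaluate_loss(model, val_set)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss ({val_loss})")
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.epoch_seconds.append(time.perf_counter() - t0)
        if stopper.update(val_loss, epoch):
            best_params = [p.data.copy() for p in model.params()]
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        if stopper.should_stop:
            history.stopped_early = True
            break
    history.best_epoch = stopper.best_epoch
    if best_params is not None:
        for p, saved in zip(model.params(), best_params):
            p.data[...] = saved
        for key, target in model.state_arrays().items():
            target[...] = best_state[key]
    return model, history


def train_one_to_all(
    train_set: SegmentDataset,
    val_set: SegmentDataset,
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
) -> tuple[dict[str, ConversionModel], dict[str, TrainHistory]]:
    """Train the one-to-all conversion.

    Shared scheme: one joint fit over the summed multi-lead loss, returned
    under the key ``"shared"``.  Individual scheme: one independent fit per
    target lead (each with its own early stopping), keyed by lead.
    """
    from dataclasses import replace as _replace

    models: dict[str, ConversionModel] = {}
    histories: dict[str, TrainHistory] = {}
    if model_config.encoder_scheme == "shared":
        model = build_model(model_config, seed=train_config.seed)
        model, hist = fit(model, train_set, val_set, train_config)
        models["shared"] = model
        histories["shared"] = hist
    else:
        for lead in model_config.target_leads:
            cfg = _replace(model_config, target_leads=(lead,))
            model = build_model(cfg, seed=train_config.seed)
            model, hist = fit(model, train_set, val_set, train_config)
            models[lead] = model
            histories[lead] = hist
    return models, histories
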