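"""Training orchestration and whole-map enhancement.

Training follows a plateau-halving schedule: Adam starts at lr 5e-4 and
the learning rate is halved whenever the mean training loss has not
improved for four consecutive epochs; training stops at 300 epochs or
when the rate reaches 1e-5.  The checkpoint with the least validation
loss is returned.

Whole-map enhancement clips and globally normalises the input, cuts it
into network-sized boxes with stride 12, runs the network and averages
the overlapping outputs back into a map with the input's geometry.  The
output lives in the simulated-density (target) amplitude space.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Adam, Tensor
from .chunking import BoxPair, augment_pair, extract_boxes, plan_chunks, reassemble
from .grid import DensityGrid, average_half_maps, clip_negative, normalize_global
from .losses import SsimParams, total_loss_t
from .model import SCUNet

__all__ = ["TrainConfig", "TrainingState", "PlateauSchedule", "train",
           "enhance_map", "enhance_half_maps"]


@dataclasses.dataclass
class TrainConfig:
    lr_init: float = 5e-4
    lr_factor: float = 0.5
    patience: int = 4           # epochs without improvement before halving
    lr_min: float = 1e-5
    max_epochs: int = 300
    batch_size: int = 108
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.lr_min < self.lr_init:
            raise ValueError("need 0 < lr_min < lr_init")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclasses.dataclass
class TrainingState:
    epochs_run: int = 0
    lr_history: list = dataclasses.field(default_factory=list)
    train_losses: list = dataclasses.field(default_factory=list)
    val_losses: list = dataclasses.field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    stopped_reason: str = ""


class PlateauSchedule:
    """Halve the learning rate when training loss stops improving.

    A halving triggers when the best loss of the last ``patience`` epochs
    is no better than the best loss seen earlier (within the window that
    started at the previous halving); the window restarts after each
    halving.  Training stops once the rate reaches ``lr_min``.
    """

    def __init__(self, lr_init: float, factor: float, patience: int,
                 lr_min: float):
        self.lr = lr_init
        self.factor = factor
        self.patience = patience
        self.lr_min = lr_min
        self._losses: list[float] = []

    def update(self, loss: float) -> bool:
        """Record an epoch loss; returns True when training should stop."""
        self._losses.append(loss)
        if len(self._losses) > self.patience:
            recent = min(self._losses[-self.patience:])
            before = min(self._losses[:-self.patience])
            if recent >= before:
                self.lr *= self.factor
                self._losses = []
                if self.lr <= self.lr_min:
                    return True
        return False


def _center_crop(pair: BoxPair, side: int) -> BoxPair:
    off = [(s - side) // 2 for s in pair.experimental.shape]
    sl = tuple(slice(o, o + side) for o in off)
    return BoxPair(pair.experimental[sl], pair.target[sl])


def _batches(n: int, size: int):
    for i in range(0, n, size):
        yield range(i, min(i + size, n))


def _epoch_loss(model: SCUNet, pairs: list[BoxPair], batch_size: int,
                params: SsimParams) -> float:
    """Mean total loss over unaugmented pairs, no gradient."""
    from .autodiff.tensor import no_grad
    losses, weights = [], []
    with no_grad():
        for idx in _batches(len(pairs), batch_size):
            xb = np.stack([pairs[i].experimental for i in idx]).astype(np.float32)
            yb = np.stack([pairs[i].target for i in idx]).astype(np.float32)
            out = model(Tensor(xb))
            loss, _ = total_loss_t(out, Tensor(yb), params)
            losses.append(float(loss.data))
            weights.append(len(idx))
    return float(np.average(losses, weights=weights))


def train(model: SCUNet, train_pairs: list[BoxPair], val_pairs: list[BoxPair],
          cfg: TrainConfig | None = None,
          log=None) -> tuple[SCUNet, TrainingState]:
    """Fit the network on raw box pairs with the plateau-halving schedule.

    Raw pairs may be larger than the network box; each is augmented
    (random proper rotation + random crop) per epoch.  Validation pairs
    are center-cropped and never augmented so that model selection is
    noise-free.
    """
    cfg = cfg or TrainConfig()
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation pair sets must be non-empty")
    side = model.cfg.box_size
    for p in train_pairs:
        if p.side < side:
            raise ValueError(f"raw pair side {p.side} < network box {side}")
    params = SsimParams()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr_init)
    state = TrainingState()
    val_set = [_center_crop(p, side) for p in val_pairs]
    best_state = model.state_dict()
    sched = PlateauSchedule(cfg.lr_init, cfg.lr_factor, cfg.patience,
                            cfg.lr_min)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_pairs))
        batch_losses, batch_sizes = [], []
        for idx in _batches(len(order), cfg.batch_size):
            aug = [augment_pair(train_pairs[order[i]], rng, crop=side)
                   for i in idx]
            xb = np.stack([p.experimental for p in aug]).astype(np.float32)
            yb = np.stack([p.target for p in aug]).astype(np.float32)
            out = model(Tensor(xb))
            loss, _ = total_loss_t(out, Tensor(yb), params)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
            batch_sizes.append(len(idx))
        train_loss = float(np.average(batch_losses, weights=batch_sizes))
        val_loss = _epoch_loss(model, val_set, cfg.batch_size, params)

        state.train_losses.append(train_loss)
        state.val_losses.append(val_loss)
        state.lr_history.append(opt.lr)
        state.epochs_run = epoch + 1
        if val_loss < state.best_val_loss:
            state.best_val_loss = val_loss
            state.best_epoch = epoch
            best_state = model.state_dict()
        if log is not None:
            log({"epoch": epoch, "lr": opt.lr, "train_loss": train_loss,
                 "val_loss": val_loss})

        if sched.update(train_loss):
            state.stopped_reason = "lr_min"
            break
        opt.lr = sched.lr
    else:
        state.stopped_reason = "max_epochs"

    model.load_state_dict(best_state)
    return model, state


def enhance_map(map_in: DensityGrid, model: SCUNet, batch_size: int = 8,
                stride: int = 12) -> DensityGrid:
    """Enhance a full map by tiled inference with overlap averaging.

    The map spacing must already equal the spacing the model was trained
    at (resample first with :func:`cryopolish.grid.resample_to_spacing`).
    """
    box = model.cfg.box_size
    normalized, _ = normalize_global(clip_negative(map_in))
    layout = plan_chunks(normalized.shape, box, stride)
    boxes = extract_boxes(normalized.values.astype(np.float32), layout)
    processed = np.empty_like(boxes)
    for idx in _batches(len(boxes), batch_size):
        processed[idx.start:idx.stop] = model.predict(boxes[idx.start:idx.stop])
    out = reassemble(processed, layout, normalized.shape)
    return map_in.copy_with(out)


def enhance_half_maps(a: DensityGrid, b: DensityGrid | None, model: SCUNet,
                      batch_size: int = 8, stride: int = 12) -> DensityGrid:
    """Enhance the average of two half-maps (or a single half-map)."""
    merged = a if b is None else average_half_maps(a, b)
    return enhance_map(merged, model, batch_size=batch_size, stride=stride)
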