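"""Training loop (Adam + cosine-annealed learning rate), evaluation, prediction.

The schedule follows the half-cosine
``lr(t) = lr_min + 0.5 (lr0 - lr_min) (1 + cos(pi t / T))`` so training
starts at ``lr0`` and ends at ``lr_min`` (default 0).  Full-scale runs use
50 epochs at initial rate 1e-4; small fixtures can override both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .losses import LossWeights, focal_dice_loss
from .metrics import (MetricReport, confusion_matrix, overlap_metrics,
                      evaluate_pair, aggregate_reports)
from .model import SCUNet, ScuNetConfig
from .phantoms import encode_mask_rgb

__all__ = ["TrainConfig", "TrainHistory", "cosine_lr", "train_model",
           "evaluate_model", "predict", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    lr0: float = 1e-4
    lr_min: float = 0.0
    batch_size: int = 4
    loss: LossWeights = LossWeights()
    model: ScuNetConfig = ScuNetConfig()
    seed: int = 0
    log_every: int = 1
    target_mdice: float | None = None   # early stop once train mDice reaches it

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (self.lr0 > self.lr_min >= 0):
            raise ValueError("require lr0 > lr_min >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    def column(self, key: str) -> list:
        return [r[key] for r in self.records]


def cosine_lr(t: int, T: int, lr0: float, lr_min: float = 0.0) -> float:
    """Half-cosine annealing: lr0 at t=0, lr_min at t=T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not 0 <= t <= T:
        raise ValueError(f"t must lie in [0, {T}], got {t}")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * t / T))


def _to_batch(images: np.ndarray, in_channels: int) -> np.ndarray:
    """(B, H, W) grayscale -> (B, C, H, W) with channel replication."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    if x.shape[1] == 1 and in_channels == 3:
        x = np.repeat(x, 3, axis=1)
    return x


def _batch_mdice(probs: np.ndarray, masks: np.ndarray, k: int) -> float:
    preds = probs.argmax(axis=1)
    vals = [overlap_metrics(confusion_matrix(p, t, k)).mdice
            for p, t in zip(preds, masks)]
    return float(np.mean(vals))


def train_model(config: TrainConfig, dataset,
                log=None) -> tuple[SCUNet, TrainHistory]:
    """Train SCU-Net on (image, mask) pairs with the compound focal Dice loss.

    ``dataset`` is a sequence of (H x W image in [0,1], H x W int mask).
    Everything is seeded from ``config.seed``: parameter init, and the batch
    shuffle of each epoch.  Returns the trained model and per-epoch history
    (epoch, lr, train_loss, train_mdice).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    model = SCUNet(config.model, seed=config.seed)
    opt = nn.Adam(model.parameters(), lr=config.lr0)
    order_rng = np.random.default_rng(config.seed + 1)
    k = config.model.num_classes - 1
    history = TrainHistory()

    images = np.stack([np.asarray(img, dtype=np.float32) for img, _ in dataset])
    masks = np.stack([np.asarray(m, dtype=np.int64) for _, m in dataset])
    xs = _to_batch(images, config.model.in_channels)

    model.train()
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr0, config.lr_min)
        opt.lr = lr
        order = order_rng.permutation(len(dataset))
        losses, dices = [], []
        for start in range(0, len(dataset), config.batch_size):
            sel = order[start:start + config.batch_size]
            probs = model.forward(nn.Tensor(xs[sel], requires_grad=True))
            lv = focal_dice_loss(probs, masks[sel], config.loss)
            if not np.isfinite(lv.total):
                raise FloatingPointError(
                    f"non-finite loss {lv.total} at epoch {epoch}, "
                    f"batch starting at {start} (indices {sel.tolist()})")
            opt.zero_grad()
            lv.total_tensor.backward()
            opt.step()
            losses.append(lv.total)
            dices.append(_batch_mdice(probs.data, masks[sel], k))
        rec = {"epoch": epoch, "lr": lr,
               "train_loss": float(np.mean(losses)),
               "train_mdice": float(np.mean(dices))}
        history.records.append(rec)
        if log is not None and epoch % config.log_every == 0:
            log(f"epoch={rec['epoch']} lr={rec['lr']:.3e} "
                f"loss={rec['train_loss']:.4f} mdice={rec['train_mdice']:.4f}")
        if (config.target_mdice is not None
                and rec["train_mdice"] >= config.target_mdice):
            break
    return model, history


def evaluate_model(model: SCUNet, dataset, *, spacing: float = 1.0,
                   include_background: bool = True) -> MetricReport:
    """Mean per-image metrics of argmax predictions over a dataset.

    numpy argmax breaks probability ties toward the lower class index.
    """
    k = model.config.num_classes - 1
    reports = []
    for img, mask in dataset:
        mask = np.asarray(mask)
        if mask.max() > k:
            raise ValueError(f"mask contains class {mask.max()} but the model "
                             f"has {k + 1} classes")
        probs = model.predict_proba(_to_batch(np.asarray(img)[None],
                                              model.config.in_channels))
        pred = probs[0].argmax(axis=0)
        reports.append(evaluate_pair(pred, mask, k, spacing=spacing,
                                     include_background=include_background))
    return aggregate_reports(reports)


def predict(model: SCUNet, image, *, alpha: float = 0.5):
    """Segment one grayscale image; returns (label mask, RGB overlay).

    Images whose sides are not divisible by 16 are reflection-padded,
    segmented, and cropped back.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("predict expects a single-channel H x W image")
    h, w = img.shape
    ph, pw = (-h) % 16, (-w) % 16
    padded = np.pad(img, ((0, ph), (0, pw)), mode="reflect") if ph or pw else img
    probs = model.predict_proba(_to_batch(padded[None],
                                          model.config.in_channels))
    mask = probs[0].argmax(axis=0)[:h, :w]
    rgb = encode_mask_rgb(mask).astype(np.float64)
    base = np.repeat((img * 255.0)[..., None], 3, axis=2)
    lesion = mask > 0
    overlay = base.copy()
    overlay[lesion] = (1 - alpha) * base[lesion] + alpha * rgb[lesion]
    return mask, overlay.round().astype(np.uint8)


def save_checkpoint(path, model: SCUNet, history: TrainHistory | None = None):
    """Serialise weights + config (numpy .npz with an embedded JSON header)."""
    arrays = model.state_arrays()
    meta = {"config": model.config.to_dict(),
            "history": history.records if history else []}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[SCUNet, TrainHistory]:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    model = SCUNet(ScuNetConfig.from_dict(meta["config"]))
    model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    model.eval()
    return model, TrainHistory(records=meta["history"])
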