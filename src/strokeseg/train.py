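"""Training loop: Adam over mini-batches with per-epoch Dice/accuracy logs.

The recipe follows the reference hyper-parameters (batch 8, learning rate
1e-4, Adam, dropout 0.2, 100 epochs, BCE-Dice default loss); all knobs are
overridable.  Training metrics are computed from the same forward passes
used for the updates (batch statistics active), validation metrics from
inference-mode passes.
"""

from __future__ import annotations

import json

import numpy as np

from . import nn
from .losses import get_loss_t
from .metrics import accuracy_from_masks, dice_from_masks
from .model import SegmentationModel, binarize
from .nn import Tensor

__all__ = ["TrainingDiverged", "train_model", "evaluate_model"]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


def _as_batch(images: np.ndarray, masks: np.ndarray):
    x = np.asarray(images, dtype=np.float32)
    y = np.asarray(masks, dtype=np.float32)
    if x.ndim == 2:
        x, y = x[None], y[None]
    if x.shape != y.shape:
        raise ValueError(f"image/mask shapes differ: {x.shape} vs {y.shape}")
    if x.ndim != 3:
        raise ValueError(f"expected (N, H, W) arrays, got {x.shape}")
    return x, y


def train_model(model: SegmentationModel,
                images: np.ndarray,
                masks: np.ndarray,
                *,
                loss: str = "bce_dice",
                learning_rate: float = 1e-4,
                batch_size: int = 8,
                epochs: int = 100,
                val_images: np.ndarray | None = None,
                val_masks: np.ndarray | None = None,
                seed: int = 0,
                stop_dice: float | None = None,
                max_steps: int | None = None,
                log_file=None,
                verbose: bool = False) -> list[dict]:
    """Train in place; returns the per-epoch history.

    ``stop_dice`` / ``max_steps`` allow step-bounded runs (smoke tests,
    single-pair overfitting): training stops as soon as the running training
    Dice exceeds ``stop_dice`` or ``max_steps`` updates have been applied.
    """
    x, y = _as_batch(images, masks)
    n = x.shape[0]
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    loss_fn = get_loss_t(loss)
    on_logits = loss == "sigmoid_bce"
    optimizer = nn.Adam(model.parameters(trainable_only=True),
                        lr=learning_rate)
    rng = np.random.default_rng(seed)
    history: list[dict] = []
    steps = 0
    model.train()

    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        epoch_dice = []
        epoch_acc = []
        stop = False
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = Tensor(x[idx][..., None])
            yb = Tensor(y[idx][..., None])
            out = model(xb, return_logits=on_logits)
            loss_t = loss_fn(yb, out)
            loss_val = float(loss_t.data)
            if not np.isfinite(loss_val):
                raise TrainingDiverged(
                    f"non-finite loss {loss_val} at epoch {epoch}, "
                    f"step {steps}; try a lower learning rate")
            optimizer.zero_grad()
            model.zero_grad()
            loss_t.backward()
            optimizer.step()
            steps += 1

            probs = (1.0 / (1.0 + np.exp(-out.data)) if on_logits
                     else out.data)
            pred = binarize(probs[..., 0])
            epoch_losses.append(loss_val)
            d = dice_from_masks(y[idx].astype(np.uint8), pred)
            epoch_dice.append(d)
            epoch_acc.append(accuracy_from_masks(y[idx].astype(np.uint8),
                                                 pred))
            if stop_dice is not None and d > stop_dice:
                stop = True
                break
            if max_steps is not None and steps >= max_steps:
                stop = True
                break

        entry = {
            "epoch": epoch + 1,
            "steps": steps,
            "loss": float(np.mean(epoch_losses)),
            "dice": float(np.mean(epoch_dice)),
            "accuracy": float(np.mean(epoch_acc)),
        }
        if val_images is not None and val_masks is not None:
            val = evaluate_model(model, val_images, val_masks)
            entry["val_dice"] = val["mean_dice"]
            entry["val_accuracy"] = val["mean_accuracy"]
        history.append(entry)
        if log_file is not None:
            log_file.write(json.dumps(entry) + "\n")
        if verbose:
            msg = (f"epoch {entry['epoch']:3d}  loss {entry['loss']:.4f}  "
                   f"dice {entry['dice']:.4f}  acc {entry['accuracy']:.4f}")
            if "val_dice" in entry:
                msg += (f"  val_dice {entry['val_dice']:.4f}  "
                        f"val_acc {entry['val_accuracy']:.4f}")
            print(msg)
        if stop:
            break
    model.eval()
    return history


def evaluate_model(model: SegmentationModel, images: np.ndarray,
                   masks: np.ndarray, threshold: float = 0.5) -> dict:
    """Per-slice and mean Dice/accuracy of inference-mode predictions."""
    x, y = _as_batch(images, masks)
    per_slice = []
    for i in range(x.shape[0]):
        prob = model.predict(x[i])
        pred = binarize(prob, threshold)
        yt = y[i].astype(np.uint8)
        per_slice.append({
            "index": i,
            "dice": dice_from_masks(yt, pred),
            "accuracy": accuracy_from_masks(yt, pred),
        })
    return {
        "per_slice": per_slice,
        "mean_dice": float(np.mean([s["dice"] for s in per_slice])),
        "mean_accuracy": float(np.mean([s["accuracy"] for s in per_slice])),
        "n_slices": len(per_slice),
    }
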