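"""Training losses: BCE, soft Dice, sigmoid BCE and their BCE-Dice sum.

Each loss has two entry points: a plain-NumPy function returning a float
(the public metric-style API) and a ``*_t`` graph version operating on
autodiff tensors, used by the training loop.  Both share the same
definitions:

* ``bce`` - mean over pixels of ``-[y log p + (1-y) log(1-p)]`` with
  probabilities clipped to ``[eps, 1-eps]``.
* ``dice`` - soft Dice loss ``1 - (2*sum(y*p) + s) / (sum(y) + sum(p) + s)``
  with smoothing ``s`` (default 1), which also defines the degenerate
  empty-mask case as 0 loss.
* ``sigmoid_bce`` - BCE evaluated on ``sigmoid(logits)`` but computed in the
  numerically stable form ``max(z,0) - z*y + log(1+exp(-|z|))``.
* ``bce_dice`` - the unweighted sum of BCE and Dice losses.

Reductions are means over all pixels (and the batch), so loss scales do not
depend on batch size.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "EPSILON", "SMOOTH", "bce_loss", "dice_loss", "sigmoid_bce_loss",
    "bce_dice_loss", "get_loss", "LOSSES",
    "bce_loss_t", "dice_loss_t", "sigmoid_bce_loss_t", "bce_dice_loss_t",
    "get_loss_t",
]

EPSILON = 1e-7
SMOOTH = 1.0


def _check_pair(y_true: np.ndarray, y_pred: np.ndarray) -> None:
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"mask/prediction shapes differ: {y_true.shape} vs {y_pred.shape}")


# -- graph versions ---------------------------------------------------------

def bce_loss_t(y_true: Tensor, y_pred: Tensor, eps: float = EPSILON) -> Tensor:
    p = nn.clip(y_pred, eps, 1.0 - eps)
    ll = y_true * nn.log(p) + (1.0 - y_true) * nn.log(1.0 - p)
    return -ll.mean()


def dice_loss_t(y_true: Tensor, y_pred: Tensor,
                smooth: float = SMOOTH) -> Tensor:
    inter = (y_true * y_pred).sum()
    denom = y_true.sum() + y_pred.sum()
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def sigmoid_bce_loss_t(y_true: Tensor, logits: Tensor) -> Tensor:
    # stable form: max(z, 0) - z*y + log1p(exp(-|z|))
    z = logits
    relu_z = nn.relu(z)
    abs_z = nn.relu(z) + nn.relu(-1.0 * z)
    softplus = nn.log(1.0 + _exp_t(-1.0 * abs_z))
    return (relu_z - z * y_true + softplus).mean()


def _exp_t(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)
    if not (x.requires_grad and nn.is_grad_enabled()):
        return Tensor(out_data)

    def bw(g):
        x._accumulate(g * out_data)

    return Tensor(out_data, True, (x,), bw)


def bce_dice_loss_t(y_true: Tensor, y_pred: Tensor) -> Tensor:
    return bce_loss_t(y_true, y_pred) + dice_loss_t(y_true, y_pred)


# -- NumPy wrappers ---------------------------------------------------------

def bce_loss(y_true, y_pred, eps: float = EPSILON) -> float:
    """Mean two-term binary cross-entropy between a binary mask and
    predicted probabilities."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    _check_pair(y_true, y_pred)
    return float(bce_loss_t(Tensor(y_true), Tensor(y_pred), eps).data)


def dice_loss(y_true, y_pred, smooth: float = SMOOTH) -> float:
    """Soft Dice loss in [0, 1); 0 for perfect overlap (and for the
    degenerate all-empty pair, thanks to smoothing)."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    _check_pair(y_true, y_pred)
    return float(dice_loss_t(Tensor(y_true), Tensor(y_pred), smooth).data)


def sigmoid_bce_loss(y_true, logits) -> float:
    """BCE applied to sigmoid(logits), log-sum-exp stable."""
    y_true = np.asarray(y_true, dtype=np.float64)
    logits = np.asarray(logits, dtype=np.float64)
    _check_pair(y_true, logits)
    return float(sigmoid_bce_loss_t(Tensor(y_true), Tensor(logits)).data)


def bce_dice_loss(y_true, y_pred) -> float:
    """Exact sum of the BCE and soft-Dice losses (unit weights)."""
    return bce_loss(y_true, y_pred) + dice_loss(y_true, y_pred)


LOSSES = {
    "bce": bce_loss,
    "dice": dice_loss,
    "sigmoid_bce": sigmoid_bce_loss,
    "bce_dice": bce_dice_loss,
}

_LOSSES_T = {
    "bce": bce_loss_t,
    "dice": dice_loss_t,
    "sigmoid_bce": sigmoid_bce_loss_t,
    "bce_dice": bce_dice_loss_t,
}


def get_loss(name: str):
    """Look up a NumPy loss by its config/CLI name."""
    try:
        return LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from "
                         f"{sorted(LOSSES)}") from None


def get_loss_t(name: str):
    """Graph-version lookup.  ``sigmoid_bce`` expects logits, the rest
    expect probabilities; the trainer handles the dispatch."""
    try:
        return _LOSSES_T[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from "
                         f"{sorted(_LOSSES_T)}") from None
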