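"""Training-curve plots (Dice / accuracy / loss per epoch)."""

from __future__ import annotations

__all__ = ["plot_history"]


def plot_history(history: list[dict], path) -> None:
    """Write a two-panel PNG: Dice/accuracy curves and the loss curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = [h["epoch"] for h in history]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(epochs, [h["dice"] for h in history], label="train Dice")
    ax1.plot(epochs, [h["accuracy"] for h in history], label="train accuracy")
    if history and "val_dice" in history[0]:
        ax1.plot(epochs, [h["val_dice"] for h in history],
                 "--", label="val Dice")
        ax1.plot(epochs, [h["val_accuracy"] for h in history],
                 "--", label="val accuracy")
    ax1.set_xlabel("epoch")
    ax1.set_ylim(0, 1)
    ax1.legend()
    ax2.plot(epochs, [h["loss"] for h in history])
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("training loss")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
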