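"""Figure helpers: loss curves, learning curve, architecture boxplots.

matplotlib is imported lazily so the core package works without it.
"""

from __future__ import annotations

__all__ = ["plot_history", "plot_learning_curve", "plot_comparison_box"]


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_history(history, title: str = "", path=None):
    """Training and validation loss vs. epoch for one run."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    epochs = range(1, history.stopped_epoch + 1)
    ax.plot(epochs, history.train_loss, label="training loss")
    ax.plot(epochs, history.val_loss, label="validation loss")
    ax.axvline(history.best_epoch, ls=":", c="grey", lw=1,
               label=f"best epoch ({history.best_epoch})")
    ax.set_xlabel("epoch")
    ax.set_ylabel("categorical cross-entropy")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_learning_curve(summary, path=None):
    """Mean accuracy vs. N_cal with a +-1 sd band (summary DataFrame)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    s = summary.sort_values("n_cal")
    ax.plot(s.n_cal, s.mean_accuracy, "o-", ms=4)
    ax.fill_between(s.n_cal, s.mean_accuracy - s.sd_accuracy,
                    s.mean_accuracy + s.sd_accuracy, alpha=0.25)
    ax.set_xscale("log")
    ax.set_xlabel("training cases $N_{cal}$")
    ax.set_ylabel("exact-set accuracy [%]")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_comparison_box(groups: dict, path=None):
    """Boxplot of per-architecture accuracy samples."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    names = sorted(groups)
    ax.boxplot([groups[n] for n in names], tick_labels=names)
    ax.set_ylabel("exact-set accuracy [%]")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
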