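"""Diagnostic figures for one seizure's clustering solution."""

from __future__ import annotations

import numpy as np


def seizure_panel(embedding: np.ndarray, labels: np.ndarray,
                  window_times: np.ndarray, sleepwake=None,
                  preictal_cluster: int | None = None, path=None):
    """Four-panel diagnostic: time-colored embedding, clustering solution,
    preictal timeline, and sleep-wake overlay.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t_min = np.asarray(window_times) / 60.0
    fig = plt.figure(figsize=(11, 8))

    ax = fig.add_subplot(2, 2, 1, projection="3d")
    p = ax.scatter(*embedding.T, c=t_min, s=4, cmap="viridis")
    fig.colorbar(p, ax=ax, label="min before onset")
    ax.set_title("embedding (time-colored)")

    ax = fig.add_subplot(2, 2, 2, projection="3d")
    ax.scatter(*embedding.T, c=labels, s=4, cmap="tab10")
    ax.set_title("clustering solution")

    ax = fig.add_subplot(2, 2, 3)
    ax.scatter(t_min, labels, s=4, c=labels, cmap="tab10")
    if preictal_cluster is not None:
        member = t_min[labels == preictal_cluster]
        ax.axvspan(member.min(), member.max(), alpha=0.2, color="red",
                   label="preictal interval")
        ax.legend()
    ax.set_xlabel("min before onset")
    ax.set_ylabel("cluster")
    ax.set_title("preictal timeline")

    ax = fig.add_subplot(2, 2, 4)
    if sleepwake is not None:
        ax.step(t_min, np.asarray(sleepwake, dtype=int), where="post",
                label="wake (1) / sleep (0)")
    if preictal_cluster is not None:
        ax.scatter(t_min, (labels == preictal_cluster).astype(int) * 0.5,
                   s=3, c="red", label="preictal member")
    ax.set_xlabel("min before onset")
    ax.legend(loc="center left")
    ax.set_title("sleep-wake overlay")

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
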