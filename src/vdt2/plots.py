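"""Optional plotting helpers (no tested logic lives here).

Requires matplotlib (``pip install vdt2[plot]``)."""

from __future__ import annotations

import numpy as np

from .validity import DistributionDiff


def plot_distribution_diff(diff: DistributionDiff, feature: str = "", ax=None):
    """Step plot of the two groups' binned proportions."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    centers = 0.5 * (diff.bin_edges[:-1] + diff.bin_edges[1:])
    ax.step(centers, diff.f_control, where="mid", color="black", label="control")
    ax.step(centers, diff.f_t2dm, where="mid", color="red", label="T2DM")
    ax.set_xlabel(feature)
    ax.set_ylabel("proportion")
    ax.set_title(f"{feature}  (tv = {diff.tv:.3f})")
    ax.legend()
    return ax


def plot_attention(results, ax=None):
    """Heatmap of per-node attention weights for a fitted tree."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    att = results.attention_frame()
    im = ax.imshow(att.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(np.arange(att.shape[1]), att.columns, rotation=90)
    ax.set_yticks(np.arange(att.shape[0]), att.index)
    plt.colorbar(im, ax=ax, label="attention weight")
    return ax
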