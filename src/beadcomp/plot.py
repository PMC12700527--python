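"""Minimal plotting helpers (matplotlib).

Imported lazily so the core library works without a display stack.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def composition_map(beads, composition: pd.DataFrame, category: str, ax=None,
                    s: float = 8.0, cmap: str = "viridis"):
    """Scatter the beads of one puck coloured by a category's weight."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    comp = composition.reindex(beads.obs_names).dropna()
    xy = np.asarray(beads[comp.index].obsm["spatial"], dtype=float)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=comp[category], s=s, cmap=cmap,
                    vmin=0, vmax=1)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(category)
    ax.set_aspect("equal")
    plt.colorbar(sc, ax=ax, label="weight")
    return ax


def neighborship_heatmap(result, ax=None, cmap: str = "RdBu_r"):
    """Symmetric heatmap of neighborship z-scores (missing entries blank)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    Z = result.z.to_numpy()
    lim = np.nanmax(np.abs(Z)) if np.isfinite(Z).any() else 1.0
    im = ax.imshow(Z, cmap=cmap, vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(result.z.columns)), result.z.columns, rotation=90)
    ax.set_yticks(range(len(result.z.index)), result.z.index)
    plt.colorbar(im, ax=ax, label="z")
    return ax
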