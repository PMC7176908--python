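"""Optional graphical-genotype heatmap (requires matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calls import DON, HET_ENC, REC
from .genmap import GeneticMap

_COLOURS = {REC: "#2166ac", DON: "#b2182b", HET_ENC: "#fddb45", "NA": "#d9d9d9"}


def plot_graphical_genotypes(encoded: pd.DataFrame, genetic_map: GeneticMap, ax=None):
    """Samples × markers heatmap: blue recurrent, red donor, yellow het.

    Markers are drawn in map order with chromosome boundaries marked.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.3 * len(encoded) + 1))
    order = [m for m in genetic_map.markers.index if m in encoded.columns]
    sub = encoded[order]
    codes = {REC: 0, HET_ENC: 1, DON: 2, "NA": 3}
    img = np.vectorize(codes.get)(sub.to_numpy(dtype=object)).astype(float)
    cmap = ListedColormap([_COLOURS[REC], _COLOURS[HET_ENC], _COLOURS[DON], _COLOURS["NA"]])
    ax.imshow(img, aspect="auto", interpolation="nearest", cmap=cmap, vmin=-0.5, vmax=3.5)
    chroms = genetic_map.markers.loc[order, "chrom"].to_numpy()
    boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 0.5
    for x in boundaries:
        ax.axvline(x, color="black", lw=0.5)
    ax.set_yticks(range(len(sub)), sub.index)
    ax.set_xticks([])
    ax.set_xlabel("markers (map order)")
    return ax
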