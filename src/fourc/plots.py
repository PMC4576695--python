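"""Simple diagnostic figures: decay-fit track and MA plot."""

from __future__ import annotations

import numpy as np


def plot_decay_fit(result, sample, ax=None, sigma_band: float = 3.0):
    """Transformed counts vs log distance with the monotone fit.

    Points are the tested fragments of one sample; the solid line is
    the fitted trend, the dashed line the fit plus ``sigma_band`` times
    the sample's residual scale.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = result.distances.loc[result.v_matrix.index]
    cis = d.notna() & (d != 0)
    x = np.log10(np.abs(d[cis]))
    ax.scatter(x, result.v_matrix.loc[cis, sample], s=6, alpha=0.4, color="grey")
    grid = np.linspace(x.min(), x.max(), 300)
    f = result.fit.evaluate(sample, 10**grid)
    ax.plot(grid, f, color="forestgreen", lw=2)
    ax.plot(grid, f + sigma_band * result.sigma[sample], "--", color="steelblue")
    ax.set_xlabel("log10 |distance from viewpoint| (nt)")
    ax.set_ylabel("variance-stabilized count")
    ax.set_title(str(sample))
    return ax


def plot_ma(diff_table, padj_thresh: float = 0.01, ax=None):
    """MA plot of the differential test (significant fragments in red)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.log2(np.maximum(diff_table["baseMean"], 1e-3))
    sig = diff_table["padj"] < padj_thresh
    ax.scatter(x[~sig], diff_table.loc[~sig, "log2FoldChange"], s=6, color="grey", alpha=0.5)
    ax.scatter(x[sig], diff_table.loc[sig, "log2FoldChange"], s=10, color="red")
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel("log2 mean normalized count")
    ax.set_ylabel("log2 fold change")
    return ax
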