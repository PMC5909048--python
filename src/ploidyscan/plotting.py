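"""Per-chromosome allele-balance visualization.

The layout pairs, at each heterozygous position, a light dot for the
dominant-allele balance (above 1/2) and a dark dot for the secondary
balance (below 1/2); horizontal bars span each window at the height of its
called peak, and a marginal histogram summarizes the whole chromosome.
Windows without a peak (too few variants) simply lack a bar, flagging
regions — e.g. runs of homozygosity — where no inference was made.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless by design

import matplotlib.pyplot as plt
import numpy as np

from .window_peaks import bin_counts, bin_edges

__all__ = ["freq_peak_plot"]

_DOM_COLOR = "#77bbee"
_SEC_COLOR = "#225588"
_BAR_COLOR = "#cc4444"


def freq_peak_plot(results, chrom: str, sample: str, ax=None):
    """Plot one chromosome of one sample from a fitted scan.

    Parameters
    ----------
    results : PloidyScanResults
    chrom, sample
        Which chromosome and sample to draw.

    Returns
    -------
    matplotlib Figure.
    """
    model = results.model
    sel = model.variants["CHROM"].to_numpy() == chrom
    if not sel.any():
        raise ValueError(f"no variants on chromosome {chrom!r}")
    if sample not in model.samples:
        raise KeyError(f"unknown sample {sample!r}")
    pos = model.variants.loc[sel, "POS"].to_numpy()
    dom = model.dominant.loc[sel, sample].to_numpy(dtype=float)
    sec = model.secondary.loc[sel, sample].to_numpy(dtype=float)

    if ax is None:
        fig, (ax, ax_hist) = plt.subplots(
            1, 2, figsize=(10, 3.2), sharey=True,
            gridspec_kw={"width_ratios": [5, 1], "wspace": 0.04})
    else:
        fig = ax.figure
        ax_hist = None

    kbp = pos / 1000.0
    ax.plot(kbp, dom, ".", color=_DOM_COLOR, ms=3, rasterized=True)
    ax.plot(kbp, sec, ".", color=_SEC_COLOR, ms=3, rasterized=True)

    coords = results.windows.coords
    wsel = coords["CHROM"].to_numpy() == chrom
    idx = np.nonzero(wsel)[0]
    for i in idx:
        for wt in (results.windows, results.windows_secondary):
            peak = wt.peaks[sample].iloc[i]
            if not np.isnan(peak):
                ax.hlines(peak, coords["START"].iloc[i] / 1000.0,
                          coords["END"].iloc[i] / 1000.0,
                          color=_BAR_COLOR, lw=2, zorder=3)

    for e in (1 / 5, 1 / 4, 1 / 3, 1 / 2, 2 / 3, 3 / 4, 4 / 5):
        ax.axhline(e, color="0.85", lw=0.6, zorder=0)
    ax.set_xlabel("position (kbp)")
    ax.set_ylabel("allele balance")
    ax.set_ylim(0, 1)
    ax.set_title(f"{sample} — {chrom}")

    if ax_hist is not None:
        width = results.windows.bin_width
        edges = bin_edges(width)
        vals = np.concatenate([dom[~np.isnan(dom)], sec[~np.isnan(sec)]])
        counts = bin_counts(vals, width)
        ax_hist.barh((edges[:-1] + edges[1:]) / 2.0, counts,
                     height=np.diff(edges), color=_DOM_COLOR,
                     edgecolor="none")
        ax_hist.set_xlabel("variants")
    return fig
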