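"""Per-gene expression profile plot.

Displays length-normalised average counts (reads on an exon divided by the
exon length) over time, one line per exon, one panel per condition.
"""

from __future__ import annotations

import numpy as np

from .io_counts import ExonCountDataset


def plot_gene_profiles(dataset: ExonCountDataset, ax_list=None):
    """Plot average counts (count / exon length) against time per condition.

    Returns the matplotlib figure.  Replicates at the same time are averaged.
    """
    import matplotlib.pyplot as plt

    conditions = np.unique(dataset.conditions)
    if ax_list is None:
        fig, ax_list = plt.subplots(
            1, len(conditions), figsize=(4 * len(conditions), 3), sharey=True
        )
        ax_list = np.atleast_1d(ax_list)
    else:
        fig = ax_list[0].figure

    for ax, g in zip(ax_list, conditions):
        mask = dataset.conditions == g
        times = np.unique(dataset.times[mask])
        for k in range(dataset.K):
            avg = [
                dataset.counts[mask & (dataset.times == t), k].mean()
                / dataset.exon_lengths[k]
                for t in times
            ]
            ax.plot(times, avg, marker="o", label=dataset.exon_ids[k])
        ax.set_title(f"{dataset.gene_id} (condition {g})")
        ax.set_xlabel("time")
    ax_list[0].set_ylabel("average count (reads / exon length)")
    ax_list[-1].legend(fontsize="small")
    fig.tight_layout()
    return fig
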