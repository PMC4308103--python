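"""Convenience plotting (requires matplotlib, installed via the ``plots`` extra)."""

from __future__ import annotations

from .pipeline import FORMS, SelectionSummary


def plot_variance_explained(summaries: list[SelectionSummary], path=None):
    """Grouped bars of mean out-of-sample adjusted R2 (+/- SD across test
    sets) per model form and experiment.  Returns the matplotlib Figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    summaries = [s for s in summaries if s.ra2_mean is not None]
    if not summaries:
        raise ValueError("no summaries with adjusted-R2 statistics")
    x = np.arange(len(summaries))
    width = 0.27
    fig, ax = plt.subplots(figsize=(1.6 * len(summaries) + 2, 4))
    colors = {"simple": "#c0392b", "additive": "#e67e22", "interaction": "#f1c40f"}
    for k, form in enumerate(FORMS):
        means = [s.ra2_mean[form] for s in summaries]
        sds = [s.ra2_sd[form] for s in summaries]
        ax.bar(x + (k - 1) * width, means, width, yerr=sds, capsize=2,
               label=form, color=colors[form])
    ax.set_xticks(x)
    ax.set_xticklabels([s.experiment_id for s in summaries], rotation=30, ha="right")
    ax.set_ylabel("fraction of phenotypic variance (adjusted $R^2$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
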