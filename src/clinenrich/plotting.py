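"""Static scatterplot export for 2D sample embeddings."""

from __future__ import annotations

from .cohort_selection import ClusterAssignment, Subcohort
from .embedding import Embedding2D


def plot_embedding(
    emb: Embedding2D,
    cohort: Subcohort | None = None,
    assignment: ClusterAssignment | None = None,
    ax=None,
):
    """Scatter the embedding; highlight a subcohort or color clusters.

    Returns the matplotlib Axes so callers can adjust or save it.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    x, y = emb.coords[:, 0], emb.coords[:, 1]
    if assignment is not None:
        ax.scatter(x, y, c=assignment.labels, cmap="tab10", s=14)
    else:
        ax.scatter(x, y, c="0.6", s=14, label="population")
    if cohort is not None:
        members = set(cohort.member_ids)
        sel = [i for i, s in enumerate(emb.sample_ids) if s in members]
        ax.scatter(x[sel], y[sel], c="crimson", s=22, label="subcohort")
        ax.legend(loc="best", frameon=False)
    ax.set_xlabel("embedding x")
    ax.set_ylabel("embedding y")
    return ax
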