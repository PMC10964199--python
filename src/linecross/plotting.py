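"""Ternary plot of per-dataset architecture proportions (convenience)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["ternary_architecture_plot"]

# vertices: additive (top), epistatic (lower left), dominance (lower right)
_V_ADD = np.array([0.5, np.sqrt(3) / 2])
_V_EPI = np.array([0.0, 0.0])
_V_DOM = np.array([1.0, 0.0])


def ternary_architecture_plot(summaries, ax=None, **scatter_kwargs):
    """Scatter informative datasets in the additive/epistatic/dominance simplex.

    ``summaries`` is the summary table produced by the batch pipeline (a
    DataFrame with prop_additive/prop_dominance/prop_epistatic columns) or
    any sequence of (additive, dominance, epistatic) triples.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    if hasattr(summaries, "columns"):
        table = summaries[summaries["informative"].astype(bool)]
        props = table[["prop_additive", "prop_dominance", "prop_epistatic"]].to_numpy()
    else:
        props = np.asarray(list(summaries), dtype=float)
    xy = (
        props[:, [0]] * _V_ADD
        + props[:, [2]] * _V_EPI
        + props[:, [1]] * _V_DOM
    )
    scatter_kwargs.setdefault("s", 12)
    scatter_kwargs.setdefault("alpha", 0.35)
    ax.scatter(xy[:, 0], xy[:, 1], **scatter_kwargs)
    tri = np.array([_V_EPI, _V_DOM, _V_ADD, _V_EPI])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    ax.text(*_V_ADD + [0, 0.03], "additive", ha="center")
    ax.text(*_V_EPI + [-0.02, -0.05], "epistatic", ha="right")
    ax.text(*_V_DOM + [0.02, -0.05], "dominance", ha="left")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
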