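"""Optional matplotlib views of the distributional analyses.

Plain working plots of the conditional accuracy functions and delta plots;
matplotlib is imported lazily so the rest of the package has no hard
dependency on it.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_caf", "plot_delta"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_caf(group_caf: pd.DataFrame, ax=None):
    """Accuracy by RT bin, one line per (group,) condition."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots()
    keys = ["group", "condition"] if "group" in group_caf.columns else ["condition"]
    for name, sub in group_caf.groupby(keys):
        label = " / ".join(map(str, name)) if isinstance(name, tuple) else str(name)
        ax.plot(sub["mean_rt"], sub["accuracy"], marker="o", label=label)
    ax.set_xlabel("mean RT (ms)")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize="small")
    return ax


def plot_delta(delta: pd.DataFrame, ax=None, label=None):
    """Incongruent - congruent RT difference by decile."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots()
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.plot(delta["mean_rt"], delta["delta"], marker="o", label=label)
    ax.set_xlabel("mean RT (ms)")
    ax.set_ylabel("delta (ms)")
    if label:
        ax.legend(fontsize="small")
    return ax
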