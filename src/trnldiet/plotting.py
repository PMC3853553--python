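"""Simple figures: NMDS ordination scatter and monthly composition bars."""

from __future__ import annotations

import pandas as pd


def plot_ordination(coordinates: pd.DataFrame, grouping: dict, path) -> None:
    """Scatter of a 2-D NMDS configuration, one marker style per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    groups = sorted(set(grouping.values()))
    markers = ["o", "s", "^", "D", "v"]
    for i, g in enumerate(groups):
        ids = [s for s in coordinates.index if grouping[s] == g]
        sub = coordinates.loc[ids]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=g, marker=markers[i % len(markers)])
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(coordinates.columns[0])
    ax.set_ylabel(coordinates.columns[1])
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_monthly(monthly: pd.DataFrame, path) -> None:
    """Stacked bars of monthly relative presence frequencies."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = monthly.plot(kind="bar", stacked=True, figsize=(8, 4), width=0.8)
    ax.set_ylabel("relative frequency of presence")
    ax.set_xlabel("month")
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left", frameon=False)
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
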