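"""van Krevelen diagrams for descriptor, enrichment and decay-rate tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def van_krevelen(
    desc: pd.DataFrame,
    color: pd.Series | str = "class4",
    size: pd.Series | None = None,
    path: str | Path | None = None,
    title: str = "",
):
    """H/C vs O/C scatter, colored by a class column or a numeric series.

    ``color`` may be the name of a categorical column of ``desc`` (one color
    per level) or a numeric Series aligned to ``desc.index`` (continuous
    colormap, e.g. enrichment percent or decay rate).
    """
    fig, ax = plt.subplots(figsize=(5, 4.2))
    s = 12 if size is None else 8 + 40 * (size / size.max())
    if isinstance(color, str):
        for level, sub in desc.groupby(color):
            sel = None if size is None else s.loc[sub.index]
            ax.scatter(sub["o_to_c"], sub["h_to_c"], s=12 if sel is None else sel, label=str(level), alpha=0.6)
        ax.legend(fontsize=6, loc="upper right")
    else:
        common = desc.index.intersection(color.index)
        sub = desc.loc[common]
        sc = ax.scatter(
            sub["o_to_c"], sub["h_to_c"], c=color.loc[common], s=12, cmap="viridis", alpha=0.7
        )
        fig.colorbar(sc, ax=ax)
    ax.set_xlabel("O/C")
    ax.set_ylabel("H/C")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
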