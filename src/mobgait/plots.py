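"""Plain plotting helpers (correlation heatmap, group profiles)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def correlation_heatmap(correlations: pd.DataFrame, group: str, ax=None):
    """Heatmap of the per-group Spearman grid (long-format input)."""
    sub = correlations[correlations["group"] == group]
    grid = sub.pivot(index="feature_a", columns="feature_b", values="rho")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * grid.shape[1] + 3, 0.5 * grid.shape[0] + 2))
    im = ax.imshow(grid.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(np.arange(grid.shape[1]), grid.columns, rotation=45, ha="right")
    ax.set_yticks(np.arange(grid.shape[0]), grid.index)
    ax.set_title(f"Spearman correlations - {group}")
    plt.colorbar(im, ax=ax, label="rho")
    ax.figure.tight_layout()
    return ax


def group_medians_bar(table: pd.DataFrame, feature: str, group_col: str = "group", ax=None):
    """Bar chart of per-group medians of one feature."""
    med = table.groupby(group_col, sort=False)[feature].median()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(med.index, med.to_numpy())
    ax.set_ylabel(feature)
    ax.figure.tight_layout()
    return ax
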