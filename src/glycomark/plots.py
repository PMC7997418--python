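"""Basic figure exports: volcano plot and H-score boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def volcano_plot(volcano: pd.DataFrame, path: str | Path,
                 fold_threshold: float = 1.5, alpha: float = 0.05) -> Path:
    """Volcano of log2 fold-change vs -log10 p with the calling thresholds."""
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = volcano["call"].map({"up": "#c0392b", "down": "#2471a3",
                                  "ns": "#aaaaaa"})
    ax.scatter(volcano["log2_fc"], -np.log10(volcano["p_value"].clip(lower=1e-300)),
               c=colors, s=14)
    lf = np.log2(fold_threshold)
    for x in (-lf, lf):
        ax.axvline(x, ls="--", lw=0.8, color="k")
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, color="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def hscore_boxplot(scored: pd.DataFrame, path: str | Path,
                   by: str = "component") -> Path:
    """Boxplots of H-scores grouped by ligand and a second factor."""
    fig, ax = plt.subplots(figsize=(7, 5))
    groups = scored.groupby(["ligand", by])["h_score"]
    labels, data = zip(*[(f"{l}\n{c}", v.to_numpy()) for (l, c), v in groups])
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("H-score")
    ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
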