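"""Optional distribution figures (global r by group; selected-node measures)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort import GROUPS, Cohort
from .measures import global_assortativity
from .ranking import NodalFeatureMatrix, RankingResult


def plot_global_assortativity(cohort: Cohort, path: str | Path) -> None:
    """Box plots of per-subject global r, split by group and modality."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), sharey=True)
    for ax, (modality, title) in zip(axes, (("structural", "sNET"), ("functional", "fNET"))):
        data, labels = [], []
        for g in GROUPS:
            subs = cohort.of_group(g)
            if not subs:
                continue
            try:
                data.append([global_assortativity(s.network(modality)) for s in subs])
            except Exception:
                continue
            labels.append(g)
        if data:
            ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_title(title)
    axes[0].set_ylabel("global assortativity r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_selected_nodes(features: NodalFeatureMatrix, ranking: RankingResult,
                        path: str | Path) -> None:
    """Per-group distributions of the measure at each selected node."""
    sel = ranking.selected
    if len(sel) == 0:
        return
    fig, axes = plt.subplots(1, len(sel), figsize=(2.2 * len(sel), 3.0), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, v in zip(axes, sel):
        data = [features.values[features.groups == g, int(v)]
                for g in GROUPS if (features.groups == g).any()]
        labels = [g for g in GROUPS if (features.groups == g).any()]
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(f"node {int(v)}\np={ranking.p_values[int(v)]:.2g}")
    axes[0].set_ylabel(f"{features.measure} ({features.modality})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
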