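"""Optional figures for cohort summaries (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt


def plot_variant_type_distribution(proportions: Mapping[str, float], path) -> None:
    """Bar chart of variant-type percentages."""
    fig, ax = plt.subplots(figsize=(5, 3))
    labels = list(proportions)
    ax.bar(labels, [proportions[k] for k in labels], color="#4878b0")
    ax.set_ylabel("% of reported variants")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_event_type_counts(counts: Mapping[str, int], path) -> None:
    """Bar chart of splice-event counts per taxonomy type."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(list(counts), list(counts.values()), color="#d1a154")
    ax.set_ylabel("unique events")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_psi_vs_controls(
    carrier_psi: Sequence[float], control_psi: Sequence[float], path
) -> None:
    """Violin contrast of carrier event PSI against the control pool."""
    fig, ax = plt.subplots(figsize=(4, 3))
    data = [list(control_psi), list(carrier_psi)]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks([1, 2], labels=["controls", "carriers"])
    ax.set_ylabel("PSI")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
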