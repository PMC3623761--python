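"""Minimal TSV-driven plots: average age profiles and PCA scatter."""

from __future__ import annotations

import numpy as np


def _age_colors(groups):
    palette = {"prenatal": "tab:green", "infant": "tab:blue", "older": "tab:red"}
    return [palette[g] for g in groups]


def plot_age_profile(ages, values, path, ylabel="mean density"):
    """Scatter of a per-sample mean profile against age, colored by age group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .trajectory import assign_age_groups

    ages = np.asarray(ages, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(ages, values, c=_age_colors(assign_age_groups(ages)), s=25)
    ax.set_xlabel("age (years)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(pca, groups, path):
    """PC1/PC2 scatter of a cohort-structure PCA, colored by age group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(pca.scores[:, 0], pca.scores[:, 1], c=_age_colors(groups), s=30)
    vf = pca.variance_fractions
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.0f}% of variance)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.0f}% of variance)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
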