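"""Optional report figures (tables are the contract, figures are not)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .vb_stats import VbProfile  # noqa: E402

__all__ = ["vb_polar_plot", "expansion_heatmap"]


def vb_polar_plot(profile: VbProfile, path, reference: VbProfile | None = None):
    """Polar bar plot of per-family tube-relative frequencies."""
    fams = profile.families
    vals = profile.tube_relative(fill_missing=0.0).to_numpy()
    theta = np.linspace(0, 2 * np.pi, len(fams), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    ax.bar(theta, vals, width=2 * np.pi / len(fams) * 0.8, alpha=0.8)
    if reference is not None:
        ax.bar(
            theta, reference.tube_relative(fill_missing=0.0).to_numpy(),
            width=2 * np.pi / len(fams) * 0.8, fill=False, edgecolor="k",
        )
    ax.set_xticks(theta)
    ax.set_xticklabels(fams, fontsize=6)
    ax.set_title(f"{profile.scope} Vbeta tube-relative frequencies")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def expansion_heatmap(profiles: dict[int, VbProfile], path):
    """Clusters x families heatmap of tube-relative frequencies."""
    ids = sorted(profiles)
    fams = profiles[ids[0]].families
    mat = np.vstack(
        [profiles[k].tube_relative(fill_missing=0.0).to_numpy() for k in ids]
    )
    fig, ax = plt.subplots(figsize=(10, 0.4 * len(ids) + 2))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(ids)), [f"cluster {k}" for k in ids], fontsize=7)
    ax.set_xticks(range(len(fams)), fams, rotation=90, fontsize=6)
    fig.colorbar(im, label="tube-relative frequency")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
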