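"""Optional matplotlib renderings of the standard SIP summary figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gradient import GradientProfile, PoolingScheme, normalize_profile

__all__ = ["plot_gradient_profiles", "plot_activity_heatmap"]


def plot_gradient_profiles(
    labeled: GradientProfile,
    control: GradientProfile,
    scheme: PoolingScheme | None = None,
    path: str | None = None,
):
    """Line chart of percent-of-gradient DNA vs density for both gradients,
    with pooled-fraction windows shaded."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for profile, color, marker in ((control, "black", "o"), (labeled, "gray", "s")):
        frame = normalize_profile(profile)
        ax.plot(
            frame["density_g_ml"], frame["dna_percent"],
            color=color, marker=marker, mfc=color if profile is control else "white",
            label=profile.treatment,
        )
    if scheme is not None:
        cmap = plt.get_cmap("tab10")
        for i, w in enumerate(scheme.windows):
            ax.axvspan(w.low, w.high, alpha=0.15, color=cmap(i), label=w.name)
    ax.set_xlabel("buoyant density (g/ml)")
    ax.set_ylabel("% of gradient DNA")
    ax.invert_xaxis()  # light fractions left, like a top-first reading
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_activity_heatmap(
    matrix: pd.DataFrame, annotations: pd.DataFrame | None = None, path: str | None = None
):
    """Taxa x dense-pool heatmap of activity A with significance symbols."""
    fig, ax = plt.subplots(
        figsize=(1.2 * matrix.shape[1] + 3, 0.3 * matrix.shape[0] + 2)
    )
    vmax = np.nanmax(np.abs(matrix.to_numpy())) or 1.0
    im = ax.imshow(matrix.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=7)
    if annotations is not None:
        for i in range(matrix.shape[0]):
            for j in range(matrix.shape[1]):
                sym = annotations.iloc[i, j]
                if sym:
                    ax.text(j, i, sym, ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="activity A (percentage points)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
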