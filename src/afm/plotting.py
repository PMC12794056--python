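"""Box-and-whisker comparison figure for the tile metric."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import GroupComparisonResult


def plot_comparison(
    result: GroupComparisonResult,
    tile_frame: pd.DataFrame,
    out_path,
    title: str = "Peritubular fibrosis per tile",
) -> Path:
    """Horizontal box plots of the per-tile fibrotic fraction by tubule class.

    The metric axis runs over [0, 1] fractions, 1.0 corresponding to 100%
    fibrotic tile area. Medians and interquartile ranges come straight from
    the per-tile table; the annotated p-values are the group comparison's.
    """
    groups = [
        tile_frame.loc[tile_frame["tubule_class"] == cls, "fibrotic_fraction"]
        for cls in ("distal", "proximal")
    ]
    fig, ax = plt.subplots(figsize=(6, 2.8))
    ax.boxplot(
        [g.to_numpy() for g in groups],
        orientation="horizontal",
        tick_labels=[f"distal (n={len(groups[0])})", f"proximal (n={len(groups[1])})"],
        widths=0.6,
    )
    ax.set_xlim(0, 1)
    ax.set_xlabel("fibrotic metric (1.0 = 100%)")
    ax.set_title(
        f"{title}\n t: p={result.p_t:.3g} ({result.t_flavor}), "
        f"U: p={result.p_u:.3g} ({result.u_method})",
        fontsize=9,
    )
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
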