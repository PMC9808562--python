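"""Figure exports: ECS histograms with fitted components, density scatters.

Every PNG is written alongside a CSV of the plotted numbers so figures can
be regenerated or restyled without rerunning the analysis.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .detect import EventTable
from .ecs import ECSFitResult


def ecs_histogram(fit: ECSFitResult, path) -> None:
    """ECS histogram with the fitted Gaussian components overlaid."""
    path = Path(path)
    centers = 0.5 * (fit.bin_edges[:-1] + fit.bin_edges[1:])
    width = fit.bin_edges[1] - fit.bin_edges[0]
    xs = np.linspace(fit.bin_edges[0], fit.bin_edges[-1], 400)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(centers, fit.bin_counts, width=width, color="0.8", edgecolor="0.5", label="events")
    for c in fit.components:
        ax.plot(xs, c.amplitude * np.exp(-0.5 * ((xs - c.mean) / c.sd) ** 2),
                label=f"{c.label}: {c.mean:.0f}")
    ax.plot(xs, fit.model(xs), "k--", lw=1, label="sum")
    ax.set_xlabel("ECS (pA·ms)")
    ax.set_ylabel("counts")
    ax.set_title(fit.sample_label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)

    curve = {"ecs": xs, "model": fit.model(xs)}
    for c in fit.components:
        curve[f"component_{c.label}"] = c.amplitude * np.exp(-0.5 * ((xs - c.mean) / c.sd) ** 2)
    pd.DataFrame(curve).to_csv(path.with_suffix(".curves.csv"), index=False)
    pd.DataFrame({"bin_center": centers, "count": fit.bin_counts}).to_csv(
        path.with_suffix(".hist.csv"), index=False
    )


def density_scatter(table: EventTable, path, component_column: str | None = None) -> None:
    """Peak current maximum vs dwell time scatter, coloured by local density
    (or by ECS component when ``component_column`` is given)."""
    path = Path(path)
    ev = table.events
    fig, ax = plt.subplots(figsize=(4.5, 4))
    if len(ev):
        x = ev["dwell_ms"].to_numpy()
        y = ev["peak_max_pA"].to_numpy()
        if component_column and component_column in ev:
            for comp, grp in ev.groupby(component_column):
                ax.scatter(grp["dwell_ms"], grp["peak_max_pA"], s=6, alpha=0.5, label=str(comp))
            ax.legend(fontsize=8)
        else:
            # 2-D histogram density as colour, the usual nanopore presentation
            h, xe, ye = np.histogram2d(x, y, bins=40)
            ix = np.clip(np.searchsorted(xe, x) - 1, 0, h.shape[0] - 1)
            iy = np.clip(np.searchsorted(ye, y) - 1, 0, h.shape[1] - 1)
            ax.scatter(x, y, c=h[ix, iy], s=6, cmap="viridis", alpha=0.7)
    ax.set_xlabel("dwell time (ms)")
    ax.set_ylabel("peak current maximum (pA)")
    ax.set_title(table.sample_label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    ev.to_csv(path.with_suffix(".csv"), index=False)
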