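"""Optional figures: hexagon scatter per zone and size-by-zone panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline import ZONE_ORDER

_SQ3_2 = np.sqrt(3.0) / 2.0
#: Hexagon outline: the six loci reachable at full receptor modulation.
_HEX_X = [0.0, _SQ3_2, _SQ3_2, 0.0, -_SQ3_2, -_SQ3_2, 0.0]
_HEX_Y = [1.0, 0.5, -0.5, -1.0, -0.5, 0.5, 1.0]


def hexagon_scatter(table: pd.DataFrame, out: str | Path,
                    achromatic_radius: float = 0.11) -> None:
    """One hexagon panel per elevational zone with species loci."""
    zones = [z for z in ZONE_ORDER if (table["zone"] == z).any()]
    fig, axes = plt.subplots(1, max(len(zones), 1),
                             figsize=(3.2 * max(len(zones), 1), 3.4))
    axes = np.atleast_1d(axes)
    for ax, zone in zip(axes, zones):
        sub = table[table["zone"] == zone]
        ax.plot(_HEX_X, _HEX_Y, color="0.4", lw=1)
        circle = plt.Circle((0, 0), achromatic_radius, fill=False,
                            color="red", lw=0.8)
        ax.add_patch(circle)
        ax.scatter(sub["x"], sub["y"], s=12, alpha=0.7)
        ax.set_title(f"{zone} (n={len(sub)})", fontsize=9)
        ax.set_aspect("equal")
        ax.set_xlim(-1.05, 1.05)
        ax.set_ylim(-1.1, 1.1)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def size_by_zone(table: pd.DataFrame, out: str | Path) -> None:
    """Flower-size (mm) box plot across the elevational zones."""
    zones = [z for z in ZONE_ORDER if (table["zone"] == z).any()]
    data = [table.loc[table["zone"] == z, "size_mm"] for z in zones]
    fig, ax = plt.subplots(figsize=(1.2 * len(zones) + 1.5, 3.2))
    ax.boxplot(data, tick_labels=zones)
    ax.set_ylabel("flower size (mm)")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
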