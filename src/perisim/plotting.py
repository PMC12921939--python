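"""Grayscale visual-field plots in the style of clinical 10-2 printouts.

Each location is drawn as a 2x2-degree tile shaded by sensitivity (dark =
low, light = high) with the numeric dB value overlaid, and the
physiological blind spot is marked as a gray oval outside the tested field
so the eye's laterality is visible at a glance (right eye: oval on the
right).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse, Rectangle

from .devices import to_octopus_equivalent
from .grid import blind_spot_position
from .zest import MeasuredField

__all__ = ["plot_field"]

#: Shading range in Octopus-equivalent dB: values at or below the low end
#: render black, at or above the high end white.
_SHADE_RANGE = (0.0, 35.0)


def plot_field(field: MeasuredField, mode: str = "raw",
               path: str | Path | None = None,
               ax: plt.Axes | None = None,
               offset: float = 14.0) -> plt.Axes:
    """Render one measured field as a grayscale tessellation.

    ``mode="raw"`` shows device-scale values; ``mode="equivalent"`` applies
    the harmonization rule (+14 dB, floor 0 stays 0) — only meaningful for
    the head-mounted device.  When ``path`` is given the figure is saved
    there and closed.
    """
    if mode not in ("raw", "equivalent"):
        raise ValueError("mode must be 'raw' or 'equivalent'")
    vals = field.sensitivity_db
    if mode == "equivalent":
        vals = np.asarray(to_octopus_equivalent(vals, offset))
    own_fig = ax is None
    if own_fig:
        _, ax = plt.subplots(figsize=(5.2, 4.2))
    lo, hi = _SHADE_RANGE
    for (x, y), v in zip(field.grid.xy, vals):
        shade = float(np.clip((v - lo) / (hi - lo), 0.0, 1.0))
        ax.add_patch(Rectangle((x - 1, y - 1), 2, 2, facecolor=str(shade),
                               edgecolor="0.7", linewidth=0.3))
        ax.text(x, y, f"{v:.0f}", ha="center", va="center", fontsize=6,
                color="black" if shade > 0.5 else "white")
    bx, by = blind_spot_position(field.eye)
    ax.add_patch(Ellipse((bx, by), 3.0, 5.0, facecolor="0.5",
                         edgecolor="none"))
    ax.set_xlim(-18, 18)
    ax.set_ylim(-12, 12)
    ax.set_aspect("equal")
    ax.set_xlabel("x [deg]")
    ax.set_ylabel("y [deg]")
    ax.set_title(f"{field.subject_id} {field.eye} — {field.device}"
                 f" ({mode})", fontsize=9)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        if own_fig:
            plt.close(ax.figure)
    return ax
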