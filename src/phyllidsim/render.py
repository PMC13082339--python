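"""Vector renders of tissue snapshots (matplotlib, SVG-friendly)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PolyCollection

from .tissue import Tissue

COLOR_FIELDS = ("merophyte", "zone", "tissue_type", "k_par", "k_per",
                "areal_growth", "anisotropy", "distance")

_ZONE_COLORS = {"attachment": "#8c8c8c", "proliferative": "#4daf4a",
                "differentiation": "#984ea3"}
_TYPE_COLORS = {"apical": "#e41a1c", "blade": "#a6d854", "midrib": "#377eb8",
                "attachment": "#8c8c8c"}


def render_snapshot(tissue: Tissue, color_by: str = "merophyte", path=None,
                    ax=None):
    """Draw one polygon per cell, colored by the requested field.

    Categorical fields (merophyte, zone, tissue_type) get deterministic
    discrete colors with a legend; scalar fields get a colormap with a
    colorbar.  Saves to `path` when given (any matplotlib format, e.g. SVG).
    """
    if color_by not in COLOR_FIELDS:
        raise ValueError(f"unknown color field {color_by!r}; "
                         f"options: {', '.join(COLOR_FIELDS)}")
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(5, 7))
    else:
        fig = ax.figure
    polys = [tissue.ring_coords(cid) for cid in sorted(tissue.cells)]
    cells = [tissue.cells[cid] for cid in sorted(tissue.cells)]

    if color_by in ("merophyte", "zone", "tissue_type"):
        if color_by == "merophyte":
            cmap = plt.get_cmap("tab20")
            vals = [c.merophyte_id for c in cells]
            colors = [cmap(v % 20) for v in vals]
            labels = {v: cmap(v % 20) for v in sorted(set(vals))}
            legend_title = "merophyte"
        elif color_by == "zone":
            colors = [_ZONE_COLORS[c.zone] for c in cells]
            labels = {z: col for z, col in _ZONE_COLORS.items()
                      if any(c.zone == z for c in cells)}
            legend_title = "zone"
        else:
            colors = [_TYPE_COLORS[c.tissue_type] for c in cells]
            labels = {z: col for z, col in _TYPE_COLORS.items()
                      if any(c.tissue_type == z for c in cells)}
            legend_title = "tissue type"
        pc = PolyCollection(polys, facecolors=colors, edgecolors="k",
                            linewidths=0.3)
        ax.add_collection(pc)
        handles = [plt.Rectangle((0, 0), 1, 1, fc=col) for col in labels.values()]
        ax.legend(handles, [str(k) for k in labels], title=legend_title,
                  loc="upper right", fontsize=6)
    else:
        if color_by == "k_par":
            vals = np.array([c.k_par for c in cells])
        elif color_by == "k_per":
            vals = np.array([c.k_per for c in cells])
        elif color_by == "areal_growth":
            vals = np.array([c.k_par + c.k_per for c in cells])
        elif color_by == "anisotropy":
            vals = np.array([abs(c.k_par - c.k_per) /
                             max(1e-12, c.k_par + c.k_per) for c in cells])
        else:  # distance
            from .quantify import distance_profiles
            prof = distance_profiles(tissue)
            vals = np.array([prof.loc[c.id, "distance"] for c in cells])
        pc = PolyCollection(polys, array=vals, cmap="viridis",
                            edgecolors="k", linewidths=0.3)
        ax.add_collection(pc)
        fig.colorbar(pc, ax=ax, label=color_by)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"t = {tissue.time:.2f} d")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        if own_fig:
            plt.close(fig)
    return ax
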