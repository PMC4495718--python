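"""Figure-style plots: packing heat maps and plane-intersection scatters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_heatmap", "plot_plane_intersections"]


def plot_heatmap(heatmap: dict, points=None, path=None):
    """Render a Voronoi neighbour-count heat map (optionally with MT centers)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    x, y, field = heatmap["x"], heatmap["y"], heatmap["field"]
    im = ax.pcolormesh(x, y, field, shading="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label="MTs within radius")
    if points is not None:
        points = np.asarray(points)
        ax.plot(points[:, 0], points[:, 1], "wo", mec="k", ms=5)
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.set_aspect("equal")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_plane_intersections(xy, threshold_nm: float = 10.0, crop_nm: float = 40.0,
                             path=None):
    """Scatter + 2D histogram of MT-vector intersections with the z-plane.

    The inset-style histogram is cropped to a ``crop_nm`` square centered
    on the origin.
    """
    xy = np.asarray(xy, dtype=float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4.5))
    ax1.scatter(xy[:, 0], xy[:, 1], s=12, alpha=0.7)
    circle = plt.Circle((0, 0), threshold_nm, fill=False, ls="--", color="r")
    ax1.add_patch(circle)
    ax1.set_xlabel("x (nm)")
    ax1.set_ylabel("y (nm)")
    ax1.set_aspect("equal")
    h = crop_nm / 2
    sel = (np.abs(xy[:, 0]) <= h) & (np.abs(xy[:, 1]) <= h)
    if sel.any():
        ax2.hist2d(xy[sel, 0], xy[sel, 1], bins=20,
                   range=[[-h, h], [-h, h]], cmap="magma")
    ax2.set_xlabel("x (nm)")
    ax2.set_ylabel("y (nm)")
    ax2.set_aspect("equal")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
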