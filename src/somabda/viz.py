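"""Optional matplotlib renders of a pipeline run (raw, rotated, contributions)."""

from __future__ import annotations

import numpy as np


def render_run(grid, rgrid, region, out_prefix) -> list[str]:
    """Write three PNG top views: source scan, rotated scan, volume contribution.

    Returns the written paths.  Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    panels = [
        ("raw", grid.z, (grid.x0, grid.x[-1], grid.y0, grid.y[-1]), "height (um)"),
        ("rotated", rgrid.z, (rgrid.xlevels[0], rgrid.xlevels[-1], rgrid.ylevels[0], rgrid.ylevels[-1]), "height (um)"),
    ]
    contrib = np.where(region.mask, rgrid.z, np.nan)
    total = np.nansum(contrib)
    if total > 0:
        contrib = contrib / total
    panels.append(("volume", contrib, panels[1][2], "fraction of soma volume"))
    for name, data, extent, label in panels:
        fig, ax = plt.subplots(figsize=(4.2, 4))
        im = ax.imshow(data, origin="lower", extent=extent, cmap="viridis")
        fig.colorbar(im, ax=ax, label=label)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
        ax.set_title(name)
        path = f"{out_prefix}_{name}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
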