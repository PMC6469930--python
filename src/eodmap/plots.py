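"""Small plotting helpers (rate maps, triggered averages, egocentric maps)."""

from __future__ import annotations

import numpy as np

from .egocentric import EgocentricMap
from .spatial import OccupancyGrid, RateMap
from .triggered import TriggeredAverage

__all__ = ["plot_rate_map", "plot_triggered_average", "plot_egocentric_map"]


def plot_rate_map(rmap: RateMap, occ: OccupancyGrid, ax=None):
    """Firing-rate map, clipped for display; excluded bins shown in gray."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    shown = np.where(occ.included, rmap.display, np.nan)
    m = ax.pcolormesh(occ.x_edges, occ.y_edges, shown, shading="flat", cmap="viridis")
    ax.set_facecolor("0.8")
    ax.set_aspect("equal")
    ax.set_title(f"max FR/bin = {rmap.max_fr:.2f} Hz")
    plt.colorbar(m, ax=ax, label="Hz")
    return ax


def plot_triggered_average(ta: TriggeredAverage, ax=None, **kw):
    """Mean +/- SEM of a spike-triggered average against lag."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(ta.lags, ta.mean, **kw)
    ax.fill_between(ta.lags, ta.mean - ta.sem, ta.mean + ta.sem, alpha=0.3)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel(ta.variable or "covariate")
    return ax


def plot_egocentric_map(emap: EgocentricMap, ax=None):
    """Landmark-presence probability around the fish (head up, at the origin)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    shown = np.where(emap.excluded, np.nan, emap.probability)
    half = emap.element_cm / 2
    extent = [emap.ego_x[0] - half, emap.ego_x[-1] + half,
              emap.ego_y[0] - half, emap.ego_y[-1] + half]
    m = ax.imshow(shown, origin="lower", extent=extent, cmap="viridis",
                  vmin=0, vmax=1)
    ax.plot(0, 0, "w^", ms=8)
    ax.set_xlabel("left - right (cm)")
    ax.set_ylabel("posterior - anterior (cm)")
    plt.colorbar(m, ax=ax, label="P(landmark | spike)")
    return ax
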