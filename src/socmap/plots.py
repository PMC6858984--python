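"""Small matplotlib helpers for quicklooks and variogram diagnostics."""

from __future__ import annotations

import numpy as np

from .geodata import Raster
from .variogram import EmpiricalVariogram, VariogramModel

__all__ = ["plot_variogram", "raster_quicklook"]


def plot_variogram(ev: EmpiricalVariogram, vm: VariogramModel | None, path) -> None:
    """Empirical semivariogram points with the fitted model curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    lags, gam, counts = ev.nonempty()
    ax.scatter(lags, gam, s=np.sqrt(counts), c="k", label="empirical")
    if vm is not None:
        h = np.linspace(0, ev.max_lag, 200)
        ax.plot(h, vm(h), "r-", label=f"{vm.family} fit")
    ax.set_xlabel("lag distance (m)")
    ax.set_ylabel("semivariance")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def raster_quicklook(r: Raster, path, cmap: str = "viridis", title: str | None = None) -> None:
    """PNG rendering of a raster (row 0 south, so origin='lower')."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(r.values, origin="lower", cmap=cmap,
                   extent=[r.x_origin, r.x_origin + r.n_cols * r.cell_size,
                           r.y_origin, r.y_origin + r.n_rows * r.cell_size])
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
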