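"""Normalized difference vegetation index and its association with SOC.

NDVI = (NIR - RED) / (NIR + RED) per cell from surface-reflectance bands
(already atmospherically corrected); cells where both bands are zero, or
either is nodata, propagate as nodata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .geodata import Raster, SampleSite

__all__ = ["NdviResult", "compute_ndvi", "correlate_ndvi_soc", "annual_composite"]


@dataclass
class NdviResult:
    ndvi: Raster
    stats: dict[str, float]
    soc_correlation: tuple[float, int] | None = None  # (Pearson r, n)


def compute_ndvi(nir: Raster, red: Raster) -> NdviResult:
    """Per-cell NDVI from co-registered NIR and RED reflectance rasters."""
    if not nir.same_grid(red):
        raise ValueError("NIR and RED rasters must share grid geometry")
    a = nir.values
    b = red.values
    if np.nanmin(a) < 0 or np.nanmin(b) < 0:
        raise ValueError("reflectances must be >= 0")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (a - b) / denom
    vals = np.where(denom == 0, np.nan, vals)
    out = nir.copy_with(vals)
    ok = ~np.isnan(vals)
    stats = {
        "min": float(np.min(vals[ok])),
        "max": float(np.max(vals[ok])),
        "mean": float(np.mean(vals[ok])),
    } if ok.any() else {"min": np.nan, "max": np.nan, "mean": np.nan}
    return NdviResult(out, stats)


def correlate_ndvi_soc(
    ndvi: Raster, sites: Sequence[SampleSite]
) -> tuple[float, int, pd.DataFrame]:
    """Pearson correlation of nearest-cell NDVI with site SOC (A horizon).

    Returns (r, n, pairs) where ``pairs`` is the plotted table of
    (site_id, ndvi, soc_a).
    """
    xs = np.array([s.x for s in sites])
    ys = np.array([s.y for s in sites])
    nd = ndvi.sample(xs, ys)
    soc = np.array([s.soc_a for s in sites])
    ok = ~np.isnan(nd)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 sites with valid NDVI; correlation undefined")
    r, _ = pearsonr(nd[ok], soc[ok])
    pairs = pd.DataFrame({
        "site_id": [s.site_id for s, m in zip(sites, ok) if m],
        "ndvi": nd[ok],
        "soc_a": soc[ok],
    })
    return float(r), int(ok.sum()), pairs


def annual_composite(monthly: Sequence[Raster], method: str = "mean") -> Raster:
    """Composite monthly NDVI rasters into one annual surface.

    ``method`` is "mean" (per-cell mean over valid months, the default) or
    "max" (maximum-value compositing).  Cells with no valid month stay
    nodata.
    """
    if not monthly:
        raise ValueError("need at least one monthly raster")
    first = monthly[0]
    for r in monthly[1:]:
        if not first.same_grid(r):
            raise ValueError("monthly rasters must share grid geometry")
    stack = np.stack([r.values for r in monthly])
    with np.errstate(invalid="ignore"):
        if method == "mean":
            out = np.nanmean(stack, axis=0)
        elif method == "max":
            out = np.nanmax(stack, axis=0)
        else:
            raise ValueError("method must be 'mean' or 'max'")
    return first.copy_with(out)
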