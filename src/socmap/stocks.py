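"""Soil organic carbon stock accounting.

Per-point stock of a soil layer (t C ha^-1):

    stock = T * SOC * B * (1 - C/100) / 10

with T the layer thickness (cm; 15 cm fixed for the A horizon, measured
for the O horizon), SOC the carbon concentration (g kg^-1), B the bulk
density (g cm^-3) and C the volume percentage of the > 2 mm fraction.

Landscape totals (Tg C) multiply the mean landscape stock density by the
landscape area (ha) and 1e-6; the park total is their sum.  Land-use
conversion scenarios reassign a landscape's area the per-hectare stock
density of its target landscape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geodata import LandUse, SampleSite

__all__ = [
    "A_HORIZON_THICKNESS_CM",
    "O_HORIZON_BULK_DENSITY",
    "StockRecord",
    "StockLedger",
    "point_stock",
    "stock_records",
    "landscape_summary",
    "total_stock",
    "scenario_stock",
]

A_HORIZON_THICKNESS_CM = 15.0
O_HORIZON_BULK_DENSITY = 0.15  # g cm^-3; organic surface layers are light


@dataclass(frozen=True)
class StockRecord:
    """Stock of one horizon at one site."""

    site_id: str
    horizon: str  # "A" or "O"
    thickness_cm: float
    stock_t_ha: float

    def __post_init__(self) -> None:
        if self.horizon not in ("A", "O"):
            raise ValueError("horizon must be 'A' or 'O'")
        if self.stock_t_ha < 0:
            raise ValueError("stock must be >= 0")


@dataclass
class StockLedger:
    """Landscape stock densities, areas and totals.

    ``mean_stocks`` maps (land_use, horizon) -> t C ha^-1;
    ``areas_ha`` maps land_use -> ha; ``totals`` holds Tg C per
    (land_use, horizon).
    """

    mean_stocks: dict[tuple[LandUse, str], float]
    areas_ha: dict[LandUse, float]
    totals: dict[tuple[LandUse, str], float]
    park_total: float

    def __post_init__(self) -> None:
        if abs(self.park_total - sum(self.totals.values())) > 1e-9:
            raise ValueError("park_total must equal the sum of landscape totals")

    @property
    def shares(self) -> dict[LandUse, float]:
        """Fraction of the park total per landscape (sums to 1)."""
        per_lu: dict[LandUse, float] = {}
        for (lu, _), tg in self.totals.items():
            per_lu[lu] = per_lu.get(lu, 0.0) + tg
        return {lu: tg / self.park_total for lu, tg in per_lu.items()}

    def density_t_ha(self, lu: LandUse) -> float:
        """Total (all-horizon) stock density of a landscape, t C ha^-1."""
        total_tg = sum(tg for (l, _), tg in self.totals.items() if l == lu)
        return total_tg * 1e6 / self.areas_ha[lu]

    def to_dict(self) -> dict:
        return {
            "mean_stocks_t_ha": {f"{lu.value}/{h}": v
                                 for (lu, h), v in self.mean_stocks.items()},
            "areas_ha": {lu.value: a for lu, a in self.areas_ha.items()},
            "totals_tg": {f"{lu.value}/{h}": v for (lu, h), v in self.totals.items()},
            "park_total_tg": self.park_total,
            "shares": {lu.value: s for lu, s in self.shares.items()},
        }


def point_stock(thickness_cm: float, soc_g_kg: float, bulk_density_g_cm3: float,
                coarse_pct: float) -> float:
    """Stock of one layer at one point, t C ha^-1."""
    if min(thickness_cm, soc_g_kg, bulk_density_g_cm3, coarse_pct) < 0:
        raise ValueError("all stock inputs must be >= 0")
    if coarse_pct > 100:
        raise ValueError("coarse_pct must be <= 100")
    return thickness_cm * soc_g_kg * bulk_density_g_cm3 * (1.0 - coarse_pct / 100.0) / 10.0


def stock_records(
    sites: Sequence[SampleSite],
    a_thickness_cm: float = A_HORIZON_THICKNESS_CM,
    o_bulk_density: float = O_HORIZON_BULK_DENSITY,
) -> list[StockRecord]:
    """A-horizon record for every site, O-horizon record where present.

    The coarse-fragment correction applies to the mineral A horizon only;
    the organic O layer is taken stone-free.
    """
    out: list[StockRecord] = []
    for s in sites:
        out.append(StockRecord(
            s.site_id, "A", a_thickness_cm,
            point_stock(a_thickness_cm, s.soc_a, s.bulk_density, s.coarse_pct),
        ))
        if s.o_thickness > 0:
            out.append(StockRecord(
                s.site_id, "O", s.o_thickness,
                point_stock(s.o_thickness, s.soc_o, o_bulk_density, 0.0),
            ))
    return out


def landscape_summary(
    records: Iterable[StockRecord], sites: Sequence[SampleSite]
) -> pd.DataFrame:
    """Summary statistics per (landscape, horizon).

    Columns: n, min, max, range, mean, median, sd (n-1), cv_pct, q1, q3,
    iqr.  Quartiles use linear interpolation.  Single-record groups get
    NaN sd/cv; empty landscapes are simply absent.
    """
    lu_by_id = {s.site_id: s.land_use for s in sites}
    rows = []
    for rec in records:
        if rec.site_id not in lu_by_id:
            raise ValueError(f"record for unknown site {rec.site_id}")
        rows.append({"land_use": lu_by_id[rec.site_id].value, "horizon": rec.horizon,
                     "stock": rec.stock_t_ha})
    df = pd.DataFrame(rows)
    out = []
    for (lu, h), grp in df.groupby(["land_use", "horizon"]):
        v = grp["stock"].to_numpy()
        q1, q3 = np.percentile(v, [25, 75])  # linear interpolation (type 7)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
        mean = float(v.mean())
        out.append({
            "land_use": lu, "horizon": h, "n": len(v),
            "min": float(v.min()), "max": float(v.max()),
            "range": float(v.max() - v.min()), "mean": mean,
            "median": float(np.median(v)), "sd": sd,
            "cv_pct": sd / mean * 100.0 if mean > 0 else np.nan,
            "q1": float(q1), "q3": float(q3), "iqr": float(q3 - q1),
        })
    return pd.DataFrame(out)


def total_stock(
    mean_stocks: Mapping[tuple[LandUse, str], float],
    areas: Mapping[LandUse, float],
) -> StockLedger:
    """Aggregate mean landscape stock densities to park totals (Tg C)."""
    totals: dict[tuple[LandUse, str], float] = {}
    for (lu, h), dens in mean_stocks.items():
        if lu not in areas:
            raise ValueError(f"no area configured for landscape {lu.value!r}")
        totals[(lu, h)] = dens * areas[lu] * 1e-6
    park_total = sum(totals.values())
    return StockLedger(dict(mean_stocks), dict(areas), totals, park_total)


def scenario_stock(ledger: StockLedger, conversion: Mapping[LandUse, LandUse]) -> float:
    """Park total (Tg C) after a land-use conversion scenario.

    Every converted landscape's area is assigned the all-horizon per-ha
    stock density of its target landscape; unconverted landscapes keep
    their own density.
    """
    for src, dst in conversion.items():
        if src not in ledger.areas_ha:
            raise ValueError(f"unknown source landscape {src!r}")
        if dst not in ledger.areas_ha:
            raise ValueError(f"unknown target landscape {dst!r}")
    new_total = 0.0
    for lu, area in ledger.areas_ha.items():
        target = conversion.get(lu, lu)
        new_total += ledger.density_t_ha(target) * area * 1e-6
    return new_total
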