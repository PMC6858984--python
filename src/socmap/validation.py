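"""Hold-out cross-validation harness and method comparison table.

The survey is split once into a training set and a stratified,
spatially separated validation set (395/45 with per-stratum quotas
17 forest / 7 grassland / 21 agriculture by default, minimum pairwise
validation spacing 1 km).  Each interpolation method is trained on the
training set and scored on the validation set with:

* ME   = mean(observed - predicted)
* RMSE = root mean squared error
* MRE  = RMSE / Delta, Delta = range of the validation observations
* R^2  = squared Pearson correlation of observed vs predicted

Methods are ranked by R^2 (descending), ties broken by RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .geodata import LandUse, Raster, SampleSite, site_coords, site_values
from .interpolate import (
    NeighborhoodSpec,
    ck_predict,
    ebk_predict,
    idw_predict,
    lpi_predict,
    ok_predict,
    rbf_predict,
)
from .variogram import VariogramModel

__all__ = [
    "HoldoutSplit",
    "CVReport",
    "MethodConfig",
    "split_holdout",
    "error_indices",
    "compare_methods",
    "default_method_suite",
]

DEFAULT_QUOTA = {LandUse.GRASSLAND: 7, LandUse.FOREST: 17, LandUse.AGRICULTURE: 21}


@dataclass(frozen=True)
class HoldoutSplit:
    """Disjoint train/validation partition of the survey."""

    train: list[SampleSite]
    validation: list[SampleSite]
    quota: dict[LandUse, int]
    min_separation: float
    separation_met: bool
    achieved_separation: float

    def __post_init__(self) -> None:
        ids_t = {s.site_id for s in self.train}
        ids_v = {s.site_id for s in self.validation}
        if ids_t & ids_v:
            raise ValueError("train and validation sets overlap")


@dataclass(frozen=True)
class MethodConfig:
    """One interpolation method plus its parameters for the comparison."""

    kind: str  # idw | lpi | rbf | ok | ck | ebk
    tag: str | None = None
    params: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.tag or self.kind


def default_method_suite() -> list[MethodConfig]:
    """The six standard engines with their default parameters."""
    return [
        MethodConfig("ck"),
        MethodConfig("ok"),
        MethodConfig("ebk"),
        MethodConfig("idw"),
        MethodConfig("lpi"),
        MethodConfig("rbf"),
    ]


@dataclass
class CVReport:
    """Per-method error indices (the method-comparison table)."""

    rows: pd.DataFrame  # columns: method, r2, rmse, me, mre

    def __post_init__(self) -> None:
        r = self.rows
        if (r["rmse"] < 0).any() or (r["mre"] < 0).any() or (r["r2"] > 1 + 1e-12).any():
            raise ValueError("invalid error indices in CV report")

    @property
    def ranking(self) -> list[str]:
        """Methods sorted by R^2 descending, ties broken by RMSE ascending."""
        ordered = self.rows.sort_values(["r2", "rmse"], ascending=[False, True])
        return list(ordered["method"])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def split_holdout(
    sites: Sequence[SampleSite],
    n_validation: int = 45,
    quota: dict[LandUse, int] | None = None,
    min_separation: float = 1000.0,
    seed: int = 0,
    max_attempts: int = 1000,
) -> HoldoutSplit:
    """Seeded stratified hold-out split with a spacing constraint.

    Draws stratified candidates until the validation points are pairwise
    at least ``min_separation`` apart, or ``max_attempts`` draws are
    exhausted, in which case the best-separated draw is returned with
    ``separation_met=False``.  Deterministic per seed.
    """
    quota = dict(quota or DEFAULT_QUOTA)
    if sum(quota.values()) != n_validation:
        raise ValueError("quota must sum to n_validation")
    by_stratum: dict[LandUse, list[int]] = {lu: [] for lu in quota}
    for i, s in enumerate(sites):
        if s.land_use in by_stratum:
            by_stratum[s.land_use].append(i)
    for lu, q in quota.items():
        if len(by_stratum[lu]) < q:
            raise ValueError(
                f"stratum {lu.value} has {len(by_stratum[lu])} sites < quota {q}"
            )
    rng = np.random.default_rng(seed)
    best_idx, best_sep = None, -np.inf
    for _ in range(max_attempts):
        chosen: list[int] = []
        for lu, q in quota.items():
            chosen.extend(rng.choice(by_stratum[lu], size=q, replace=False))
        coords = site_coords([sites[i] for i in chosen])
        sep = float(pdist(coords).min())
        if sep > best_sep:
            best_sep, best_idx = sep, chosen
        if sep >= min_separation:
            break
    val_set = set(best_idx)
    train = [s for i, s in enumerate(sites) if i not in val_set]
    validation = [sites[i] for i in sorted(val_set)]
    met = best_sep >= min_separation
    if not met:
        warnings.warn(
            f"validation spacing constraint not met: best {best_sep:.0f} m "
            f"< {min_separation:.0f} m after {max_attempts} attempts"
        )
    return HoldoutSplit(train, validation, quota, min_separation, met, best_sep)


def error_indices(observed, predicted) -> dict[str, float]:
    """ME, RMSE, MRE and R^2 of predictions against held-out observations."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and predicted must be equal-length vectors (n >= 2)")
    resid = obs - pred
    me = float(resid.mean())
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    delta = float(obs.max() - obs.min())
    if delta <= 0:
        raise ValueError("zero observed range; MRE undefined")
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("zero variance in observed or predicted; R^2 undefined")
    r, _ = pearsonr(obs, pred)
    return {"me": me, "rmse": rmse, "mre": rmse / delta, "r2": float(r ** 2)}


def _run_method(mc: MethodConfig, train, targets, vm, secondary, values, seed):
    kw = dict(mc.params)
    nb = kw.pop("nb", None) or NeighborhoodSpec()
    if mc.kind == "idw":
        return idw_predict(train, targets, nb=nb, values=values, **kw)
    if mc.kind == "lpi":
        return lpi_predict(train, targets, nb=nb, values=values, **kw)
    if mc.kind == "rbf":
        return rbf_predict(train, targets, nb=nb, values=values, **kw)
    if mc.kind == "ok":
        return ok_predict(train, targets, vm, nb=nb, values=values, **kw)
    if mc.kind == "ck":
        if not secondary:
            raise ValueError("cokriging requires secondary rasters")
        return ck_predict(train, secondary, targets, vm_primary=vm, nb=nb,
                          values=values, **kw)
    if mc.kind == "ebk":
        kw.setdefault("seed", seed)
        return ebk_predict(train, targets, nb=nb, values=values, **kw)
    raise ValueError(f"unknown method kind {mc.kind!r}")


def compare_methods(
    split: HoldoutSplit,
    method_configs: Sequence[MethodConfig],
    vm: VariogramModel,
    secondary: Sequence[Raster] = (),
    value_selector="soc_a",
    log_scale: bool = False,
    seed: int = 0,
) -> CVReport:
    """Train every configured method on the split and score it.

    With ``log_scale`` the interpolation and the error indices both live
    on the natural-log scale (the scale on which the variogram was
    modelled); otherwise raw values are used throughout.
    """
    if len(method_configs) < 1:
        raise ValueError("need at least one method")
    train_vals = site_values(split.train, value_selector)
    obs = site_values(split.validation, value_selector)
    if log_scale:
        if np.any(train_vals <= 0) or np.any(obs <= 0):
            raise ValueError("log scale requires positive values")
        train_vals = np.log(train_vals)
        obs = np.log(obs)
    targets = site_coords(split.validation)
    rows = []
    for mc in method_configs:
        try:
            surf = _run_method(mc, split.train, targets, vm, secondary,
                               train_vals, seed)
        except Exception as exc:
            raise RuntimeError(f"method {mc.label!r} failed: {exc}") from exc
        idx = error_indices(obs, surf.estimates)
        rows.append({"method": mc.label, **idx})
    df = pd.DataFrame(rows)[["method", "r2", "rmse", "me", "mre"]]
    return CVReport(df)
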