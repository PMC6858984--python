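"""Empirical semivariograms, parametric model fitting, spatial-dependence class.

The semivariance at lag h is half the mean squared difference between
values at locations separated by h.  Models are fitted by Cressie-weighted
least squares with weights N(h) / gamma_model(h)^2, which down-weights
sparse long-lag bins.

The exponential model is parameterised as

    gamma(h) = nugget + psill * (1 - exp(-h / range_param))

so the "effective range" (95% of the sill) is ~3 * range_param; it is
reported alongside so printed parameters are reusable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .geodata import SampleSite, site_coords, site_values

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "empirical_semivariogram",
    "cross_semivariogram",
    "fit_variogram_model",
    "nugget_sill_ratio",
]

FAMILIES = ("exponential", "spherical", "gaussian")


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned empirical semivariogram.

    Empty bins carry ``pair_counts == 0`` and ``gamma == NaN``.
    """

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    max_lag: float
    n_lags: int

    def __post_init__(self) -> None:
        lc = np.asarray(self.lag_centers, dtype=float)
        if np.any(np.diff(lc) <= 0):
            raise ValueError("lag_centers must be strictly increasing")
        g = np.asarray(self.gamma, dtype=float)
        if np.any(g[~np.isnan(g)] < 0):
            raise ValueError("gamma must be non-negative")

    def nonempty(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ok = self.pair_counts > 0
        return self.lag_centers[ok], self.gamma[ok], self.pair_counts[ok]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"lag": self.lag_centers, "gamma": self.gamma, "n_pairs": self.pair_counts}
        )


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram model (bounded families only)."""

    family: str
    nugget: float
    partial_sill: float
    range_param: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be >= 0")
        if not self.range_param > 0:
            raise ValueError("range_param must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def effective_range(self) -> float:
        """Distance at which the model reaches ~95% of the sill."""
        if self.family == "exponential":
            return 3.0 * self.range_param
        if self.family == "gaussian":
            return math.sqrt(3.0) * self.range_param
        return self.range_param  # spherical reaches the sill exactly

    def __call__(self, h) -> np.ndarray:
        """Model semivariance gamma(h); gamma(0) = 0, gamma(0+) -> nugget."""
        h = np.asarray(h, dtype=float)
        r = h / self.range_param
        if self.family == "exponential":
            struct = 1.0 - np.exp(-r)
        elif self.family == "gaussian":
            struct = 1.0 - np.exp(-(r ** 2))
        else:  # spherical
            struct = np.where(r < 1.0, 1.5 * r - 0.5 * r ** 3, 1.0)
        out = self.nugget + self.partial_sill * struct
        return np.where(h == 0.0, 0.0, out)

    def covariance(self, h) -> np.ndarray:
        """Covariance C(h) = sill - gamma(h) (nugget included at h = 0)."""
        h = np.asarray(h, dtype=float)
        return self.sill - self.__call__(h)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "nugget": float(self.nugget),
            "partial_sill": float(self.partial_sill),
            "sill": float(self.sill),
            "range_param": float(self.range_param),
            "effective_range": float(self.effective_range),
        }


def _bin_pairs(
    d: np.ndarray, sq: np.ndarray, max_lag: float, n_lags: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    # half-open bins [low, high)
    idx = np.floor(d / (max_lag / n_lags)).astype(int)
    ok = (idx >= 0) & (idx < n_lags)
    counts = np.bincount(idx[ok], minlength=n_lags)
    sums = np.bincount(idx[ok], weights=sq[ok], minlength=n_lags)
    dsums = np.bincount(idx[ok], weights=d[ok], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    # report the mean pair distance per occupied bin (midpoint if empty)
    mid = 0.5 * (edges[:-1] + edges[1:])
    centers = np.where(counts > 0, dsums / np.maximum(counts, 1), mid)
    return centers, gamma, counts


def empirical_semivariogram(
    sites: Sequence[SampleSite],
    value_selector="soc_a",
    max_lag: float | None = None,
    n_lags: int = 15,
    log_transform: bool = False,
) -> EmpiricalVariogram:
    """Empirical semivariogram over all unordered site pairs.

    gamma(h) = sum (z_i - z_j)^2 / (2 N(h)) within each half-open lag bin.
    ``max_lag`` defaults to half the maximum pairwise distance;
    ``log_transform`` applies a natural log to the values first.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    if isinstance(sites[0], SampleSite):
        coords = site_coords(sites)
        z = site_values(sites, value_selector)
    else:  # raw (n, 2) coordinates with an explicit value vector
        coords = np.asarray(sites, dtype=float)
        z = np.asarray(value_selector, dtype=float)
        if len(z) != len(coords):
            raise ValueError("value vector length must match coordinates")
    if log_transform:
        if np.any(z <= 0):
            raise ValueError("log transform requires strictly positive values")
        z = np.log(z)
    d = pdist(coords)
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    if not max_lag > 0:
        raise ValueError("max_lag must be > 0")
    if np.all(d >= max_lag):
        raise ValueError("all pairs lie beyond max_lag; variogram would be empty")
    sq = pdist(z[:, None], metric="sqeuclidean")
    centers, gamma, counts = _bin_pairs(d, sq, max_lag, n_lags)
    return EmpiricalVariogram(centers, gamma, counts, max_lag, n_lags)


def cross_semivariogram(
    coords: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    max_lag: float,
    n_lags: int = 15,
) -> "_RawVariogram":
    """Cross-semivariogram of two co-located variables.

    gamma_uv(h) = sum (u_i - u_j)(v_i - v_j) / (2 N(h)).  Used to fit the
    linear model of coregionalization for cokriging.  Negative bin values
    are legitimate here, so a plain container without the non-negativity
    invariant is returned.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    d = np.hypot(coords[iu, 0] - coords[ju, 0], coords[iu, 1] - coords[ju, 1])
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    prod = (u[iu] - u[ju]) * (v[iu] - v[ju])
    width = max_lag / n_lags
    idx = np.floor(d / width).astype(int)
    ok = (idx >= 0) & (idx < n_lags)
    counts = np.bincount(idx[ok], minlength=n_lags)
    sums = np.bincount(idx[ok], weights=prod[ok], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    centers = (np.arange(n_lags) + 0.5) * width
    return _RawVariogram(centers, gamma, counts, max_lag, n_lags)


@dataclass(frozen=True)
class _RawVariogram:
    """Cross-variogram container; gamma may be negative."""

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    max_lag: float
    n_lags: int

    def nonempty(self):
        ok = self.pair_counts > 0
        return self.lag_centers[ok], self.gamma[ok], self.pair_counts[ok]


def fit_variogram_model(
    ev: EmpiricalVariogram, family: str = "exponential"
) -> VariogramModel:
    """Fit a bounded variogram model by Cressie-weighted least squares.

    Minimises sum_k N_k (gamma_k / gamma_model(h_k) - 1)^2 over
    (nugget, partial sill, range) with non-negativity bounds, from five
    deterministic initialisations; the best-objective fit is returned.
    """
    lags, gam, counts = ev.nonempty()
    if len(lags) < 4:
        raise ValueError("need at least 4 non-empty lag bins to fit a model")
    if np.all(gam <= 0):
        raise ValueError("degenerate variogram: all semivariances are zero")
    s0 = float(np.mean(gam[-max(1, len(gam) // 3):]))  # plateau guess
    g1 = float(gam[0])
    hmax = float(lags[-1])
    starts = [
        (max(g1 * 0.5, 1e-8 * s0), max(s0 - g1 * 0.5, 1e-8 * s0), hmax / 3.0),
        (1e-8 * s0, s0, hmax / 3.0),
        (0.5 * s0, 0.5 * s0, hmax / 10.0),
        (max(g1, 1e-8 * s0), s0, float(lags[0])),
        (0.1 * s0, 0.9 * s0, hmax),
    ]
    sqrt_n = np.sqrt(counts.astype(float))

    def residuals(theta):
        m = VariogramModel(family, *np.maximum(theta, [0.0, 0.0, 1e-12]))
        gm = np.maximum(m(lags), 1e-12)
        return sqrt_n * (gam / gm - 1.0)

    # a range far beyond the observed lags is not identifiable; cap it so
    # the sill stays finite instead of drifting along the flat valley
    range_cap = 2.0 * hmax
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0=np.asarray(x0, float),
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, range_cap]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        cost = float(res.cost)
        if best is None or cost < best[0]:
            best = (cost, res.x)
    if best is None:
        raise RuntimeError("variogram fit failed from every initialisation")
    nug, psill, rng = best[1]
    nug, psill, rng = float(max(nug, 0.0)), float(max(psill, 0.0)), float(max(rng, 1e-9))
    # identifiability: structure saturated below the first observed lag is
    # indistinguishable from nugget variance; report it as nugget
    if rng < lags[0] / 3.0:
        nug += psill
        psill = 0.0
        rng = float(lags[0])
    return VariogramModel(family, nug, psill, rng)


def nugget_sill_ratio(m: VariogramModel) -> tuple[float, str]:
    """Nugget-to-sill ratio and the conventional dependence class.

    < 0.25 strong, 0.25-0.75 moderate, > 0.75 weak spatial dependence.
    """
    if m.sill <= 0:
        raise ValueError("sill is zero; nugget-sill ratio undefined")
    ratio = m.nugget / m.sill
    if ratio < 0.25:
        dependence = "strong"
    elif ratio <= 0.75:
        dependence = "moderate"
    else:
        dependence = "weak"
    return ratio, dependence
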