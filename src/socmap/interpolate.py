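"""Six spatial prediction engines sharing one interface.

Deterministic methods: inverse distance weighting (IDW), local polynomial
interpolation (LPI), radial basis functions (RBF, five bases).
Geostatistical methods: ordinary kriging (OK), ordinary cokriging (CK,
up to four secondary variables through a linear model of
coregionalization), and a simplified empirical Bayes kriging (EBK) that
propagates variogram-parameter uncertainty through a spectrum of
bootstrap-simulated variograms on overlapping spatial subsets.

Every engine maps (training sites, target locations) -> predicted values,
with a kriging variance where the theory defines one.  Training inputs
are either :class:`~socmap.geodata.SampleSite` sequences (with a value
selector) or raw coordinate/value arrays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import exp1, k0

from .geodata import Raster, SampleSite, site_coords, site_values
from .variogram import (
    VariogramModel,
    cross_semivariogram,
    fit_variogram_model,
)

__all__ = [
    "NeighborhoodSpec",
    "PredictionSurface",
    "CoverageError",
    "ConditioningError",
    "RBF_BASES",
    "idw_predict",
    "lpi_predict",
    "rbf_predict",
    "ok_predict",
    "ck_predict",
    "ebk_predict",
]

log = logging.getLogger(__name__)

RBF_BASES = (
    "thin_plate_spline",
    "spline_with_tension",
    "completely_regularized_spline",
    "multiquadric",
    "inverse_multiquadric",
)

_EULER = 0.5772156649015329
_SNAP = 1e-9  # metres; closer than this counts as coincident


class CoverageError(RuntimeError):
    """A target location has too few neighbours in range."""


class ConditioningError(RuntimeError):
    """A local linear system is singular (e.g. duplicate sites)."""


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Local search neighbourhood shared by all engines."""

    max_neighbors: int = 15
    min_neighbors: int = 4
    search_radius: float | None = None  # None = unlimited

    def __post_init__(self) -> None:
        if self.min_neighbors > self.max_neighbors:
            raise ValueError("min_neighbors must be <= max_neighbors")
        if self.search_radius is not None and not self.search_radius > 0:
            raise ValueError("search_radius must be > 0 when finite")


@dataclass
class PredictionSurface:
    """Predictions (and kriging variance, where defined) at target points."""

    estimates: np.ndarray
    variance: np.ndarray | None
    method_tag: str
    params_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variance is not None and np.any(self.variance < 0):
            raise ValueError("variance must be non-negative")

    @property
    def stderr(self) -> np.ndarray | None:
        return None if self.variance is None else np.sqrt(self.variance)


# ---------------------------------------------------------------------------
# shared plumbing

def _coerce_training(sites, values, value_selector):
    if len(sites) and isinstance(sites[0], SampleSite):
        coords = site_coords(sites)
        z = site_values(sites, value_selector) if values is None else np.asarray(values, float)
    else:
        coords = np.asarray(sites, dtype=float)
        if values is None:
            raise ValueError("values array required when sites is a coordinate array")
        z = np.asarray(values, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("training coordinates must be (n, 2)")
    if len(z) != len(coords):
        raise ValueError("values length must match number of sites")
    return coords, z


def _dedupe(coords: np.ndarray, z: np.ndarray, extra: np.ndarray | None = None):
    """Average sites sharing coordinates (within the snap tolerance)."""
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    keep, sums, counts, esums = [], [], [], []
    for i in order:
        if keep and np.hypot(*(coords[i] - coords[keep[-1]])) < _SNAP:
            sums[-1] += z[i]
            counts[-1] += 1
            if extra is not None:
                esums[-1] += extra[i]
        else:
            keep.append(i)
            sums.append(float(z[i]))
            counts.append(1)
            if extra is not None:
                esums.append(extra[i].astype(float).copy())
    counts = np.asarray(counts, float)
    if np.any(counts > 1):
        warnings.warn("duplicate site coordinates averaged before prediction")
    out_coords = coords[keep]
    out_z = np.asarray(sums) / counts
    out_extra = None if extra is None else np.asarray(esums) / counts[:, None]
    return out_coords, out_z, out_extra


def _neighborhoods(coords: np.ndarray, targets: np.ndarray, nb: NeighborhoodSpec):
    """Yield (distances, indices) of in-range neighbours per target."""
    tree = cKDTree(coords)
    k = min(nb.max_neighbors, len(coords))
    d, idx = tree.query(targets, k=k)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    uncovered = []
    rows = []
    for t in range(len(targets)):
        dt, it = d[t], idx[t]
        if nb.search_radius is not None:
            ok = dt <= nb.search_radius
            dt, it = dt[ok], it[ok]
        if len(dt) < max(1, nb.min_neighbors):
            uncovered.append(t)
        rows.append((dt, it))
    if uncovered:
        raise CoverageError(
            f"{len(uncovered)} target(s) with fewer than {nb.min_neighbors} "
            f"neighbours in range: indices {uncovered[:10]}"
        )
    return rows


def _as_targets(targets) -> np.ndarray:
    t = np.asarray(targets, dtype=float)
    if t.ndim == 1:
        t = t[None, :]
    if t.shape[1] != 2:
        raise ValueError("targets must be (m, 2) coordinates")
    return t


# ---------------------------------------------------------------------------
# inverse distance weighting

def idw_predict(
    sites, targets, beta: float = 2.0,
    nb: NeighborhoodSpec | None = None,
    value_selector="soc_a", values=None,
) -> PredictionSurface:
    """Inverse-distance-weighted prediction with power ``beta``.

    A target within the snap tolerance of a training site returns that
    site's value exactly.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    nb = nb or NeighborhoodSpec()
    coords, z = _coerce_training(sites, values, value_selector)
    coords, z, _ = _dedupe(coords, z)
    targets = _as_targets(targets)
    rows = _neighborhoods(coords, targets, nb)
    est = np.empty(len(targets))
    for t, (dt, it) in enumerate(rows):
        if dt[0] < _SNAP:
            est[t] = z[it[0]]
            continue
        w = dt ** (-beta)
        est[t] = np.dot(w, z[it]) / w.sum()
    return PredictionSurface(est, None, "idw", {"beta": beta, "neighborhood": nb})


# ---------------------------------------------------------------------------
# local polynomial interpolation

def _poly_terms(dx: np.ndarray, dy: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(dx)]
    if order >= 1:
        cols += [dx, dy]
    if order >= 2:
        cols += [dx * dx, dx * dy, dy * dy]
    return np.column_stack(cols)


def lpi_predict(
    sites, targets, order: int = 1,
    nb: NeighborhoodSpec | None = None,
    kernel_bandwidth: float | None = None,
    value_selector="soc_a", values=None,
) -> PredictionSurface:
    """Local polynomial interpolation (inexact, smoothing).

    At each target a polynomial of the given order in (x, y) is fitted to
    the neighbourhood by weighted least squares with kernel weights
    ``(1 - h/bandwidth)^2`` for h < bandwidth; the prediction is the fitted
    value at the target.  The default bandwidth is twice the distance to
    the farthest neighbour, giving the smooth, gently weighted local trend
    surface characteristic of the method (a tight bandwidth would turn it
    into a near-exact interpolator).  Rank-deficient local systems fall back to an
    order-0 (kernel-weighted mean) fit with a logged warning.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    nb = nb or NeighborhoodSpec()
    coords, z = _coerce_training(sites, values, value_selector)
    coords, z, _ = _dedupe(coords, z)
    targets = _as_targets(targets)
    rows = _neighborhoods(coords, targets, nb)
    n_terms = {0: 1, 1: 3, 2: 6}[order]
    est = np.empty(len(targets))
    for t, (dt, it) in enumerate(rows):
        bw = kernel_bandwidth if kernel_bandwidth is not None else 2.0 * float(dt.max()) * (1 + 1e-9)
        inside = dt < bw
        if not inside.any():
            raise CoverageError(f"target {t}: no neighbours inside bandwidth {bw}")
        dt, it = dt[inside], it[inside]
        w = (1.0 - dt / bw) ** 2
        w = np.maximum(w, 1e-12)
        dx = coords[it, 0] - targets[t, 0]
        dy = coords[it, 1] - targets[t, 1]
        scale = max(float(dt.max()), _SNAP)
        use_order = order
        if len(dt) < n_terms:
            use_order = 0
            log.warning("lpi: target %d has %d neighbours < %d terms; order-0 fallback",
                        t, len(dt), n_terms)
        while True:
            X = _poly_terms(dx / scale, dy / scale, use_order)
            sw = np.sqrt(w)
            coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], z[it] * sw, rcond=None)
            if rank == X.shape[1] or use_order == 0:
                if rank < X.shape[1]:
                    log.warning("lpi: degenerate order-0 system at target %d", t)
                break
            use_order -= 1
            log.warning("lpi: rank-deficient local system at target %d; "
                        "falling back to order %d", t, use_order)
        est[t] = coef[0]  # polynomial evaluated at the target (dx = dy = 0)
    return PredictionSurface(est, None, "lpi",
                             {"order": order, "kernel_bandwidth": kernel_bandwidth,
                              "neighborhood": nb})


# ---------------------------------------------------------------------------
# radial basis functions

def _rbf_phi(basis: str, r: np.ndarray, c: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if basis == "thin_plate_spline":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = r * r * np.log(r)
        return np.where(r > 0, out, 0.0)
    if basis == "multiquadric":
        return np.sqrt(r * r + c * c)
    if basis == "inverse_multiquadric":
        return 1.0 / np.sqrt(r * r + c * c)
    if basis == "spline_with_tension":
        x = c * r
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log(x / 2.0) + k0(x) + _EULER
        return np.where(x > 0, out, 0.0)
    if basis == "completely_regularized_spline":
        x = (c * r / 2.0) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log(x) + exp1(x) + _EULER
        return np.where(x > 0, out, 0.0)
    raise ValueError(f"unknown RBF basis {basis!r}; expected one of {RBF_BASES}")


def rbf_predict(
    sites, targets, basis: str = "completely_regularized_spline",
    shape_param: float | None = None,
    nb: NeighborhoodSpec | None = None,
    value_selector="soc_a", values=None,
) -> PredictionSurface:
    """Exact radial-basis-function interpolation on local neighbourhoods.

    The surface passes through every training value.  The thin-plate
    spline carries a full linear trend; the other bases a constant term.
    When ``shape_param`` is None it is optimised per neighbourhood by
    leave-one-out cross-validation (Rippa's shortcut: the LOO residual at
    node i is ``w_i / (A^-1)_ii``), which is what GIS implementations do
    with their "optimize parameter" default and what keeps the flatter
    kernels from oscillating.
    """
    nb = nb or NeighborhoodSpec()
    coords, z = _coerce_training(sites, values, value_selector)
    # duplicates make the system singular; identify the pair explicitly
    tree = cKDTree(coords)
    pairs = tree.query_pairs(_SNAP)
    if pairs:
        i, j = sorted(pairs)[0]
        raise ConditioningError(f"duplicate training sites {i} and {j} make the RBF system singular")
    targets = _as_targets(targets)
    rows = _neighborhoods(coords, targets, nb)
    candidates = np.logspace(-1, 1, 7)
    est = np.empty(len(targets))
    for t, (dt, it) in enumerate(rows):
        pts = coords[it]
        scale = max(float(np.mean(dt)), _SNAP)
        local = (pts - targets[t]) / scale
        k = len(it)
        rr = np.linalg.norm(local[:, None, :] - local[None, :, :], axis=2)
        if basis == "thin_plate_spline":
            P = np.column_stack([np.ones(k), local])
        else:
            P = np.ones((k, 1))
        p = P.shape[1]

        def assemble(c):
            A = np.zeros((k + p, k + p))
            A[:k, :k] = _rbf_phi(basis, rr, c)
            A[:k, k:] = P
            A[k:, :k] = P.T
            return A

        rhs = np.concatenate([z[it], np.zeros(p)])
        if shape_param is not None or basis == "thin_plate_spline":
            cs = [shape_param if shape_param is not None else 1.0]
        else:
            cs = candidates
        best = None
        for c in cs:
            A = assemble(c)
            try:
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError as exc:
                if len(cs) == 1:
                    raise ConditioningError(f"singular RBF system at target {t}") from exc
                continue
            sol = Ainv @ rhs
            # ill-conditioned flat kernels break exact interpolation; skip
            if len(cs) > 1 and not np.allclose(A @ sol, rhs,
                                               atol=1e-7 * max(1.0, np.abs(rhs).max())):
                continue
            diag = np.diag(Ainv)[:k]
            with np.errstate(divide="ignore", invalid="ignore"):
                loo = sol[:k] / diag
            score = float(np.sum(loo[np.isfinite(loo)] ** 2))
            if best is None or score < best[0]:
                best = (score, c, sol)
        if best is None:
            raise ConditioningError(f"singular RBF system at target {t}")
        _, c, sol = best
        r0 = np.linalg.norm(local, axis=1)
        phi0 = _rbf_phi(basis, r0, c)
        trend0 = np.concatenate([[1.0], np.zeros(p - 1)])  # local coords vanish at target
        est[t] = np.dot(sol[:k], phi0) + np.dot(sol[k:], trend0)
    return PredictionSurface(est, None, f"rbf_{basis}",
                             {"basis": basis, "shape_param": shape_param, "neighborhood": nb})


# ---------------------------------------------------------------------------
# ordinary kriging

def _ok_solve(gamma_nn: np.ndarray, gamma_n0: np.ndarray, z: np.ndarray):
    k = len(z)
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = gamma_nn
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    rhs = np.concatenate([gamma_n0, [1.0]])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError("singular kriging system (duplicate sites?)") from exc
    lam, mu = sol[:k], sol[k]
    est = float(np.dot(lam, z))
    var = float(np.dot(lam, gamma_n0) + mu)
    return est, var, lam, mu


def ok_predict(
    sites, targets, vm: VariogramModel,
    nb: NeighborhoodSpec | None = None,
    value_selector="soc_a", values=None,
) -> PredictionSurface:
    """Ordinary kriging with a local neighbourhood.

    Per target the kriging system (semivariance matrix among neighbours
    plus a Lagrange multiplier enforcing unit weight sum) is solved; the
    kriging variance is floored at zero.
    """
    nb = nb or NeighborhoodSpec()
    coords, z = _coerce_training(sites, values, value_selector)
    coords, z, _ = _dedupe(coords, z)
    targets = _as_targets(targets)
    rows = _neighborhoods(coords, targets, nb)
    est = np.empty(len(targets))
    var = np.empty(len(targets))
    for t, (dt, it) in enumerate(rows):
        pts = coords[it]
        h = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        est[t], v, _, _ = _ok_solve(vm(h), vm(dt), z[it])
        if v < 0:
            log.debug("ok: negative kriging variance %.3e floored at target %d", v, t)
            v = 0.0
        var[t] = v
    return PredictionSurface(est, var, "ok", {"variogram": vm.to_dict(), "neighborhood": nb})


# ---------------------------------------------------------------------------
# ordinary cokriging with a linear model of coregionalization

@dataclass(frozen=True)
class LMC:
    """Linear model of coregionalization with two common structures.

    gamma_ab(h) = B0[a, b] * 1(h > 0) + B1[a, b] * g(h), where g is the
    unit-sill structure of ``base`` (family + range).  B0 and B1 are
    positive semidefinite.
    """

    base: VariogramModel  # unit description: family + range (sills unused)
    B0: np.ndarray
    B1: np.ndarray

    def gamma(self, a: int, b: int, h: np.ndarray) -> np.ndarray:
        unit = VariogramModel(self.base.family, 0.0, 1.0, self.base.range_param)
        h = np.asarray(h, dtype=float)
        return np.where(h > 0, self.B0[a, b] + self.B1[a, b] * unit(h), 0.0)

    def cov(self, a: int, b: int, h: np.ndarray) -> np.ndarray:
        """(Cross-)covariance C_ab(h) = sill_ab - gamma_ab(h); the nugget
        component contributes only at h ~ 0 (within the snap tolerance)."""
        unit = VariogramModel(self.base.family, 0.0, 1.0, self.base.range_param)
        h = np.asarray(h, dtype=float)
        struct = self.B1[a, b] * (1.0 - unit(np.maximum(h, 0.0)))
        return np.where(h < _SNAP, self.B0[a, b] + self.B1[a, b], struct)


def _psd_project(M: np.ndarray, fixed00: float | None = None) -> np.ndarray:
    """Nearest PSD matrix; optionally with entry (0, 0) held fixed.

    Alternates eigenvalue clipping with resetting the fixed entry
    (Dykstra-style); a handful of iterations suffices for the 5x5
    matrices that occur here.
    """
    M = 0.5 * (M + M.T)
    if fixed00 is not None:
        M[0, 0] = fixed00
    for _ in range(100):
        w, V = np.linalg.eigh(M)
        if np.all(w >= -1e-12) and (fixed00 is None or abs(M[0, 0] - fixed00) < 1e-12):
            break
        w = np.clip(w, 0.0, None)
        M = V @ np.diag(w) @ V.T
        if fixed00 is not None:
            M[0, 0] = fixed00
    return M


def fit_lmc(coords: np.ndarray, table: np.ndarray, base: VariogramModel,
            n_lags: int = 15) -> LMC:
    """Fit an LMC to co-located variables by constrained weighted least squares.

    ``table`` is (n_sites, n_vars) with the primary variable in column 0.
    The primary's direct-variogram coefficients are held fixed at the
    ``base`` model's nugget / partial sill; secondary direct and all cross
    coefficients are fitted per pair, then the coefficient matrices are
    projected onto the PSD cone (keeping the primary entries).
    """
    n_vars = table.shape[1]
    from scipy.spatial.distance import pdist

    max_lag = 0.5 * float(pdist(coords).max())
    unit = VariogramModel(base.family, 0.0, 1.0, base.range_param)
    B0 = np.zeros((n_vars, n_vars))
    B1 = np.zeros((n_vars, n_vars))
    B0[0, 0] = base.nugget
    B1[0, 0] = base.partial_sill
    for a in range(n_vars):
        for b in range(a, n_vars):
            if a == 0 and b == 0:
                continue
            cv = cross_semivariogram(coords, table[:, a], table[:, b], max_lag, n_lags)
            lags, gam, counts = cv.nonempty()
            X = np.column_stack([np.ones_like(lags), unit(lags)])
            w = np.sqrt(counts.astype(float))
            coef, *_ = np.linalg.lstsq(X * w[:, None], gam * w, rcond=None)
            B0[a, b] = B0[b, a] = coef[0]
            B1[a, b] = B1[b, a] = coef[1]
    return LMC(base, _psd_project(B0, base.nugget), _psd_project(B1, base.partial_sill))


def ck_predict(
    sites, secondary: Sequence[Raster], targets,
    vm_primary: VariogramModel | None = None,
    lmc: LMC | None = None,
    nb: NeighborhoodSpec | None = None,
    value_selector="soc_a", values=None,
) -> PredictionSurface:
    """Ordinary cokriging with 1-4 secondary variables given as rasters.

    Secondary values are sampled at the training sites *and* at each
    prediction location (collocated cokriging) -- the collocated value is
    what lets the secondary reduce the prediction variance below ordinary
    kriging's nugget floor.  The linear model of coregionalization is
    fitted from the co-located site data unless supplied, with the
    primary's direct variogram held at ``vm_primary``.  Unbiasedness:
    primary weights sum to 1, each secondary's weights (including the
    collocated one) sum to 0.  Secondaries with (near) zero fitted
    variance carry no information and are dropped with a warning, which
    reduces the system to ordinary kriging.
    """
    if not 1 <= len(secondary) <= 4:
        raise ValueError("cokriging supports 1 to 4 secondary variables")
    nb = nb or NeighborhoodSpec()
    coords, z = _coerce_training(sites, values, value_selector)
    sec = np.column_stack([r.sample(coords[:, 0], coords[:, 1]) for r in secondary])
    if np.isnan(sec).any():
        raise ValueError("secondary rasters must cover all training sites")
    coords, z, sec = _dedupe(coords, z, sec)
    targets = _as_targets(targets)

    if vm_primary is None:
        raise ValueError("vm_primary is required (fit it with fit_variogram_model)")
    table = np.column_stack([z, sec])
    if lmc is None:
        lmc = fit_lmc(coords, table, vm_primary)
    # drop uninformative secondaries
    keep = [0]
    psill0 = lmc.B0[0, 0] + lmc.B1[0, 0]
    for a in range(1, table.shape[1]):
        if lmc.B0[a, a] + lmc.B1[a, a] <= 1e-10 * max(psill0, 1e-30):
            warnings.warn(f"secondary variable {a - 1} has ~zero variance; dropped from cokriging")
        else:
            keep.append(a)
    table = table[:, keep]
    B0 = lmc.B0[np.ix_(keep, keep)]
    B1 = lmc.B1[np.ix_(keep, keep)]
    lmc = LMC(lmc.base, B0, B1)
    p = table.shape[1]  # primary + retained secondaries

    sec_at_targets = np.column_stack(
        [r.sample(targets[:, 0], targets[:, 1]) for r in secondary]
    )[:, [a - 1 for a in keep if a > 0]] if p > 1 else np.zeros((len(targets), 0))
    if p > 1 and np.isnan(sec_at_targets).any():
        raise ValueError("secondary rasters must cover all prediction targets")

    rows = _neighborhoods(coords, targets, nb)
    est = np.empty(len(targets))
    var = np.empty(len(targets))
    sill0 = float(lmc.cov(0, 0, 0.0))
    for t, (dt, it) in enumerate(rows):
        k = len(it)
        pts = coords[it]
        h = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        # data layout: primary at k sites, then per secondary k sites + the
        # collocated value at the target itself
        sizes = [k] + [k + 1] * (p - 1)
        offs = np.concatenate([[0], np.cumsum(sizes)])
        nd = int(offs[-1])
        N = nd + p
        A = np.zeros((N, N))
        rhs = np.zeros(N)
        data = np.empty(nd)
        data[:k] = table[it, 0]
        for a in range(1, p):
            data[offs[a]:offs[a] + k] = table[it, a]
            data[offs[a] + k] = sec_at_targets[t, a - 1]
        h_aug = np.zeros((k + 1, k + 1))
        h_aug[:k, :k] = h
        h_aug[:k, k] = h_aug[k, :k] = dt
        for a in range(p):
            ka = sizes[a]
            for b in range(p):
                kb = sizes[b]
                A[offs[a]:offs[a] + ka, offs[b]:offs[b] + kb] = lmc.cov(
                    a, b, h_aug[:ka, :kb])
            A[offs[a]:offs[a] + ka, nd + a] = 1.0
            A[nd + a, offs[a]:offs[a] + ka] = 1.0
            d_to_target = np.concatenate([dt, [0.0]])[:ka]
            rhs[offs[a]:offs[a] + ka] = lmc.cov(a, 0, d_to_target)
        rhs[nd] = 1.0  # primary weights sum to 1; secondaries to 0
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        if not np.allclose(A @ sol, rhs, atol=1e-6):
            raise ConditioningError(f"cokriging system inconsistent at target {t}")
        w = sol[:nd]
        est[t] = float(np.dot(w, data))
        v = sill0 - float(np.dot(w, rhs[:nd])) - float(sol[nd])
        var[t] = max(v, 0.0)
    return PredictionSurface(est, var, "ck",
                             {"n_secondary": p - 1, "variogram": vm_primary.to_dict(),
                              "neighborhood": nb})


# ---------------------------------------------------------------------------
# simplified empirical Bayes kriging

def _spatial_subsets(coords: np.ndarray, subset_size: int, overlap: float):
    """Recursive median split into blocks of <= subset_size, then each block
    is grown by ``overlap`` * size nearest outside sites."""
    idx_all = np.arange(len(coords))

    def split(idx):
        if len(idx) <= subset_size:
            return [idx]
        pts = coords[idx]
        axis = int(np.argmax(pts.max(axis=0) - pts.min(axis=0)))
        med = np.median(pts[:, axis])
        left = idx[pts[:, axis] <= med]
        right = idx[pts[:, axis] > med]
        if len(left) == 0 or len(right) == 0:  # degenerate: all on the median
            half = len(idx) // 2
            left, right = idx[:half], idx[half:]
        return split(left) + split(right)

    blocks = split(idx_all)
    tree = cKDTree(coords)
    out = []
    for blk in blocks:
        centroid = coords[blk].mean(axis=0)
        n_extra = int(round(overlap * len(blk)))
        if n_extra > 0:
            k = min(len(coords), len(blk) + 3 * n_extra)
            _, near = tree.query(centroid, k=k)
            near = np.atleast_1d(near)
            extras = [i for i in near if i not in set(blk)][:n_extra]
            blk = np.concatenate([blk, np.asarray(extras, dtype=int)]) if extras else blk
        out.append((np.sort(blk), centroid))
    return out


def _bootstrap_models(coords, z, n_simulations, rng):
    """Base variogram fit plus parametric-bootstrap refits on noisy bins."""
    from scipy.spatial.distance import pdist

    from .variogram import EmpiricalVariogram, _bin_pairs

    d = pdist(coords)
    max_lag = 0.5 * float(d.max())
    sq = pdist(z[:, None], metric="sqeuclidean")
    centers, gam, counts = _bin_pairs(d, sq, max_lag, 15)
    ev = EmpiricalVariogram(centers, np.maximum(gam, 0.0), counts, max_lag, 15)
    base = fit_variogram_model(ev, "exponential")
    models = [base]
    lags, _, cnt = ev.nonempty()
    gm = base(lags)
    for _ in range(n_simulations - 1):
        noisy = gm * (1.0 + rng.normal(size=len(lags)) * np.sqrt(2.0 / cnt))
        noisy = np.maximum(noisy, 1e-12)
        full_gamma = np.full(ev.n_lags, np.nan)
        full_gamma[ev.pair_counts > 0] = noisy
        ev_b = EmpiricalVariogram(ev.lag_centers, full_gamma, ev.pair_counts,
                                  ev.max_lag, ev.n_lags)
        try:
            models.append(fit_variogram_model(ev_b, "exponential"))
        except (ValueError, RuntimeError):
            models.append(base)
    return models


def ebk_predict(
    sites, targets, subset_size: int = 100, overlap: float = 0.5,
    n_simulations: int = 100, seed: int = 0,
    nb: NeighborhoodSpec | None = None,
    value_selector="soc_a", values=None,
) -> PredictionSurface:
    """Simplified empirical Bayes kriging.

    Sites are partitioned into overlapping spatial subsets; each subset
    gets an exponential variogram fit plus ``n_simulations - 1``
    parametric-bootstrap refits (a "spectrum of semivariograms").  A
    target is predicted as the inverse-squared-distance-weighted mixture
    (over the nearest subset centroids) of OK estimates under each
    simulated variogram; the reported variance is the total variance of
    that mixture.  Deterministic for a fixed seed.

    This is a published-contract re-creation, not the proprietary
    restricted-ML algorithm of commercial GIS suites.
    """
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    nb = nb or NeighborhoodSpec()
    coords, z = _coerce_training(sites, values, value_selector)
    coords, z, _ = _dedupe(coords, z)
    if subset_size > len(coords):
        subset_size = len(coords)
    if subset_size < 10:
        raise ValueError("subset_size must be >= 10 sites to fit a variogram")
    rng = np.random.default_rng(seed)
    subsets = _spatial_subsets(coords, subset_size, overlap)
    sub_models = [_bootstrap_models(coords[blk], z[blk], n_simulations, rng)
                  for blk, _ in subsets]
    centroids = np.array([c for _, c in subsets])
    targets = _as_targets(targets)
    est = np.empty(len(targets))
    var = np.empty(len(targets))
    n_mix = min(2, len(subsets))
    for t, x0 in enumerate(targets):
        dc = np.linalg.norm(centroids - x0, axis=1)
        order = np.argsort(dc)[:n_mix]
        if dc[order[0]] < _SNAP:
            w_sub = np.zeros(len(order))
            w_sub[0] = 1.0
        else:
            w_sub = dc[order] ** -2
            w_sub = w_sub / w_sub.sum()
        mean_acc = 0.0
        second_acc = 0.0
        for w, si in zip(w_sub, order):
            blk, _ = subsets[si]
            sub_coords, sub_z = coords[blk], z[blk]
            rows = _neighborhoods(sub_coords, x0[None, :], nb)
            dt, it = rows[0]
            pts = sub_coords[it]
            h = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
            preds = np.empty(len(sub_models[si]))
            vars_ = np.empty(len(sub_models[si]))
            for m, vm in enumerate(sub_models[si]):
                e, v, _, _ = _ok_solve(vm(h), vm(dt), sub_z[it])
                preds[m] = e
                vars_[m] = max(v, 0.0)
            mean_acc += w * preds.mean()
            second_acc += w * np.mean(vars_ + preds ** 2)
        est[t] = mean_acc
        var[t] = max(second_acc - mean_acc ** 2, 0.0)
    return PredictionSurface(est, var, "ebk",
                             {"subset_size": subset_size, "overlap": overlap,
                              "n_simulations": n_simulations, "seed": seed,
                              "neighborhood": nb})
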