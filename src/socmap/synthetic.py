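"""Seeded synthetic mountain-park survey generator.

Emulates a volcanic national park of ~482 km^2 with three altitude-banded
land-use strata (seasonal agriculture on the lower slopes, conifer forest
on the mid slopes, grassland/high moor above 4,000 m), a spatially
autocorrelated soil-organic-carbon field, an O horizon whose thickness
depends on land use, and an NDVI surface positively linked to SOC.

The SOC field is lognormal: a Gaussian random field on the natural-log
scale with an exponential semivariogram (nugget 0.529, sill 2.226 by
default) is shifted per stratum so the back-transformed field matches the
configured stratum mean.  The field-level variogram therefore governs the
dispersion of the simulated values; the per-stratum ``sd_soc`` entries are
descriptive survey statistics carried in the config, not an independent
dial (both cannot be matched at once, see the methods note).

Everything is deterministic per seed (numpy PCG64 generators spawned from
a single seed sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .geodata import (
    LandUse,
    LanduseMap,
    Raster,
    SampleSite,
    write_landuse_geojson,
    write_raster,
    write_sample_table,
)
from .variogram import VariogramModel

__all__ = [
    "StratumParams",
    "SurveyConfig",
    "SyntheticPark",
    "generate_dem",
    "assign_landuse",
    "simulate_soc_field",
    "generate_ndvi",
    "sample_survey",
    "generate_park",
    "recover_variogram",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class StratumParams:
    """Per-land-use survey statistics and altitude band (upper bound closed)."""

    mean_soc: float          # g C kg^-1, A horizon
    sd_soc: float            # g C kg^-1 (descriptive; see module docstring)
    alt_min: float           # m a.s.l.
    alt_max: float           # m a.s.l.; inf = open above
    o_thickness_mean: float  # cm; 0 = no O horizon in this stratum

    def __post_init__(self) -> None:
        if not self.sd_soc > 0:
            raise ValueError("sd_soc must be > 0")
        if not self.mean_soc > 0:
            raise ValueError("mean_soc must be > 0")


def _default_strata() -> dict[LandUse, StratumParams]:
    return {
        LandUse.AGRICULTURE: StratumParams(5.19, 1.98, 2200.0, 3000.0, 0.0),
        LandUse.FOREST: StratumParams(40.31, 18.55, 2500.0, 4000.0, 5.31),
        LandUse.GRASSLAND: StratumParams(12.82, 5.17, 4000.0, float("inf"), 1.0),
    }


@dataclass
class SurveyConfig:
    """Full description of the synthetic park and survey design.

    Defaults emulate a 440-site campaign over a 22 km x 22 km (~482 km^2)
    stratovolcano park rising from 2,200 to 4,461 m a.s.l.
    """

    seed: int = 0
    n_sites: int = 440
    extent_km: float = 22.0
    cell_size: float = 200.0                       # m
    altitude_range: tuple[float, float] = (2200.0, 4461.0)
    cone_exponent: float = 1.3                     # radial profile shape; 1.3 gives ~7% grassland
    dem_noise_amp: float = 40.0                    # m, smooth seeded relief noise
    dem_noise_scale: float = 1000.0                # m, correlation length of relief noise
    p_forest_mixed: float = 0.3                    # forest probability in the 2500-3000 m band
    mixed_patch_scale_m: float = 1500.0            # coherence length of the forest/field mosaic
    strata: dict[LandUse, StratumParams] = field(default_factory=_default_strata)
    variogram: VariogramModel = field(
        default_factory=lambda: VariogramModel("exponential", 0.529, 2.226 - 0.529, 3000.0)
    )
    o_soc_range: tuple[float, float] = (284.76, 484.20)  # g kg^-1, O horizon
    o_bulk_density: float = 0.15                   # g cm^-3 (organic layer)
    bd_range: tuple[float, float] = (0.9, 1.4)     # g cm^-3, A horizon
    coarse_range: tuple[float, float] = (0.0, 20.0)  # volume %
    ndvi_intercept: float = 0.32
    ndvi_slope: float = 0.15
    ndvi_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_sites < 10:
            raise ValueError("n_sites must be >= 10")
        if self.variogram.nugget < 0 or self.variogram.partial_sill < 0:
            raise ValueError("variogram nugget and partial sill must be >= 0")
        if self.ndvi_slope <= 0:
            raise ValueError("ndvi_slope must be > 0")

    @property
    def extent_m(self) -> float:
        return self.extent_km * 1000.0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator per pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])

    def to_dict(self) -> dict:
        d = {
            k: v for k, v in asdict(self).items()
            if k not in ("strata", "variogram")
        }
        d["strata"] = {lu.value: asdict(sp) for lu, sp in self.strata.items()}
        d["variogram"] = self.variogram.to_dict()
        return d


@dataclass
class SyntheticPark:
    """All truth rasters of one generated park plus the config that made it."""

    dem: Raster
    landuse: Raster
    soc_field: Raster
    ndvi: Raster
    truth: SurveyConfig

    def __post_init__(self) -> None:
        for r in (self.landuse, self.soc_field, self.ndvi):
            if not self.dem.same_grid(r):
                raise ValueError("all park rasters must share grid geometry")


def generate_dem(cfg: SurveyConfig) -> Raster:
    """Radial volcanic cone plus smooth seeded relief noise.

    Altitude decreases from the configured maximum at the centre to the
    minimum at the edge following ``(1 - (r/R)^q)`` with q =
    ``cone_exponent``; the result is clipped to the configured range so
    every cell falls inside a land-use altitude band.
    """
    amin, amax = cfg.altitude_range
    n = int(round(cfg.extent_m / cfg.cell_size))
    xs = (np.arange(n) + 0.5) * cfg.cell_size
    X, Y = np.meshgrid(xs, xs)
    cx = cy = cfg.extent_m / 2.0
    R = cfg.extent_m / 2.0
    r = np.hypot(X - cx, Y - cy)
    profile = np.clip(1.0 - (r / R) ** cfg.cone_exponent, 0.0, 1.0)
    alt = amin + (amax - amin) * profile
    rng = cfg.rng(0)
    white = rng.normal(size=(n, n))
    sigma_cells = cfg.dem_noise_scale / cfg.cell_size
    smooth = gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    sd = smooth.std()
    if sd > 0:
        alt = alt + smooth / sd * cfg.dem_noise_amp
    return Raster(np.clip(alt, amin, amax), 0.0, 0.0, cfg.cell_size)


def assign_landuse(dem: Raster, cfg: SurveyConfig) -> Raster:
    """Classify cells by altitude band.

    Bands are half-open at the top of the *lower* band, i.e. an altitude
    exactly on a shared boundary belongs to the lower band.  Where the
    agriculture and forest bands overlap (2,500-3,000 m by default) the
    class is a seeded Bernoulli draw with forest probability
    ``p_forest_mixed``, spatially coherent at ``mixed_patch_scale_m`` (a
    smoothed noise field thresholded at the matching quantile), so the
    mosaic forms contiguous forest patches and fields rather than
    cell-level salt-and-pepper.
    """
    alt = dem.values
    rng = cfg.rng(1)
    out = np.full(alt.shape, np.nan)
    lus = list(cfg.strata)
    in_band = np.zeros(alt.shape + (len(lus),), dtype=bool)
    for j, lu in enumerate(lus):
        sp = cfg.strata[lu]
        lo, hi = sp.alt_min, sp.alt_max
        in_band[..., j] = ((alt > lo) | (alt == min(b.alt_min for b in cfg.strata.values()))) \
            & (alt <= hi)
    n_cand = in_band.sum(axis=-1)
    if np.any((n_cand == 0) & ~np.isnan(alt)):
        bad = float(alt[(n_cand == 0) & ~np.isnan(alt)].flat[0])
        raise ValueError(f"altitude {bad} m falls outside every configured band")
    for j, lu in enumerate(lus):
        only = (n_cand == 1) & in_band[..., j]
        out[only] = lu.code
    mixed = n_cand > 1
    if mixed.any():
        jf = lus.index(LandUse.FOREST)
        ja = lus.index(LandUse.AGRICULTURE)
        smooth = gaussian_filter(rng.normal(size=alt.shape),
                                 sigma=cfg.mixed_patch_scale_m / dem.cell_size,
                                 mode="reflect")
        both = mixed & in_band[..., jf] & in_band[..., ja]
        if both.any():
            cut = np.quantile(smooth[both], cfg.p_forest_mixed)
            draw = smooth < cut
        else:
            draw = np.zeros(alt.shape, dtype=bool)
        out[both & draw] = LandUse.FOREST.code
        out[both & ~draw] = LandUse.AGRICULTURE.code
        other = mixed & ~both
        if other.any():  # any other overlap: first-listed stratum wins
            for j, lu in enumerate(lus):
                sel = other & in_band[..., j] & np.isnan(out)
                out[sel] = lu.code
    return dem.copy_with(out)


def _grf_exponential(shape: tuple[int, int], cell_size: float, psill: float,
                     range_m: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean GRF with C(h) = psill * exp(-h / range_m).

    Circulant embedding on a doubled torus; the tiny negative eigenvalues
    that can appear for the exponential kernel are clipped to zero.
    """
    n1, n2 = shape
    m1, m2 = 2 * n1, 2 * n2
    dy = np.minimum(np.arange(m1), m1 - np.arange(m1)) * cell_size
    dx = np.minimum(np.arange(m2), m2 - np.arange(m2)) * cell_size
    h = np.hypot(dy[:, None], dx[None, :])
    cov = psill * np.exp(-h / range_m)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    amp = np.sqrt(lam / (m1 * m2))
    noise = rng.normal(size=(m1, m2)) + 1j * rng.normal(size=(m1, m2))
    fld = np.fft.fft2(amp * noise)
    return fld.real[:n1, :n2]


def simulate_soc_field(landuse: Raster, cfg: SurveyConfig) -> Raster:
    """Lognormal SOC field (g kg^-1) with the configured log-scale variogram.

    log SOC = mu_stratum + GRF(partial sill) + nugget white noise, with
    mu_stratum = ln(mean_stratum) - sill/2 so the back-transformed field
    matches each stratum's configured mean in expectation.  Output is
    strictly positive on data cells.
    """
    vm = cfg.variogram
    rng = cfg.rng(2)
    shape = landuse.values.shape
    if vm.partial_sill > 0:
        grf = _grf_exponential(shape, landuse.cell_size, vm.partial_sill,
                               vm.range_param, rng)
    else:
        grf = np.zeros(shape)
    if vm.nugget > 0:
        grf = grf + rng.normal(scale=np.sqrt(vm.nugget), size=shape)
    mu = np.full(shape, np.nan)
    for lu, sp in cfg.strata.items():
        mu[landuse.values == lu.code] = np.log(sp.mean_soc) - vm.sill / 2.0
    field_vals = np.exp(mu + grf)
    return landuse.copy_with(field_vals)


def generate_ndvi(soc_field: Raster, cfg: SurveyConfig) -> Raster:
    """NDVI surface positively linked to SOC.

    ndvi = clip(intercept + slope * standardized(log SOC) + noise, -1, 1).
    Standardisation happens on the log scale so the heavy-tailed SOC field
    maps to a well-spread greenness surface; the link stays monotone in SOC.
    """
    rng = cfg.rng(3)
    vals = soc_field.values
    ok = ~np.isnan(vals)
    logv = np.log(vals[ok])
    zs = (logv - logv.mean()) / max(logv.std(), 1e-12)
    ndvi = np.full(vals.shape, np.nan)
    noise = rng.normal(scale=cfg.ndvi_noise_sd, size=zs.shape) if cfg.ndvi_noise_sd > 0 else 0.0
    ndvi[ok] = np.clip(cfg.ndvi_intercept + cfg.ndvi_slope * zs + noise, -1.0, 1.0)
    return soc_field.copy_with(ndvi)


def sample_survey(park: SyntheticPark, cfg: SurveyConfig | None = None) -> list[SampleSite]:
    """Draw the survey: one site per square block, quasi-uniform coverage.

    The extent is tiled into ~n_sites blocks (the "100-ha grid" template);
    a jittered point is drawn in each block, so stratum counts come out
    proportional to class areas.  Each site reads altitude, land use, SOC
    and NDVI off the truth rasters; bulk density and coarse fragments are
    uniform draws; O-horizon thickness is exponential around the stratum
    mean (agriculture has none) with O-horizon SOC uniform in the
    configured range.
    """
    cfg = cfg or park.truth
    rng = cfg.rng(4)
    lu_r = park.landuse
    n_data = int(np.sum(~np.isnan(lu_r.values)))
    if cfg.n_sites > n_data:
        raise ValueError("n_sites exceeds the number of data cells")
    b = int(np.ceil(np.sqrt(cfg.n_sites)))
    block = cfg.extent_m / b
    pts = []
    for iy in range(b):
        for ix in range(b):
            x = (ix + rng.random()) * block
            y = (iy + rng.random()) * block
            pts.append((x, y))
    pts = np.array(pts)
    # keep points on data cells, then thin deterministically to n_sites
    lu_vals = lu_r.sample(pts[:, 0], pts[:, 1])
    pts = pts[~np.isnan(lu_vals)]
    if len(pts) < cfg.n_sites:
        raise ValueError("not enough data-covered blocks for the requested n_sites")
    sel = rng.choice(len(pts), size=cfg.n_sites, replace=False)
    pts = pts[np.sort(sel)]

    sites: list[SampleSite] = []
    alts = park.dem.sample(pts[:, 0], pts[:, 1])
    socs = park.soc_field.sample(pts[:, 0], pts[:, 1])
    lus = park.landuse.sample(pts[:, 0], pts[:, 1])
    ndvis = park.ndvi.sample(pts[:, 0], pts[:, 1])
    for i, ((x, y), alt, soc, lu_code, nd) in enumerate(zip(pts, alts, socs, lus, ndvis)):
        lu = LandUse.from_code(lu_code)
        sp = cfg.strata[lu]
        bd = rng.uniform(*cfg.bd_range)
        coarse = rng.uniform(*cfg.coarse_range)
        if sp.o_thickness_mean > 0:
            o_thick = float(rng.exponential(sp.o_thickness_mean))
            soc_o = float(rng.uniform(*cfg.o_soc_range))
        else:
            o_thick, soc_o = 0.0, None
        sites.append(SampleSite(
            site_id=f"S{i + 1:04d}", x=float(x), y=float(y), altitude=float(alt),
            land_use=lu, soc_a=float(soc), bulk_density=float(bd),
            coarse_pct=float(coarse), soc_o=soc_o, o_thickness=o_thick,
            ndvi=float(nd),
        ))
    return sites


def recover_variogram(sites: Sequence[SampleSite], cfg: SurveyConfig,
                      n_lags: int = 10):
    """Refit the field variogram from a survey (generator self-validation).

    The stationary variogram belongs to the stratum-demeaned log-SOC
    residual, so per-stratum sample means are removed first.  The fit is
    restricted to lags within twice the range parameter (two thirds of
    the effective range, where the exponential model still has curvature):
    beyond that the bounded model is flat and long-lag bins contribute
    only noise to the weighted least squares.  Bin width then roughly
    matches the survey spacing.
    """
    from .geodata import site_coords
    from .variogram import empirical_semivariogram, fit_variogram_model

    z = np.log([s.soc_a for s in sites])
    strata = np.array([s.land_use.value for s in sites])
    for lu in np.unique(strata):
        z[strata == lu] -= z[strata == lu].mean()
    ev = empirical_semivariogram(
        site_coords(sites), z,
        max_lag=2.0 * cfg.variogram.range_param, n_lags=n_lags,
    )
    return fit_variogram_model(ev, cfg.variogram.family)


def generate_park(cfg: SurveyConfig) -> SyntheticPark:
    """Run the full generator chain: DEM -> land use -> SOC field -> NDVI."""
    dem = generate_dem(cfg)
    landuse = assign_landuse(dem, cfg)
    soc = simulate_soc_field(landuse, cfg)
    ndvi = generate_ndvi(soc, cfg)
    return SyntheticPark(dem, landuse, soc, ndvi, cfg)


def _idealized_landuse_map(cfg: SurveyConfig) -> LanduseMap:
    """Noise-free altitude-band polygons (annuli) of the cone template.

    The per-cell raster is the authoritative land-use map (it carries the
    relief noise and the mixed-band Bernoulli draw); these polygons are the
    idealized template, with the mixed band assigned to its majority class.
    """
    from shapely.geometry import Point, box

    amin, amax = cfg.altitude_range
    R = cfg.extent_m / 2.0
    centre = Point(R, R)
    square = box(0.0, 0.0, cfg.extent_m, cfg.extent_m)

    def radius_at(alt: float) -> float:
        frac = (alt - amin) / (amax - amin)
        return R * (1.0 - frac) ** (1.0 / cfg.cone_exponent)

    r_grass = radius_at(cfg.strata[LandUse.GRASSLAND].alt_min)
    r_forest = radius_at(cfg.strata[LandUse.FOREST].alt_min
                         if cfg.p_forest_mixed >= 0.5
                         else cfg.strata[LandUse.AGRICULTURE].alt_max)
    grass = centre.buffer(r_grass, quad_segs=256)
    forest = centre.buffer(r_forest, quad_segs=256).difference(grass)
    agri = square.difference(centre.buffer(r_forest, quad_segs=256))
    return LanduseMap([
        (LandUse.GRASSLAND, grass),
        (LandUse.FOREST, forest),
        (LandUse.AGRICULTURE, agri),
    ])


def write_fixture_bundle(cfg: SurveyConfig, out_dir) -> dict[str, str]:
    """Generate a park + survey and write the complete input bundle.

    Writes samples.csv, dem.asc, landuse.asc, landuse.geojson, ndvi.tif,
    nir.tif/red.tif (bands consistent with the NDVI surface, summing to a
    constant reflectance of 0.5) and truth.yaml.  Returns a manifest of
    written paths.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    park = generate_park(cfg)
    sites = sample_survey(park, cfg)
    manifest = {}

    write_sample_table(sites, out / "samples.csv")
    manifest["samples"] = str(out / "samples.csv")
    write_raster(park.dem, out / "dem.asc")
    manifest["dem"] = str(out / "dem.asc")
    write_raster(park.landuse, out / "landuse.asc")
    manifest["landuse"] = str(out / "landuse.asc")
    write_landuse_geojson(_idealized_landuse_map(cfg), out / "landuse.geojson")
    manifest["landuse_polygons"] = str(out / "landuse.geojson")
    write_raster(park.ndvi, out / "ndvi.tif")
    manifest["ndvi"] = str(out / "ndvi.tif")
    nir = park.ndvi.copy_with(0.25 * (1.0 + park.ndvi.values))
    red = park.ndvi.copy_with(0.25 * (1.0 - park.ndvi.values))
    write_raster(nir, out / "nir.tif")
    write_raster(red, out / "red.tif")
    manifest["nir"] = str(out / "nir.tif")
    manifest["red"] = str(out / "red.tif")
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    manifest["truth"] = str(out / "truth.yaml")
    return manifest
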