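"""Synthetic tower tables, tower time series, and gridded scenes.

The generator emulates the statistical structure of the eddy-covariance
training set and of the gridded inputs so the full pipeline can be exercised
without any download:

* Predictors are drawn from the per-variable marginal families and ranges of
  the tower network (exponential LAI and precipitation, uniform shortwave
  radiation, chi-square temperatures, gamma moisture variables), coupled with
  a Gaussian copula so predictors are mildly cross-correlated — fully
  independent predictors would make relevance ranking trivially easy.
* Fluxes come from a known nonlinear light/temperature/moisture response
  (below), plus additive Gaussian noise.  The generative parameters are
  recorded with every output, so noise-free fluxes can be regenerated
  exactly: they are the ground truth for recovery tests.
* Scenes are smoothed Gaussian random fields segmented by a categorical
  vegetation mosaic, with LAI on a fine grid and climate on an integer-ratio
  coarser grid, emulating the two-resolution satellite/reanalysis setting.

Flux-generating function (defaults in FluxParams)::

    GPP  = g_max (1 - exp(-k_L LAI)) SW/(SW + S_half) w(SWC_1) t(TA) + e1
    RECO = r_b Q10^((TS_1 - T_ref)/10) + f_g GPP + e2
    NEE  = GPP - RECO + e3        (positive = uptake)

with w(s) = s/(s + W_half) a saturating soil-moisture limiter and t(T) a
Gaussian temperature response around T_opt.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io_formats.grids import GridGeo, GridScene
from .io_formats.tower import NEE_SIGN_UPTAKE, TowerRecord
from .schema import PredictorSchema, default_schema

__all__ = [
    "FluxParams",
    "GeneratorConfig",
    "sample_predictors",
    "generate_fluxes",
    "generate_tower_series",
    "generate_grid_scene",
    "marginal_distribution",
]

# Upper-quantile mass outside the valid range before truncation: families are
# scaled so ~99.5% of the untruncated mass lies below valid_max (and the
# support starts at valid_min), keeping the central mass inside the range.
_TAIL = 0.995


@dataclass(frozen=True)
class FluxParams:
    """Parameters of the flux-generating function (tower-scale defaults).

    g_max:   light-saturated canopy assimilation, micromol CO2 m-2 s-1.
    k_L:     canopy light-extinction coefficient (per unit LAI).
    S_half:  half-saturation shortwave irradiance, W m-2.
    W_half:  half-saturation soil water content, %.
    T_opt:   optimum air temperature for assimilation, degC.
    T_width: width of the Gaussian temperature response, degC.
    r_b:     basal respiration at T_ref, micromol CO2 m-2 s-1.
    q10:     respiration temperature sensitivity per 10 degC.
    t_ref:   reference soil temperature, degC.
    f_g:     fraction of GPP fed back into autotrophic respiration.
    """

    g_max: float = 30.0
    k_L: float = 0.5
    S_half: float = 100.0
    W_half: float = 15.0
    T_opt: float = 20.0
    T_width: float = 12.0
    r_b: float = 2.0
    q10: float = 2.0
    t_ref: float = 15.0
    f_g: float = 0.25

    def __post_init__(self) -> None:
        if self.g_max < 0 or self.r_b < 0:
            raise ValueError("g_max and r_b must be non-negative")


#: Default additive noise per flux, micromol CO2 m-2 s-1 — 10% of the
#: noise-free signal standard deviation under the default generator
#: (measured once on a large sample; see docs/methods.md).
DEFAULT_NOISE_SD = {"GPP": 0.24, "RECO": 0.095, "NEE": 0.17}


@dataclass
class GeneratorConfig:
    """Bundle of generator settings (all overridable per call)."""

    n_samples: int = 1000
    seed: int = 0
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    flux_params: FluxParams = field(default_factory=FluxParams)
    grid_extent: tuple[float, float] = (6.0, 6.0)  # degrees
    resolution_lai: float = 0.1
    climate_ratio: int = 3
    n_vegetation_classes: int = 5
    time_steps: int = 46

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")


def marginal_distribution(descriptor) -> stats.rv_continuous:
    """Frozen scipy distribution matching a predictor's family and range.

    Shape parameters are fixed so that the support starts at valid_min and
    ~99.5% of the untruncated mass lies below valid_max.
    """
    lo, hi = descriptor.valid_min, descriptor.valid_max
    span = hi - lo
    if descriptor.family == "uniform":
        return stats.uniform(loc=lo, scale=span)
    if descriptor.family == "exponential":
        scale = span / stats.expon.ppf(_TAIL)
        return stats.expon(loc=lo, scale=scale)
    if descriptor.family == "chi-square":
        df = 5.0
        scale = span / stats.chi2.ppf(_TAIL, df)
        return stats.chi2(df, loc=lo, scale=scale)
    if descriptor.family == "gamma":
        a = 2.0
        scale = span / stats.gamma.ppf(_TAIL, a)
        return stats.gamma(a, loc=lo, scale=scale)
    raise ValueError(f"unknown family {descriptor.family!r}")


def default_copula_correlation(schema: PredictorSchema) -> np.ndarray:
    """Hand-set rank-correlation matrix for the Gaussian copula.

    Encodes the physically expected couplings: air/soil temperatures move
    together, soil depths are strongly vertically coherent, radiation drives
    sensible/latent heat and temperature, moisture tracks precipitation.
    Projected to the nearest positive-definite matrix.
    """
    names = schema.names
    R = np.eye(len(names))

    def put(a: str, b: str, r: float) -> None:
        if a in names and b in names:
            i, j = names.index(a), names.index(b)
            R[i, j] = R[j, i] = r

    put("SW", "TA", 0.5)
    put("SW", "H", 0.45)
    put("SW", "LE", 0.4)
    put("TA", "TS_1", 0.7)
    put("TA", "TS_2", 0.6)
    put("TA", "TS_3", 0.5)
    put("TS_1", "TS_2", 0.85)
    put("TS_2", "TS_3", 0.85)
    put("TS_1", "TS_3", 0.7)
    put("SWC_1", "SWC_2", 0.85)
    put("SWC_2", "SWC_3", 0.85)
    put("SWC_1", "SWC_3", 0.7)
    put("SWC_1", "P", 0.35)
    put("LAI", "LE", 0.4)
    put("LAI", "SW", 0.2)
    put("LE", "TA", 0.3)
    put("WS", "H", 0.2)
    return _nearest_correlation(R)


def _nearest_correlation(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    w, V = np.linalg.eigh((R + R.T) / 2)
    w = np.maximum(w, floor)
    R2 = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


def sample_predictors(
    n: int,
    schema: PredictorSchema | None = None,
    seed: int = 0,
    correlation: np.ndarray | None = None,
) -> pd.DataFrame:
    """n x D predictor table from the per-variable families + copula.

    Every value lies inside [valid_min, valid_max]: the Gaussian copula
    sample is mapped through the quantile function of each range-truncated
    marginal, so truncation is exact rather than by rejection.
    """
    schema = schema or default_schema()
    if n == 0:
        return pd.DataFrame(columns=schema.names)
    if n < 0:
        raise ValueError("n must be >= 0")
    R = default_copula_correlation(schema) if correlation is None else correlation
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, schema.D)) @ L.T
    U = stats.norm.cdf(Z)
    cols = {}
    for j, p in enumerate(schema):
        dist = marginal_distribution(p)
        u_lo, u_hi = dist.cdf(p.valid_min), dist.cdf(p.valid_max)
        vals = dist.ppf(u_lo + U[:, j] * (u_hi - u_lo))
        cols[p.name] = np.clip(vals, p.valid_min, p.valid_max)
    return pd.DataFrame(cols)


def generate_fluxes(
    predictors: pd.DataFrame,
    params: FluxParams | None = None,
    noise_sd: dict | float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """GPP/RECO/NEE columns from the generative flux function.

    NEE is stored in the uptake-positive convention (NEE = GPP - RECO plus
    its own noise).  With ``noise_sd`` 0 (or a dict of zeros) the output is
    the exact noise-free ground truth.
    """
    params = params or FluxParams()
    if noise_sd is None:
        noise_sd = dict(DEFAULT_NOISE_SD)
    if np.isscalar(noise_sd):
        noise_sd = {"GPP": float(noise_sd), "RECO": float(noise_sd),
                    "NEE": float(noise_sd)}
    if any(v < 0 for v in noise_sd.values()):
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(predictors)

    gpp0, reco0 = noise_free_fluxes(predictors, params)
    gpp = gpp0 + rng.normal(0.0, noise_sd.get("GPP", 0.0), n)
    reco = reco0 + rng.normal(0.0, noise_sd.get("RECO", 0.0), n)
    nee = (gpp - reco) + rng.normal(0.0, noise_sd.get("NEE", 0.0), n)
    return pd.DataFrame({"GPP": gpp, "RECO": reco, "NEE": nee},
                        index=predictors.index)


def noise_free_fluxes(
    predictors: pd.DataFrame, params: FluxParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (GPP, RECO) from the generative response functions."""
    p = params or FluxParams()
    lai = np.asarray(predictors["LAI"], dtype=float)
    sw = np.asarray(predictors["SW"], dtype=float)
    swc = np.asarray(predictors["SWC_1"], dtype=float)
    ta = np.asarray(predictors["TA"], dtype=float)
    ts = np.asarray(predictors["TS_1"], dtype=float)

    light = 1.0 - np.exp(-p.k_L * lai)
    radiation = sw / (sw + p.S_half)
    water = swc / (swc + p.W_half)
    temp = np.exp(-0.5 * ((ta - p.T_opt) / p.T_width) ** 2)
    gpp = p.g_max * light * radiation * water * temp
    reco = p.r_b * p.q10 ** ((ts - p.t_ref) / 10.0) + p.f_g * gpp
    return gpp, reco


def generate_tower_series(
    site_id: str,
    vegetation_class: str,
    years: int = 1,
    seed: int = 0,
    schema: PredictorSchema | None = None,
    params: FluxParams | None = None,
    noise_sd: dict | float | None = None,
    start_year: int = 2019,
) -> list[TowerRecord]:
    """Daily multi-year tower series with seasonal cycles + AR(1) noise.

    Seasonal amplitude and phase are vegetation-class-specific (deciduous
    classes swing harder than evergreen ones); fluxes are generated day-wise
    from the same flux function as the tables.
    """
    if years <= 0:
        raise ValueError("years must be >= 1")
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)
    n_days = 365 * years
    doy = np.arange(n_days) % 365
    season = -np.cos(2.0 * np.pi * (doy - _CLASS_PHASE.get(vegetation_class, 0.0))
                     / 365.0)  # peaks mid-year (northern summer)
    amp = _CLASS_AMPLITUDE.get(vegetation_class, 0.6)

    cols = {}
    for p in schema:
        mid = 0.5 * (p.valid_min + p.valid_max)
        half = 0.5 * (p.valid_max - p.valid_min)
        ar = _ar1(n_days, rho=0.8, rng=rng) * 0.25 * half
        base = mid + amp * 0.7 * half * season + ar
        cols[p.name] = np.clip(base, p.valid_min, p.valid_max)
    preds = pd.DataFrame(cols)
    fluxes = generate_fluxes(preds, params, noise_sd,
                             seed=int(rng.integers(2**31)))

    start = np.datetime64(f"{start_year}-01-01")
    records = []
    for i in range(n_days):
        day = (start + np.timedelta64(i, "D")).astype("datetime64[D]")
        records.append(
            TowerRecord(
                site_id=site_id,
                date=day.item(),
                vegetation_class=vegetation_class,
                predictors={k: float(preds[k].iloc[i]) for k in preds.columns},
                fluxes={k: float(fluxes[k].iloc[i]) for k in fluxes.columns},
                nee_sign=NEE_SIGN_UPTAKE,
            )
        )
    return records


# Seasonal parameters per vegetation class: (relative amplitude, phase-day).
_CLASS_AMPLITUDE = {
    "CRO": 0.8, "ENF": 0.4, "DBF": 0.9, "EBF": 0.15, "DNF": 0.9,
    "GRA": 0.7, "WET": 0.5, "CSH": 0.5, "OSH": 0.45, "MF": 0.6, "MSF": 0.3,
}
_CLASS_PHASE = {c: 0.0 for c in _CLASS_AMPLITUDE}
_CLASS_PHASE.update({"CRO": 15.0, "GRA": 10.0, "MSF": -30.0})


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(n) * np.sqrt(1.0 - rho**2)
    out = np.empty(n)
    out[0] = rng.standard_normal()
    for i in range(1, n):
        out[i] = rho * out[i - 1] + eps[i]
    return out


def generate_grid_scene(
    extent: tuple[float, float] = (6.0, 6.0),
    resolution_lai: float = 0.1,
    climate_ratio: int = 3,
    time_steps: int = 46,
    seed: int = 0,
    schema: PredictorSchema | None = None,
    params: FluxParams | None = None,
    n_vegetation_classes: int = 5,
    origin: tuple[float, float] = (0.0, 50.0),
    extrapolation_fraction: float = 0.05,
) -> tuple[GridScene, GridScene, np.ndarray, dict]:
    """(fine LAI scene, coarse climate scene, vegetation map, truth) tuple.

    LAI lives on the fine grid, climate on an ``climate_ratio``-times coarser
    grid (the ratio must divide the fine shape exactly).  Fields are smoothed
    Gaussian random fields modulated by a categorical vegetation mosaic and a
    shared seasonal cycle over ``time_steps`` 8-day composites.

    A small fraction of pixels (``extrapolation_fraction``) is pushed
    slightly beyond the schema's valid range on the LAI and TA bands — this
    deliberately exercises the out-of-training-range behaviour of upscaling
    (clamp + flag + inflated epistemic sigma), mirroring what satellite
    inputs do at high latitudes.

    The returned ``truth`` dict holds noise-free GPP/RECO/NEE (T, H, W)
    arrays computed from the co-registered fine-grid predictors (climate
    bilinearly upsampled to the fine grid — the same co-registration the
    upscaling pipeline performs), plus the generative parameters.
    """
    if climate_ratio < 1 or int(climate_ratio) != climate_ratio:
        raise ValueError("climate_ratio must be a positive integer")
    schema = schema or default_schema()
    params = params or FluxParams()
    rng = np.random.default_rng(seed)

    W = int(round(extent[0] / resolution_lai))
    H = int(round(extent[1] / resolution_lai))
    if W % climate_ratio or H % climate_ratio:
        raise ValueError(
            f"fine grid {H}x{W} is not an integer multiple of climate_ratio "
            f"{climate_ratio}"
        )
    geo_fine = GridGeo(origin[0], origin[1], resolution_lai, resolution_lai)
    geo_coarse = GridGeo(origin[0], origin[1],
                         resolution_lai * climate_ratio,
                         resolution_lai * climate_ratio)

    # categorical vegetation mosaic: argmax over smoothed random fields
    fields = np.stack([
        ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=H / 8)
        for _ in range(n_vegetation_classes)
    ])
    veg_map = np.argmax(fields, axis=0)

    # 8-day season (mid-window day-of-year), shared across bands
    starts = np.arange(time_steps) * 8
    mid_doy = starts + 4
    season_t = -np.cos(2.0 * np.pi * mid_doy / 365.0)  # (T,)

    # per-class multiplicative modulation of the seasonal swing
    class_amp = rng.uniform(0.4, 1.0, size=n_vegetation_classes)
    amp_map = class_amp[veg_map]  # (H, W)

    def smooth_field() -> np.ndarray:
        f = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=H / 12)
        return f / max(f.std(), 1e-12)

    over = {"LAI", "TA"}  # bands allowed to exceed the valid range slightly
    T = time_steps
    fine_bands: dict[str, np.ndarray] = {}
    for p in schema:
        mid = 0.5 * (p.valid_min + p.valid_max)
        half = 0.5 * (p.valid_max - p.valid_min)
        spatial = smooth_field()  # (H, W), unit variance
        noise_t = rng.standard_normal(T) * 0.1
        arr = (
            mid
            + 0.55 * half * amp_map[None] * season_t[:, None, None]
            + 0.30 * half * spatial[None]
            + half * noise_t[:, None, None] * 0.5
        )
        if p.name in over and extrapolation_fraction > 0:
            margin = extrapolation_fraction * (p.valid_max - p.valid_min)
            arr = np.clip(arr, p.valid_min, p.valid_max + margin)
        else:
            arr = np.clip(arr, p.valid_min, p.valid_max)
        fine_bands[p.name] = arr

    # LAI shaped by the mosaic: vegetation classes differ in canopy density
    lai_class = rng.uniform(0.3, 1.0, size=n_vegetation_classes)
    fine_bands["LAI"] = fine_bands["LAI"] * lai_class[veg_map][None]

    times = (np.datetime64("2020-01-01") +
             starts.astype("timedelta64[D]")).astype("datetime64[D]")
    ndays = np.full(T, 8)
    ndays[-1] = 365 - 8 * (T - 1) if T == 46 else 8

    lai_scene = GridScene({"LAI": fine_bands["LAI"]}, geo_fine, times,
                          ndays=ndays)

    climate_names = [p.name for p in schema if p.name != "LAI"]
    r = int(climate_ratio)
    coarse_bands = {
        name: fine_bands[name].reshape(T, H // r, r, W // r, r).mean(axis=(2, 4))
        for name in climate_names
    }
    climate_scene = GridScene(coarse_bands, geo_coarse, times, ndays=ndays)

    # ground truth from the co-registered fine grid: climate upsampled
    # bilinearly back to the fine grid (the pipeline's own co-registration)
    from .upscaling import resample_to_grid

    climate_fine = resample_to_grid(climate_scene, geo_fine, (H, W),
                                    method="bilinear")
    co_bands = {"LAI": fine_bands["LAI"], **climate_fine.bands}
    flat = pd.DataFrame({n: co_bands[n].ravel() for n in schema.names})
    gpp0, reco0 = noise_free_fluxes(flat, params)
    truth = {
        "GPP": gpp0.reshape(T, H, W),
        "RECO": reco0.reshape(T, H, W),
        "NEE": (gpp0 - reco0).reshape(T, H, W),
        "params": asdict(params),
        "seed": seed,
    }
    return lai_scene, climate_scene, veg_map, truth
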