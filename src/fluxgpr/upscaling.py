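"""Apply a trained flux model to gridded predictor stacks.

Covers the gridded half of the pipeline: 8-day compositing of daily stacks,
mask-aware bilinear/nearest resampling between grids (pixel-center
convention throughout), chunked per-pixel prediction producing a flux map
with its epistemic sigma layer, and aggregation of a year of composites to
annual totals in gC m-2 y-1.

Out-of-training-range pixels are clamped to the schema's valid range and
recorded in a flag raster by default (masking them would hide exactly the
extrapolation behaviour the sigma layer is meant to expose at, e.g., high
latitudes); ``oor_policy="mask"`` masks them instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gpr
from .io_formats.grids import GridGeo, GridScene
from .schema import PredictorSchema

__all__ = [
    "FluxMap",
    "composite_8day",
    "resample_to_grid",
    "predict_map",
    "aggregate_annual",
    "convert_flux_units",
    "CARBON_MOLAR_MASS",
]

#: grams of carbon per mole of CO2 assimilated
CARBON_MOLAR_MASS = 12.011
SECONDS_PER_DAY = 86400.0

UNIT_UMOL_S = "umol m-2 s-1"
UNIT_GC_DAY = "gC m-2 d-1"
UNIT_GC_YEAR = "gC m-2 y-1"


@dataclass
class FluxMap:
    """Per-pixel flux estimate + epistemic sigma on one grid.

    estimate/sigma: (T, H, W) arrays (T = 1 for annual maps); sigma shares
    the estimate's units and mask.  ``flags`` counts out-of-range predictor
    bands per pixel.  ``sign_convention`` records the NEE sign (positive =
    uptake) so consistency checks can refuse to mix conventions silently.
    """

    estimate: np.ndarray
    sigma: np.ndarray
    variable: str
    units: str
    geo: GridGeo
    times: np.ndarray
    mask: np.ndarray
    ndays: np.ndarray | None = None
    flags: np.ndarray | None = None
    sign_convention: str = "uptake_positive"

    def __post_init__(self) -> None:
        est = np.asarray(self.estimate, dtype=float)
        if est.ndim == 2:
            est = est[None]
        sig = np.asarray(self.sigma, dtype=float).reshape(est.shape)
        mask = np.asarray(self.mask, dtype=bool).reshape(est.shape)
        if np.any(sig[~mask] < 0):
            raise ValueError("sigma must be >= 0 on unmasked pixels")
        self.estimate, self.sigma, self.mask = est, sig, mask
        self.times = np.asarray(self.times, dtype="datetime64[D]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.estimate.shape

    def to_scene(self) -> GridScene:
        """Lossless view as a GridScene for raster writing."""
        bands = {"estimate": _masked(self.estimate, self.mask),
                 "sigma": _masked(self.sigma, self.mask)}
        if self.flags is not None:
            bands["flags"] = np.broadcast_to(
                np.asarray(self.flags, dtype=float), self.estimate.shape
            ).copy()
        return GridScene(bands, self.geo, self.times, ndays=self.ndays)


def _masked(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[mask] = np.nan
    return out


def composite_8day(
    daily: GridScene, min_valid_days: int = 4
) -> GridScene:
    """Average a daily stack into 8-day composites anchored at Jan 1.

    A 365-day year yields 46 composites, the last covering 5 days (6 in leap
    years).  Pixels with fewer than ``min_valid_days`` valid days in a
    window (or the full window, if shorter) are masked.
    """
    times = daily.times
    years = times.astype("datetime64[Y]")
    doy = (times - years.astype("datetime64[D]")).astype(int)  # 0-based
    window = doy // 8
    keys = list(dict.fromkeys(zip(years.tolist(), window.tolist())))

    T_out = len(keys)
    H, W = daily.height, daily.width
    out_bands = {n: np.full((T_out, H, W), np.nan) for n in daily.band_names}
    out_times = np.empty(T_out, dtype="datetime64[D]")
    out_ndays = np.empty(T_out, dtype=int)
    valid = ~daily.mask
    for t_out, (yr, win) in enumerate(keys):
        sel = (years == np.datetime64(yr, "Y")) & (window == win)
        nv = valid[sel].sum(axis=0)  # valid days per pixel
        need = min(min_valid_days, int(sel.sum()))
        good = nv >= max(need, 1)
        for name, arr in daily.bands.items():
            a = np.where(valid[sel], arr[sel], 0.0)
            with np.errstate(invalid="ignore"):
                mean = np.where(good, a.sum(axis=0) / np.maximum(nv, 1), np.nan)
            out_bands[name][t_out] = mean
        out_times[t_out] = np.datetime64(yr, "Y").astype("datetime64[D]") + \
            np.timedelta64(win * 8, "D")
        out_ndays[t_out] = int(sel.sum())
    return GridScene(out_bands, daily.geo, out_times, ndays=out_ndays)


def resample_to_grid(
    src: GridScene,
    target_geo: GridGeo,
    target_shape: tuple[int, int],
    method: str = "bilinear",
) -> GridScene:
    """Resample every band of ``src`` onto a target grid.

    ``bilinear`` uses mask-aware weights (nodata never bleeds into valid
    output; a target pixel whose four neighbours are all invalid is masked);
    ``nearest`` is for categorical maps and introduces no new values.
    Pixel-center convention; edge pixels extrapolate as constants.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    Ht, Wt = target_shape
    xt = target_geo.x_centers(Wt)
    yt = target_geo.y_centers(Ht)
    # fractional source pixel coordinates of the target centers
    col_f = (xt - src.geo.x0) / src.geo.dx - 0.5
    row_f = (src.geo.y0 - yt) / src.geo.dy - 0.5

    Hs, Ws = src.height, src.width
    if (col_f.max() < -0.5 or col_f.min() > Ws - 0.5 or
            row_f.max() < -0.5 or row_f.min() > Hs - 0.5):
        raise ValueError("source and target grids do not overlap spatially")

    T = src.n_times
    out_bands = {n: np.empty((T, Ht, Wt)) for n in src.band_names}
    if method == "nearest":
        rows = np.clip(np.round(row_f).astype(int), 0, Hs - 1)
        cols = np.clip(np.round(col_f).astype(int), 0, Ws - 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        for name, arr in src.bands.items():
            res = arr[:, rr, cc]
            res[src.mask[:, rr, cc]] = np.nan
            out_bands[name] = res
    else:
        r0f = np.floor(row_f).astype(int)
        c0f = np.floor(col_f).astype(int)
        r0 = np.clip(r0f, 0, Hs - 1)
        c0 = np.clip(c0f, 0, Ws - 1)
        r1 = np.clip(r0f + 1, 0, Hs - 1)
        c1 = np.clip(c0f + 1, 0, Ws - 1)
        fr = np.clip(row_f - r0f, 0.0, 1.0)
        fc = np.clip(col_f - c0f, 0.0, 1.0)
        # outside the outermost pixel centers both neighbours coincide:
        # constant extrapolation
        fr = np.where(r1 == r0, 0.0, fr)
        fc = np.where(c1 == c0, 0.0, fc)
        FR, FC = np.meshgrid(fr, fc, indexing="ij")
        corners = [(r0, c0, (1 - FR) * (1 - FC)), (r0, c1, (1 - FR) * FC),
                   (r1, c0, FR * (1 - FC)), (r1, c1, FR * FC)]
        for name, arr in src.bands.items():
            num = np.zeros((T, Ht, Wt))
            den = np.zeros((T, Ht, Wt))
            for rows, cols, w in corners:
                rr, cc = np.meshgrid(rows, cols, indexing="ij")
                vals = arr[:, rr, cc]
                ok = ~src.mask[:, rr, cc]
                wt = w[None] * ok
                num += np.where(ok, vals, 0.0) * wt
                den += wt
            with np.errstate(invalid="ignore", divide="ignore"):
                out_bands[name] = np.where(den > 0, num / den, np.nan)
    return GridScene(out_bands, target_geo, src.times, ndays=src.ndays)


def predict_map(
    model: gpr.TrainedGPR,
    scene: GridScene,
    schema: PredictorSchema | None = None,
    oor_policy: str = "clamp",
    chunk_size: int = 4096,
    include_noise: bool = False,
) -> FluxMap:
    """Per-pixel flux estimate and epistemic sigma from a predictor scene.

    The scene must carry one band per model predictor, all co-registered
    (resample first).  Out-of-range pixels are clamped to the schema range
    and counted in the ``flags`` raster (default) or masked.  Evaluation is
    chunked; chunking does not change the result.
    """
    if oor_policy not in ("clamp", "mask"):
        raise ValueError(f"unknown out-of-range policy {oor_policy!r}")
    names = list(model.training.predictor_names)
    missing = [n for n in names if n not in scene.bands]
    if missing:
        raise ValueError(f"scene is missing predictor band(s): {missing}")

    T, H, W = scene.shape
    Xall = scene.stack(names).reshape(-1, len(names))
    mask = scene.mask.reshape(-1).copy()

    flags = np.zeros(Xall.shape[0], dtype=np.int16)
    if schema is not None:
        for j, name in enumerate(names):
            p = schema[name]
            out = (Xall[:, j] < p.valid_min) | (Xall[:, j] > p.valid_max)
            out &= ~mask
            flags += out.astype(np.int16)
            if oor_policy == "clamp":
                Xall[:, j] = np.clip(Xall[:, j], p.valid_min, p.valid_max)
        if oor_policy == "mask":
            mask |= flags > 0

    est = np.full(Xall.shape[0], np.nan)
    sig = np.full(Xall.shape[0], np.nan)
    idx = np.flatnonzero(~mask)
    if idx.size:
        Xv = np.nan_to_num(Xall[idx], nan=0.0)
        pred = gpr.predict(model, Xv, include_noise=include_noise,
                           chunk_size=chunk_size)
        est[idx] = pred.mean
        sig[idx] = pred.sigma
    return FluxMap(
        estimate=est.reshape(T, H, W),
        sigma=np.where(mask, 0.0, sig).reshape(T, H, W),
        variable=model.training.flux_variable,
        units=UNIT_UMOL_S,
        geo=scene.geo,
        times=scene.times,
        mask=mask.reshape(T, H, W),
        ndays=scene.ndays,
        flags=flags.reshape(T, H, W),
    )


def convert_flux_units(
    value, from_units: str, to_units: str, days_per_year: int = 365
):
    """Convert between umol CO2 m-2 s-1, gC m-2 d-1, and gC m-2 y-1.

    Uses the molar mass of carbon (12.011 g/mol); the yearly rate assumes
    ``days_per_year`` days.  Round trips are identity to ~1e-16 relative.
    """
    to_daily = {
        UNIT_UMOL_S: CARBON_MOLAR_MASS * 1e-6 * SECONDS_PER_DAY,
        UNIT_GC_DAY: 1.0,
        UNIT_GC_YEAR: 1.0 / days_per_year,
    }
    if from_units not in to_daily or to_units not in to_daily:
        raise ValueError(
            f"unsupported unit pair {from_units!r} -> {to_units!r}"
        )
    return np.multiply(value, to_daily[from_units] / to_daily[to_units])


def aggregate_annual(
    maps: list[FluxMap],
    coverage_threshold: float = 0.8,
    days_per_year: int = 365,
) -> FluxMap:
    """Aggregate a year of composite FluxMaps to an annual total map.

    The annual total is the day-weighted mean flux converted to gC m-2 y-1;
    sigma is aggregated as the day-weighted root-mean-square of composite
    sigmas, converted identically — an upper-bound convention (it ignores
    temporal error cancellation), not a calibrated interval.  Pixels whose
    valid composites cover fewer than ``coverage_threshold`` of the year's
    days are masked.
    """
    if not maps:
        raise ValueError("need at least one composite map")
    first = maps[0]
    var = first.variable
    for m in maps:
        if m.variable != var:
            raise ValueError("cannot mix flux variables in annual aggregation")
        if m.units != UNIT_UMOL_S:
            raise ValueError("annual aggregation expects composite maps in "
                             f"{UNIT_UMOL_S}")
        if m.estimate.shape[1:] != first.estimate.shape[1:]:
            raise ValueError("all composites must share one grid")

    est = np.concatenate([m.estimate for m in maps], axis=0)
    sig = np.concatenate([m.sigma for m in maps], axis=0)
    mask = np.concatenate([m.mask for m in maps], axis=0)
    nd = np.concatenate([
        m.ndays if m.ndays is not None else np.full(m.shape[0], 8)
        for m in maps
    ]).astype(float)

    w = nd[:, None, None] * ~mask
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_flux = np.where(wsum > 0,
                             np.nansum(np.where(mask, 0.0, est) * w, axis=0)
                             / wsum, np.nan)
        rms_sigma = np.where(wsum > 0,
                             np.sqrt(np.nansum(np.where(mask, 0.0, sig**2) * w,
                                               axis=0) / wsum), np.nan)
    covered = wsum >= coverage_threshold * days_per_year
    out_mask = ~covered

    factor = convert_flux_units(1.0, UNIT_UMOL_S, UNIT_GC_YEAR,
                                days_per_year=days_per_year)
    year = first.times[0].astype("datetime64[Y]").astype("datetime64[D]")
    return FluxMap(
        estimate=np.where(covered, mean_flux * factor, np.nan)[None],
        sigma=np.where(covered, rms_sigma * factor, 0.0)[None],
        variable=var,
        units=UNIT_GC_YEAR,
        geo=first.geo,
        times=np.asarray([year]),
        mask=out_mask[None],
        ndays=np.asarray([int(wsum.max())]) if wsum.size else None,
        sign_convention=first.sign_convention,
    )
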