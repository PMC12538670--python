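"""Validation and benchmarking of gridded flux products.

Three analyses:

* **Tower validation** — extract the pixel containing each validation tower
  from a flux-map time series, score it against the tower's observed series,
  and summarize R2/rmse per vegetation class (median and quartiles, the
  boxplot statistics).
* **Gridded intercomparison** — per-pixel temporal Pearson R and rmse
  between two flux products over their common period, after regridding the
  finer product onto the coarser grid by area-weighted (block) mean; global
  medians summarize the maps.
* **NEE consistency** — compare NEE computed as GPP - RECO from separate
  models against the directly modeled NEE; sign conventions must match
  explicitly, there is no silent flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats.grids import GridGeo
from .training import compute_metrics
from .upscaling import FluxMap

__all__ = [
    "TowerObservation",
    "tower_validation",
    "gridded_intercompare",
    "nee_consistency",
]


@dataclass
class TowerObservation:
    """A validation tower: location, class, and observed 8-day flux series."""

    site_id: str
    x: float
    y: float
    vegetation_class: str
    series: np.ndarray  # aligned with the flux map's time index


def _pixel_of(geo: GridGeo, shape: tuple[int, int], x: float, y: float):
    col = int(np.floor((x - geo.x0) / geo.dx))
    row = int(np.floor((geo.y0 - y) / geo.dy))
    H, W = shape
    if not (0 <= row < H and 0 <= col < W):
        return None
    return row, col


def tower_validation(
    flux_maps: FluxMap,
    towers: list[TowerObservation],
    footprint: str = "pixel",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Score a flux-map series at tower locations; summarize per class.

    ``footprint="pixel"`` extracts the single containing pixel; ``"3x3"``
    averages the unmasked 3x3 neighbourhood (a crude footprint proxy,
    provided unclaimed).  Towers outside the grid are skipped with a
    warning string.  Returns (per-tower metrics, per-class summary with
    median/quartiles of R2 and rmse, warnings).
    """
    if footprint not in ("pixel", "3x3"):
        raise ValueError(f"unknown footprint {footprint!r}")
    T, H, W = flux_maps.shape
    rows = []
    warnings_list: list[str] = []
    for tw in towers:
        loc = _pixel_of(flux_maps.geo, (H, W), tw.x, tw.y)
        if loc is None:
            warnings_list.append(
                f"tower {tw.site_id} at ({tw.x}, {tw.y}) is outside the grid; "
                "skipped"
            )
            continue
        r, c = loc
        if footprint == "pixel":
            series = flux_maps.estimate[:, r, c].copy()
            series[flux_maps.mask[:, r, c]] = np.nan
        else:
            rs = slice(max(r - 1, 0), min(r + 2, H))
            cs = slice(max(c - 1, 0), min(c + 2, W))
            block = np.where(flux_maps.mask[:, rs, cs], np.nan,
                             flux_maps.estimate[:, rs, cs])
            with np.errstate(invalid="ignore"):
                series = np.nanmean(block.reshape(T, -1), axis=1)
        obs = np.asarray(tw.series, dtype=float)
        if obs.size != T:
            raise ValueError(
                f"tower {tw.site_id}: series length {obs.size} != map T {T}"
            )
        ok = np.isfinite(obs) & np.isfinite(series)
        if ok.sum() < 3:
            warnings_list.append(
                f"tower {tw.site_id}: fewer than 3 common composites; skipped"
            )
            continue
        m = compute_metrics(obs[ok], series[ok])
        rows.append({"site_id": tw.site_id,
                     "vegetation_class": tw.vegetation_class,
                     "r2": m.r2, "rmse": m.rmse, "n": m.n})
    per_tower = pd.DataFrame(rows)
    if per_tower.empty:
        return per_tower, pd.DataFrame(), warnings_list
    summary = per_tower.groupby("vegetation_class").agg(
        n_towers=("site_id", "count"),
        r2_median=("r2", "median"),
        r2_q1=("r2", lambda s: s.quantile(0.25)),
        r2_q3=("r2", lambda s: s.quantile(0.75)),
        rmse_median=("rmse", "median"),
        rmse_q1=("rmse", lambda s: s.quantile(0.25)),
        rmse_q3=("rmse", lambda s: s.quantile(0.75)),
    ).reset_index()
    return per_tower, summary, warnings_list


def _to_common_grid(a: FluxMap, b: FluxMap) -> tuple[FluxMap, FluxMap]:
    """Regrid the finer product onto the coarser grid by block mean."""
    if a.geo.dx == b.geo.dx and a.geo.dy == b.geo.dy:
        return a, b
    fine, coarse, swapped = (a, b, False) if a.geo.dx < b.geo.dx else (b, a, True)
    rx = coarse.geo.dx / fine.geo.dx
    ry = coarse.geo.dy / fine.geo.dy
    if abs(rx - round(rx)) > 1e-9 or abs(ry - round(ry)) > 1e-9:
        raise ValueError("grid resolutions are not integer multiples; "
                         "cannot block-average")
    rx, ry = int(round(rx)), int(round(ry))
    T, H, W = fine.shape
    Hc, Wc = H // ry, W // rx
    est = np.where(fine.mask, np.nan, fine.estimate)
    est = est[:, : Hc * ry, : Wc * rx].reshape(T, Hc, ry, Wc, rx)
    with np.errstate(invalid="ignore"):
        est = np.nanmean(est, axis=(2, 4))
    sig = np.where(fine.mask, np.nan, fine.sigma)
    sig = sig[:, : Hc * ry, : Wc * rx].reshape(T, Hc, ry, Wc, rx)
    with np.errstate(invalid="ignore"):
        sig = np.sqrt(np.nanmean(sig**2, axis=(2, 4)))
    regridded = FluxMap(
        estimate=est, sigma=np.nan_to_num(sig), variable=fine.variable,
        units=fine.units, geo=coarse.geo, times=fine.times,
        mask=~np.isfinite(est), ndays=fine.ndays,
        sign_convention=fine.sign_convention,
    )
    return (regridded, coarse) if not swapped else (coarse, regridded)


def gridded_intercompare(
    product_a: FluxMap, product_b: FluxMap, min_common: int = 3
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-pixel temporal Pearson R and rmse between two flux products.

    The finer product is block-averaged onto the coarser grid first.  The
    common period is the intersection of the two time indexes; pixels with
    fewer than ``min_common`` common composites are masked (NaN).  The
    summary reports the global median R and median rmse over valid pixels.
    """
    a, b = _to_common_grid(product_a, product_b)
    if a.estimate.shape[1:] != b.estimate.shape[1:]:
        raise ValueError("products do not share a grid after regridding")
    common, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    if common.size == 0:
        raise ValueError("products have no overlapping period")
    xa = np.where(a.mask, np.nan, a.estimate)[ia]
    xb = np.where(b.mask, np.nan, b.estimate)[ib]

    ok = np.isfinite(xa) & np.isfinite(xb)
    n = ok.sum(axis=0).astype(float)
    xa_v = np.where(ok, xa, 0.0)
    xb_v = np.where(ok, xb, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = xa_v.sum(axis=0) / n
        mb = xb_v.sum(axis=0) / n
        da = np.where(ok, xa - ma, 0.0)
        db = np.where(ok, xb - mb, 0.0)
        cov = (da * db).sum(axis=0)
        va = (da**2).sum(axis=0)
        vb = (db**2).sum(axis=0)
        r_map = cov / np.sqrt(va * vb)
        rmse_map = np.sqrt(np.where(ok, (xa - xb) ** 2, 0.0).sum(axis=0) / n)
    bad = n < min_common
    r_map[bad] = np.nan
    rmse_map[bad] = np.nan
    summary = {
        "median_r": float(np.nanmedian(r_map)),
        "median_rmse": float(np.nanmedian(rmse_map)),
        "n_pixels": int(np.isfinite(rmse_map).sum()),
        "n_common_composites": int(common.size),
    }
    return r_map, rmse_map, summary


def nee_consistency(
    gpp: FluxMap, reco: FluxMap, nee: FluxMap
) -> tuple[dict, dict]:
    """Difference map (GPP - RECO) - NEE_direct and summary quantiles.

    All three series must be on one grid, one time index, and one NEE sign
    convention (positive = uptake); mismatched sign tags raise.
    """
    tags = {gpp.sign_convention, reco.sign_convention, nee.sign_convention}
    if len(tags) != 1:
        raise ValueError(
            f"sign-convention tags disagree: {sorted(tags)}; refusing to "
            "flip silently"
        )
    if not (gpp.estimate.shape == reco.estimate.shape == nee.estimate.shape):
        raise ValueError("the three series must share one grid and period")
    if not (np.array_equal(gpp.times, reco.times)
            and np.array_equal(gpp.times, nee.times)):
        raise ValueError("time indexes are not aligned")
    mask = gpp.mask | reco.mask | nee.mask
    diff = np.where(mask, np.nan,
                    (gpp.estimate - reco.estimate) - nee.estimate)
    with np.errstate(invalid="ignore"):
        mean_map = np.nanmean(diff, axis=0)
        rmse_map = np.sqrt(np.nanmean(diff**2, axis=0))
    vals = diff[np.isfinite(diff)]
    summary = {
        "median_difference": float(np.median(vals)) if vals.size else np.nan,
        "mean_difference": float(vals.mean()) if vals.size else np.nan,
        "rmse": float(np.sqrt((vals**2).mean())) if vals.size else np.nan,
        "q05": float(np.quantile(vals, 0.05)) if vals.size else np.nan,
        "q95": float(np.quantile(vals, 0.95)) if vals.size else np.nan,
        "n": int(vals.size),
    }
    return {"mean": mean_map, "rmse": rmse_map, "diff": diff}, summary
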