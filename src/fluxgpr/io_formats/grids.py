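"""Gridded raster containers and NetCDF/GeoTIFF I/O.

Coordinate convention (used package-wide): north-up, row-major grids with
pixel-center registration.  ``GridGeo(x0, y0, dx, dy)`` places the center of
pixel (row, col) at ``x = x0 + (col + 0.5) dx`` and ``y = y0 - (row + 0.5)
dy`` where (x0, y0) is the outer corner of the top-left pixel and dx, dy > 0
are pixel sizes.

Two on-disk formats are supported:

* NetCDF (``.nc``) for time x y x x stacks, written through xarray's scipy
  backend (NETCDF3_CLASSIC).  Payloads stay float64, so the round trip is
  bitwise lossless; masked cells are encoded as NaN.
* GeoTIFF-style TIFF (``.tif``/``.tiff``) for single-time multiband scenes,
  written with tifffile as float32 (round trip exact within float32
  quantization).  Georeferencing, band names, and the time stamp travel in a
  JSON ImageDescription tag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr

__all__ = ["GridGeo", "GridScene", "read_grid", "write_grid"]

DEFAULT_CRS = "EPSG:4326"


@dataclass(frozen=True)
class GridGeo:
    """Geotransform + CRS tag for a north-up pixel-center-registered grid."""

    x0: float
    y0: float
    dx: float
    dy: float
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("pixel sizes dx, dy must be > 0")

    def x_centers(self, width: int) -> np.ndarray:
        return self.x0 + (np.arange(width) + 0.5) * self.dx

    def y_centers(self, height: int) -> np.ndarray:
        return self.y0 - (np.arange(height) + 0.5) * self.dy

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "dx": self.dx, "dy": self.dy,
                "crs": self.crs}

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeo":
        return cls(d["x0"], d["y0"], d["dx"], d["dy"], d.get("crs", DEFAULT_CRS))


class GridScene:
    """Co-registered multiband raster stack with a time axis.

    bands: mapping predictor name -> (T, H, W) float array.
    times: length-T array of composite start dates (numpy datetime64[D]).
    ndays: optional length-T array of days covered by each composite.
    mask:  (T, H, W) boolean, True where invalid; always the union of
           per-band non-finite cells and any explicit mask supplied.
    """

    def __init__(
        self,
        bands: dict[str, np.ndarray],
        geo: GridGeo,
        times: np.ndarray | list,
        mask: np.ndarray | None = None,
        ndays: np.ndarray | None = None,
    ):
        if not bands:
            raise ValueError("scene needs at least one band")
        arrs = {}
        shape = None
        for name, arr in bands.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                arr = arr[None, :, :]
            if arr.ndim != 3:
                raise ValueError(f"band {name!r} must be (T, H, W)")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"band {name!r} shape {arr.shape} != {shape}"
                )
            arrs[name] = arr
        self.bands = arrs
        self.geo = geo
        self.times = np.asarray(times, dtype="datetime64[D]")
        if self.times.size != shape[0]:
            raise ValueError(
                f"time index length {self.times.size} != band T {shape[0]}"
            )
        invalid = np.zeros(shape, dtype=bool)
        for arr in arrs.values():
            invalid |= ~np.isfinite(arr)
        if mask is not None:
            invalid |= np.asarray(mask, dtype=bool).reshape(shape)
        self.mask = invalid
        self.ndays = None if ndays is None else np.asarray(ndays, dtype=int)
        if self.ndays is not None and self.ndays.size != shape[0]:
            raise ValueError("ndays length must match time index")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def n_times(self) -> int:
        return self.shape[0]

    @property
    def height(self) -> int:
        return self.shape[1]

    @property
    def width(self) -> int:
        return self.shape[2]

    @property
    def band_names(self) -> list[str]:
        return list(self.bands.keys())

    def stack(self, names: list[str] | None = None) -> np.ndarray:
        """(T, H, W, D) array of the named bands in order."""
        names = names or self.band_names
        missing = [n for n in names if n not in self.bands]
        if missing:
            raise KeyError(f"scene is missing predictor band(s): {missing}")
        return np.stack([self.bands[n] for n in names], axis=-1)

    def select_time(self, t: int) -> "GridScene":
        return GridScene(
            {n: a[t : t + 1] for n, a in self.bands.items()},
            self.geo,
            self.times[t : t + 1],
            mask=self.mask[t : t + 1],
            ndays=None if self.ndays is None else self.ndays[t : t + 1],
        )


def write_grid(path: str | Path, scene, band_map: dict[str, str] | None = None) -> None:
    """Write a GridScene (or FluxMap via its ``to_scene``) to NetCDF or TIFF."""
    path = Path(path)
    if hasattr(scene, "to_scene"):
        scene = scene.to_scene()
    if path.suffix.lower() in (".nc", ".nc4", ".cdf"):
        _write_netcdf(path, scene)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_tiff(path, scene)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")


def read_grid(
    path: str | Path,
    band_map: dict[str, str] | None = None,
    default_crs: str = DEFAULT_CRS,
) -> GridScene:
    """Read a raster stack; ``band_map`` renames file variables to predictors."""
    path = Path(path)
    if path.suffix.lower() in (".nc", ".nc4", ".cdf"):
        scene = _read_netcdf(path, default_crs)
    elif path.suffix.lower() in (".tif", ".tiff"):
        scene = _read_tiff(path, default_crs)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")
    if band_map:
        scene.bands = {band_map.get(k, k): v for k, v in scene.bands.items()}
    return scene


def _write_netcdf(path: Path, scene: GridScene) -> None:
    data = {}
    for name, arr in scene.bands.items():
        out = arr.copy()
        out[scene.mask] = np.nan
        data[name] = (("time", "y", "x"), out)
    ds = xr.Dataset(
        data,
        coords={
            "time": scene.times.astype("datetime64[ns]"),
            "y": scene.geo.y_centers(scene.height),
            "x": scene.geo.x_centers(scene.width),
        },
        attrs={"geo": json.dumps(scene.geo.to_dict())},
    )
    if scene.ndays is not None:
        ds["ndays"] = ("time", scene.ndays)
    ds.to_netcdf(path, engine="scipy")


def _read_netcdf(path: Path, default_crs: str) -> GridScene:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if "geo" in ds.attrs:
        geo = GridGeo.from_dict(json.loads(ds.attrs["geo"]))
    else:
        # Reconstruct from coordinate vectors; CRS falls back to the default.
        warnings.warn(
            f"{path}: no CRS/geotransform metadata; assuming {default_crs}",
            stacklevel=2,
        )
        x = ds["x"].values
        y = ds["y"].values
        dx = float(x[1] - x[0]) if x.size > 1 else 1.0
        dy = float(y[0] - y[1]) if y.size > 1 else 1.0
        geo = GridGeo(float(x[0]) - dx / 2, float(y[0]) + dy / 2, dx, dy,
                      default_crs)
    ndays = None
    bands = {}
    for name, da in ds.data_vars.items():
        if name == "ndays":
            ndays = da.values.astype(int)
            continue
        arr = da.values.astype(float)
        if arr.ndim == 2:
            arr = arr[None]
        bands[name] = arr
    times = ds["time"].values.astype("datetime64[D]")
    return GridScene(bands, geo, times, ndays=ndays)


def _write_tiff(path: Path, scene: GridScene) -> None:
    if scene.n_times != 1:
        raise ValueError(
            "TIFF path stores single-time multiband scenes; use NetCDF for "
            "time series"
        )
    names = scene.band_names
    data = np.stack([scene.bands[n][0] for n in names]).astype(np.float32)
    data[:, scene.mask[0]] = np.nan
    meta = {
        "fluxgpr": 1,
        "geo": scene.geo.to_dict(),
        "bands": names,
        "time": str(scene.times[0]),
        "ndays": None if scene.ndays is None else int(scene.ndays[0]),
        "nodata": "nan",
    }
    tifffile.imwrite(path, data, description=json.dumps(meta))


def _read_tiff(path: Path, default_crs: str) -> GridScene:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta: dict = {}
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    if data.ndim == 2:
        data = data[None]
    if "geo" in meta:
        geo = GridGeo.from_dict(meta["geo"])
    else:
        warnings.warn(
            f"{path}: no georeferencing metadata; assuming unit grid in "
            f"{default_crs}",
            stacklevel=2,
        )
        geo = GridGeo(0.0, float(data.shape[-2]), 1.0, 1.0, default_crs)
    names = meta.get("bands") or [f"band_{i + 1}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} bands but {len(names)} band names"
        )
    time = np.asarray([meta.get("time", "2000-01-01")], dtype="datetime64[D]")
    ndays = meta.get("ndays")
    bands = {n: data[i][None].astype(float) for i, n in enumerate(names)}
    return GridScene(
        bands, geo, time,
        ndays=None if ndays is None else np.asarray([ndays]),
    )
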