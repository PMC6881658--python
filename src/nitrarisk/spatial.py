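"""Inverse-distance-weighted (IDW) interpolation of well concentrations.

IDW predicts the concentration at an unsampled point as a weighted mean
of the observations, with weights proportional to ``d**-p`` where ``d``
is the distance to each well and ``p`` the power parameter (default 2).
Nearby wells therefore dominate, and because the weights are positive
and normalised the prediction is always a convex combination of the
data: the interpolated surface never over- or under-shoots the observed
range. A point closer than ``eps`` to a well returns that well's value
(exact-hit rule); coincident wells with different values are averaged.

Distances are planar Euclidean in degree space by default — adequate for
the small extents of a single well field — with an optional
equirectangular scaling of longitude by cos(mean latitude).
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .exposure import Sample, ValidationError

__all__ = [
    "GridSpec",
    "IDWParams",
    "Raster",
    "idw_predict",
    "interpolate_grid",
    "exceedance_mask",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: bbox (lon_min, lat_min, lon_max, lat_max), cell size in degrees."""

    bbox: tuple[float, float, float, float]
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        lon_min, lat_min, lon_max, lat_max = self.bbox
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ValidationError(f"degenerate bbox {self.bbox}")
        if not self.cell_size > 0:
            raise ValidationError("cell_size must be positive")

    @property
    def ncols(self) -> int:
        return max(1, math.ceil((self.bbox[2] - self.bbox[0]) / self.cell_size - 1e-9))

    @property
    def nrows(self) -> int:
        return max(1, math.ceil((self.bbox[3] - self.bbox[1]) / self.cell_size - 1e-9))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (nrows, ncols), row 0 at the north edge."""
        lons = self.bbox[0] + (np.arange(self.ncols) + 0.5) * self.cell_size
        lats = self.bbox[1] + (np.arange(self.nrows) + 0.5) * self.cell_size
        lats = lats[::-1]  # north-to-south row order (ESRI convention)
        return np.meshgrid(lons, lats)


@dataclass(frozen=True)
class IDWParams:
    power: float = 2.0
    max_neighbors: int | None = None
    search_radius: float | None = None
    eps: float = 1e-9  # exact-hit distance, degrees
    metric: str = "degrees"  # or "equirectangular"

    def __post_init__(self) -> None:
        if not self.power > 0:
            raise ValidationError("IDW power must be positive")
        if self.max_neighbors is not None and self.max_neighbors < 1:
            raise ValidationError("max_neighbors must be >= 1")
        if self.search_radius is not None and not self.search_radius > 0:
            raise ValidationError("search_radius must be positive")
        if self.metric not in ("degrees", "equirectangular"):
            raise ValidationError(f"unknown metric {self.metric!r}")


@dataclass
class Raster:
    """Row-major concentration grid; row 0 is the northernmost."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValidationError(
                f"raster shape {self.values.shape} inconsistent with grid "
                f"({self.grid.nrows}, {self.grid.ncols})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return self.values != self.grid.nodata


def _georeferenced(samples: Sequence[Sample]) -> list[Sample]:
    geo = [s for s in samples if s.has_coords]
    if len(geo) < len(samples):
        warnings.warn(
            f"{len(samples) - len(geo)} samples without coordinates excluded from interpolation",
            stacklevel=3,
        )
    if not geo:
        raise ValidationError("no georeferenced samples")
    return geo


def _dedupe(
    lon: np.ndarray, lat: np.ndarray, val: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average samples sharing a location (within eps), warn when collapsing."""
    keep_lon, keep_lat, keep_val = [], [], []
    used = np.zeros(lon.size, dtype=bool)
    merged = False
    for i in range(lon.size):
        if used[i]:
            continue
        same = (np.abs(lon - lon[i]) <= eps) & (np.abs(lat - lat[i]) <= eps) & ~used
        used |= same
        if same.sum() > 1:
            merged = True
        keep_lon.append(lon[same].mean())
        keep_lat.append(lat[same].mean())
        keep_val.append(val[same].mean())
    if merged:
        warnings.warn("coincident sample locations averaged before interpolation", stacklevel=4)
    return np.array(keep_lon), np.array(keep_lat), np.array(keep_val)


def _predict_points(
    tx: np.ndarray,
    ty: np.ndarray,
    samples: Sequence[Sample],
    params: IDWParams,
    nodata: float,
) -> np.ndarray:
    geo = _georeferenced(samples)
    lon = np.array([s.lon for s in geo], dtype=float)
    lat = np.array([s.lat for s in geo], dtype=float)
    val = np.array([s.cf for s in geo], dtype=float)
    lon, lat, val = _dedupe(lon, lat, val, params.eps)

    xscale = 1.0
    if params.metric == "equirectangular":
        xscale = math.cos(math.radians(float(lat.mean())))

    # (targets, samples) distance matrix; well fields are small enough
    dx = (tx[:, None] - lon[None, :]) * xscale
    dy = ty[:, None] - lat[None, :]
    d = np.hypot(dx, dy)

    out = np.full(tx.size, nodata, dtype=float)
    hit = d <= params.eps
    has_hit = hit.any(axis=1)
    for i in np.nonzero(has_hit)[0]:
        out[i] = val[hit[i]].mean()

    rest = ~has_hit
    if rest.any():
        dr = d[rest]
        sel = np.ones_like(dr, dtype=bool)
        if params.search_radius is not None:
            sel &= dr <= params.search_radius
        if params.max_neighbors is not None and params.max_neighbors < lon.size:
            k = params.max_neighbors
            order = np.argsort(dr, axis=1)
            keep = np.zeros_like(sel)
            rows = np.arange(dr.shape[0])[:, None]
            keep[rows, order[:, :k]] = True
            sel &= keep
        # normalise by the per-target minimum distance before exponentiation:
        # the factor cancels in the weighted mean, but distance ratios >= 1
        # neither overflow nor underflow, so very large powers stay stable
        dmin = np.where(sel, dr, np.inf).min(axis=1)
        pred = np.full(dr.shape[0], nodata)
        ok = np.isfinite(dmin)
        if ok.any():
            with np.errstate(under="ignore"):
                ratio = dr[ok] / dmin[ok, None]
                w = np.where(sel[ok], ratio**-params.power, 0.0)
            pred[ok] = (w * val[None, :]).sum(axis=1) / w.sum(axis=1)
        out[rest] = pred
    return out


def idw_predict(
    lon: float,
    lat: float,
    samples: Sequence[Sample],
    params: IDWParams = IDWParams(),
) -> float | None:
    """IDW prediction at a single point; None when no well is in range."""
    if not (math.isfinite(lon) and math.isfinite(lat)):
        raise ValidationError("target coordinates must be finite")
    v = _predict_points(
        np.array([lon], dtype=float), np.array([lat], dtype=float), samples, params, np.nan
    )[0]
    return None if math.isnan(v) else float(v)


def interpolate_grid(
    samples: Sequence[Sample],
    grid: GridSpec,
    params: IDWParams = IDWParams(),
) -> Raster:
    """IDW prediction at every cell center of ``grid``; deterministic."""
    glon, glat = grid.cell_centers()
    vals = _predict_points(glon.ravel(), glat.ravel(), samples, params, grid.nodata)
    return Raster(grid, vals.reshape(grid.nrows, grid.ncols))


def exceedance_mask(raster: Raster, guideline: float) -> Raster:
    """Binary raster, 1 where concentration strictly exceeds the guideline.

    Nodata cells stay nodata; intended for comparison against a
    drinking-water limit (e.g. 50 mg/L nitrate).
    """
    if not guideline > 0:
        raise ValidationError("guideline must be positive")
    out = np.where(raster.mask, (raster.values > guideline).astype(float), raster.grid.nodata)
    return Raster(raster.grid, out)
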