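"""Readers and writers for the package's interchange formats.

Sample tables travel as plain CSV with header ``id,lon,lat,no3_mg_l``
(the coordinate columns are optional, the concentration column is not);
rasters as ESRI ASCII grids (.asc); well points as GeoJSON; run
configuration as YAML or JSON. The CSV dialect is fixed — comma
separator, "." decimal point, UTF-8, LF — so outputs are byte-stable
across locales and re-runs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exposure import Sample, ValidationError
from .spatial import GridSpec, Raster

__all__ = [
    "read_samples",
    "write_samples",
    "write_esri_ascii",
    "read_esri_ascii",
    "write_geojson",
    "load_config",
]

CONCENTRATION_COLUMN = "no3_mg_l"


def read_samples(path: str | Path) -> list[Sample]:
    """Read and validate a sample CSV.

    The ``id`` column is optional (1-based row numbers are used when it
    is absent); ``lon``/``lat`` must appear together or not at all.
    Malformed rows raise a :class:`ValidationError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if CONCENTRATION_COLUMN not in df.columns:
        raise ValidationError(
            f"{path.name}: missing required column {CONCENTRATION_COLUMN!r} "
            f"(found {list(df.columns)})"
        )
    has_lon, has_lat = "lon" in df.columns, "lat" in df.columns
    if has_lon != has_lat:
        raise ValidationError(f"{path.name}: lon and lat columns must appear together")
    if df.empty:
        warnings.warn(f"{path.name}: no data rows", stacklevel=2)
        return []

    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = row._asdict()
        sid = str(rowd.get("id") or i)
        try:
            cf = float(rowd[CONCENTRATION_COLUMN])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path.name} row {i}: non-numeric concentration "
                f"{rowd[CONCENTRATION_COLUMN]!r}"
            ) from exc
        lon = lat = None
        if has_lon:
            lon_v, lat_v = rowd.get("lon"), rowd.get("lat")
            if not (pd.isna(lon_v) or pd.isna(lat_v)):
                lon, lat = float(lon_v), float(lat_v)
            elif not (pd.isna(lon_v) and pd.isna(lat_v)):
                raise ValidationError(f"{path.name} row {i}: lon/lat must both be set or both empty")
        try:
            samples.append(Sample(sid, cf, lon=lon, lat=lat))
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {i}: {exc}") from exc
    ids = [s.id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})
        raise ValidationError(f"{path.name}: duplicate sample ids {dup}")
    return samples


def write_samples(samples: Sequence[Sample], path: str | Path) -> None:
    """Write the standard sample CSV. Concentrations keep full repr precision."""
    path = Path(path)
    with_coords = any(s.has_coords for s in samples)
    lines = ["id,lon,lat," + CONCENTRATION_COLUMN if with_coords else "id," + CONCENTRATION_COLUMN]
    for s in samples:
        if with_coords:
            lon = repr(s.lon) if s.lon is not None else ""
            lat = repr(s.lat) if s.lat is not None else ""
            lines.append(f"{s.id},{lon},{lat},{s.cf!r}")
        else:
            lines.append(f"{s.id},{s.cf!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def write_esri_ascii(raster: Raster, path: str | Path, precision: int = 6) -> None:
    """Write a raster as an ESRI ASCII grid (NCOLS/NROWS/... header)."""
    g = raster.grid
    header = (
        f"NCOLS {g.ncols}\n"
        f"NROWS {g.nrows}\n"
        f"XLLCORNER {g.bbox[0]!r}\n"
        f"YLLCORNER {g.bbox[1]!r}\n"
        f"CELLSIZE {g.cell_size!r}\n"
        f"NODATA_VALUE {g.nodata!r}\n"
    )
    body = "\n".join(
        " ".join(f"{v:.{precision}g}" for v in row) for row in raster.values
    )
    Path(path).write_text(header + body + "\n", encoding="utf-8", newline="\n")


def read_esri_ascii(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_esri_ascii`."""
    text = Path(path).read_text(encoding="utf-8").strip().splitlines()
    hdr = {}
    for line in text[:6]:
        key, val = line.split(None, 1)
        hdr[key.upper()] = float(val)
    ncols, nrows = int(hdr["NCOLS"]), int(hdr["NROWS"])
    cell = hdr["CELLSIZE"]
    bbox = (
        hdr["XLLCORNER"],
        hdr["YLLCORNER"],
        hdr["XLLCORNER"] + ncols * cell,
        hdr["YLLCORNER"] + nrows * cell,
    )
    values = np.loadtxt(text[6:], dtype=float).reshape(nrows, ncols)
    return Raster(GridSpec(bbox, cell, nodata=hdr["NODATA_VALUE"]), values)


def write_geojson(samples: Sequence[Sample], path: str | Path) -> None:
    """Write georeferenced samples as a GeoJSON FeatureCollection of Points."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [s.lon, s.lat]},
            "properties": {"id": s.id, CONCENTRATION_COLUMN: s.cf},
        }
        for s in samples
        if s.has_coords
    ]
    obj = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8", newline="\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run-configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        obj = json.loads(text)
    else:
        obj = yaml.safe_load(text)
    if not isinstance(obj, dict):
        raise ValidationError(f"{path.name}: configuration must be a mapping")
    return obj
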