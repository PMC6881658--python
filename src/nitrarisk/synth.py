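"""Synthetic well networks and the packaged 66-sample survey fixture.

Two data sources live here:

* :func:`fixture_table2` — the published survey of 66 rural groundwater
  wells (nitrate 6-49 mg/L, right-skewed), shipped verbatim as the
  package's reference dataset. The wells carry no coordinates because
  none were published.
* :func:`generate_wells` — a seeded generator producing well networks
  with the same statistical structure: concentrations from a lognormal
  fitted to the fixture (or any :class:`~nitrarisk.montecarlo.DistributionSpec`),
  optionally laid over a smooth bilinear spatial trend plus Gaussian
  noise so that interpolation can be validated against a known surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exposure import Sample, ValidationError
from .montecarlo import DistributionSpec, _truncated_draw

__all__ = ["SynthConfig", "generate_wells", "fixture_table2", "FIXTURE_LOGNORMAL"]

#: The 66 published nitrate concentrations (mg/L), in survey order.
_FIXTURE_CONCENTRATIONS = (
    12.0, 18.5, 24.0, 14.0, 9.0, 12.0, 13.5, 17.5, 15.0, 17.0,
    20.0, 28.0, 14.5, 13.0, 17.6, 14.5, 10.0, 6.5, 16.5, 15.0,
    8.5, 6.5, 9.0, 18.5, 12.0, 13.0, 16.5, 10.0, 13.5, 25.0,
    12.0, 12.0, 13.5, 17.0, 49.0, 17.0, 19.5, 11.5, 15.0, 12.5,
    18.0, 14.5, 13.0, 15.5, 11.5, 14.5, 11.0, 13.0, 15.8, 16.5,
    6.0, 16.0, 15.5, 16.0, 13.0, 13.0, 10.0, 12.5, 23.5, 13.0,
    26.5, 8.5, 20.5, 14.0, 13.0, 12.5,
)

#: Maximum-likelihood lognormal fit (mu, sigma on the log scale) to the
#: fixture concentrations; the default generating distribution.
FIXTURE_LOGNORMAL = DistributionSpec("lognormal", (2.6518606930386418, 0.343615667125744))

#: Approximate extent of the surveyed area in south-east Iran
#: (lon_min, lat_min, lon_max, lat_max), decimal degrees.
DEFAULT_BBOX = (60.45, 26.95, 60.95, 27.45)


def fixture_table2() -> list[Sample]:
    """The 66 published well measurements, ids "1".."66", no coordinates."""
    return [Sample(str(i + 1), c) for i, c in enumerate(_FIXTURE_CONCENTRATIONS)]


@dataclass(frozen=True)
class SynthConfig:
    """Settings for the synthetic well generator.

    In ``random`` mode concentrations are i.i.d. draws from ``conc_dist``.
    In ``trend_plus_noise`` mode concentration = bilinear surface of the
    (normalised) coordinates plus Gaussian noise, floored at zero; the
    ``trend`` coefficients (a0, ax, ay, axy) act on coordinates rescaled
    to [0, 1] over the bbox, so the surface is bbox-relative.
    """

    n_wells: int = 66
    seed: int = 0
    conc_dist: DistributionSpec = FIXTURE_LOGNORMAL
    spatial_mode: str = "random"
    trend: tuple[float, float, float, float] = (10.0, 20.0, 5.0, 0.0)
    noise_sd: float = 0.0
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValidationError("n_wells must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.spatial_mode not in ("random", "trend_plus_noise"):
            raise ValidationError(f"unknown spatial_mode {self.spatial_mode!r}")
        lon_min, lat_min, lon_max, lat_max = self.bbox
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ValidationError(f"degenerate bbox {self.bbox}")


def trend_surface(
    lon, lat, trend: tuple[float, float, float, float], bbox: tuple[float, float, float, float]
):
    """Bilinear surface a0 + ax*u + ay*v + axy*u*v on bbox-normalised coords."""
    lon_min, lat_min, lon_max, lat_max = bbox
    u = (np.asarray(lon, dtype=float) - lon_min) / (lon_max - lon_min)
    v = (np.asarray(lat, dtype=float) - lat_min) / (lat_max - lat_min)
    a0, ax, ay, axy = trend
    return a0 + ax * u + ay * v + axy * u * v


def generate_wells(config: SynthConfig) -> list[Sample]:
    """Seed-reproducible synthetic wells scattered uniformly in the bbox."""
    rng = np.random.default_rng(config.seed)
    lon_min, lat_min, lon_max, lat_max = config.bbox
    lon = rng.uniform(lon_min, lon_max, config.n_wells)
    lat = rng.uniform(lat_min, lat_max, config.n_wells)
    if config.spatial_mode == "trend_plus_noise":
        cf = trend_surface(lon, lat, config.trend, config.bbox)
        if config.noise_sd > 0:
            cf = cf + rng.normal(0.0, config.noise_sd, config.n_wells)
        cf = np.maximum(cf, 0.0)
    else:
        cf = _truncated_draw(config.conc_dist, rng, config.n_wells)
        cf = np.maximum(cf, 0.0)
    return [
        Sample(str(i + 1), float(cf[i]), lon=float(lon[i]), lat=float(lat[i]))
        for i in range(config.n_wells)
    ]
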