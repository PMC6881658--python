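"""Deterministic ingestion-exposure and hazard-quotient computation.

The non-carcinogenic risk model for a single contaminant ingested with
drinking water is the standard two-step chronic-exposure calculation:

    EDI = C_f * C_d / B_w         (estimated daily intake, mg/kg/day)
    HQ  = EDI / RfD               (hazard quotient, dimensionless)

where ``C_f`` is the contaminant concentration in water (mg/L), ``C_d``
the daily water intake (L/day), ``B_w`` body weight (kg) and ``RfD`` the
oral reference dose (mg/kg/day; 1.6 for nitrate per the IRIS database).
``HQ > 1`` flags exposure above the level considered safe for lifetime
ingestion; ``HQ < 1`` means no adverse non-carcinogenic effect is
expected.

Four age-group parameterisations (infant, children, teenager, adults)
ship as :data:`DEFAULT_GROUPS`.
"""

from __future__ import annotations

import decimal
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Sample",
    "ExposureGroup",
    "RiskResult",
    "RiskSummary",
    "DEFAULT_GROUPS",
    "ValidationError",
    "compute_edi",
    "compute_hq",
    "assess",
    "summarize",
    "summarize_concentrations",
    "exceedance_flags",
    "round_half_up",
]

NITRATE_RFD = 1.6
"""Oral reference dose for nitrate, mg/kg body weight per day (IRIS)."""


class ValidationError(ValueError):
    """Raised when input data violate the model's domain constraints."""


@dataclass(frozen=True)
class Sample:
    """One well measurement: id, optional lon/lat, concentration in mg/L."""

    id: str
    cf: float
    lon: float | None = None
    lat: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cf) and self.cf >= 0):
            raise ValidationError(
                f"sample {self.id!r}: concentration must be finite and >= 0, got {self.cf}"
            )
        if (self.lon is None) != (self.lat is None):
            raise ValidationError(
                f"sample {self.id!r}: lon and lat must be given together"
            )
        if self.lon is not None and not (
            math.isfinite(self.lon) and math.isfinite(self.lat)
        ):
            raise ValidationError(f"sample {self.id!r}: non-finite coordinates")

    @property
    def has_coords(self) -> bool:
        return self.lon is not None


@dataclass(frozen=True)
class ExposureGroup:
    """Named exposure group: intake C_d (L/day), weight B_w (kg), RfD (mg/kg/day)."""

    name: str
    cd: float
    bw: float
    rfd: float = NITRATE_RFD

    def __post_init__(self) -> None:
        for attr in ("cd", "bw", "rfd"):
            v = getattr(self, attr)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"exposure group {self.name!r}: {attr} must be positive, got {v}"
                )


#: Age-group parameter sets used throughout: (C_d L/day, B_w kg, RfD mg/kg/day).
DEFAULT_GROUPS: tuple[ExposureGroup, ...] = (
    ExposureGroup("infant", cd=0.08, bw=10.0),
    ExposureGroup("children", cd=0.85, bw=15.0),
    ExposureGroup("teenager", cd=2.0, bw=50.0),
    ExposureGroup("adults", cd=2.5, bw=78.0),
)


@dataclass(frozen=True)
class RiskResult:
    sample_id: str
    group_name: str
    edi: float
    hq: float


@dataclass(frozen=True)
class RiskSummary:
    """Per-group summary statistics of C_f, EDI and HQ over a result set."""

    group_name: str
    n: int
    cf: dict[str, float] = field(repr=False)
    edi: dict[str, float] = field(repr=False)
    hq: dict[str, float]


def compute_edi(cf, group: ExposureGroup):
    """Estimated daily intake C_f*C_d/B_w in mg/kg/day.

    ``cf`` may be a scalar or array of concentrations (mg/L).
    """
    cf = np.asarray(cf, dtype=float)
    if not np.all(np.isfinite(cf) & (cf >= 0)):
        raise ValidationError("concentration must be finite and >= 0")
    out = cf * group.cd / group.bw
    return float(out) if out.ndim == 0 else out


def compute_hq(edi, rfd: float = NITRATE_RFD):
    """Hazard quotient EDI/RfD (dimensionless). Scalar or array ``edi``."""
    if not (math.isfinite(rfd) and rfd > 0):
        raise ValidationError(f"reference dose must be positive, got {rfd}")
    edi = np.asarray(edi, dtype=float)
    out = edi / rfd
    return float(out) if out.ndim == 0 else out


def _check_unique_ids(samples: Sequence[Sample]) -> None:
    seen: dict[str, int] = {}
    for s in samples:
        seen[s.id] = seen.get(s.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate sample ids: {dups}")


def assess(
    samples: Sequence[Sample], groups: Sequence[ExposureGroup] = DEFAULT_GROUPS
) -> list[RiskResult]:
    """One :class:`RiskResult` per (sample, group), in input order.

    Samples iterate in the outer loop so results for one well are adjacent.
    """
    samples = list(samples)
    groups = list(groups)
    if not samples:
        raise ValidationError("no samples given")
    if not groups:
        raise ValidationError("no exposure groups given")
    _check_unique_ids(samples)
    out = []
    for s in samples:
        for g in groups:
            edi = compute_edi(s.cf, g)
            out.append(RiskResult(s.id, g.name, edi, compute_hq(edi, g.rfd)))
    return out


def _stats(values: np.ndarray) -> dict[str, float]:
    # sample SD (n-1); a single observation has SD 0 by convention
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return {
        "mean": float(values.mean()),
        "min": float(values.min()),
        "max": float(values.max()),
        "sd": sd,
    }


def summarize(
    results: Iterable[RiskResult], by: str, samples: Sequence[Sample] | None = None
) -> RiskSummary:
    """Mean/min/max/SD of EDI and HQ for the group named ``by``.

    If ``samples`` is given, the same statistics of the underlying
    concentrations are included (otherwise the C_f block is empty).
    SD is the sample standard deviation (n-1 denominator).
    """
    rs = [r for r in results if r.group_name == by]
    if not rs:
        raise ValidationError(f"no results for group {by!r}")
    edi = np.array([r.edi for r in rs])
    hq = np.array([r.hq for r in rs])
    cf_stats: dict[str, float] = {}
    if samples is not None:
        cf_stats = _stats(np.array([s.cf for s in samples], dtype=float))
    return RiskSummary(by, len(rs), cf_stats, _stats(edi), _stats(hq))


def summarize_concentrations(samples: Sequence[Sample]) -> dict[str, float]:
    """Mean/min/max/SD of the raw concentrations (mg/L)."""
    if not samples:
        raise ValidationError("no samples given")
    return _stats(np.array([s.cf for s in samples], dtype=float))


def exceedance_flags(
    results: Iterable[RiskResult], threshold: float = 1.0
) -> list[tuple[str, str, bool]]:
    """(sample_id, group_name, HQ strictly above threshold) per result."""
    if not threshold > 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    return [(r.sample_id, r.group_name, r.hq > threshold) for r in results]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, the convention of printed risk tables.

    Spreadsheet software rounds 0.31875 at 4 decimals to 0.3188, unlike
    banker's rounding; use this when comparing against published tables.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))
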