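"""Monte-Carlo propagation of exposure-parameter uncertainty into HQ.

Any of the three model inputs (concentration C_f, intake C_d, weight B_w)
can be declared a probability distribution; repeated independent draws of
the triple are pushed through the deterministic EDI/HQ model, yielding an
output distribution that is summarised by mean, SD, percentiles (P90 by
default), the probability of exceeding HQ = 1, and a contribution-to-
variance sensitivity decomposition.

The default configuration treats only the concentration as stochastic —
it is the one input for which measurement data exist — fitted by maximum
likelihood among candidate families and selected by the Kolmogorov-
Smirnov statistic. Intake and weight default to point masses at the
group's nominal values, so that an all-point-mass configuration collapses
exactly onto the deterministic result.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .exposure import ExposureGroup, Sample, ValidationError, compute_edi, compute_hq

__all__ = [
    "DistributionSpec",
    "MCConfig",
    "MCResult",
    "fit_concentration_distribution",
    "simulate_hq",
    "percentile",
    "sensitivity_ctv",
    "prob_exceedance",
]

_KINDS = ("point", "normal", "lognormal", "uniform", "triangular", "empirical")

#: Hard cap on redraw attempts for physically impossible values,
#: expressed as a multiple of the requested iteration count.
MAX_REDRAW_FACTOR = 10


@dataclass(frozen=True)
class DistributionSpec:
    """A named parametric distribution (or point mass) for one model input.

    Parameter conventions by ``kind``:

    - ``point``: (value,)
    - ``normal``: (mean, sd)
    - ``lognormal``: (mu, sigma) of the underlying normal (log scale)
    - ``uniform``: (low, high)
    - ``triangular``: (low, mode, high)
    - ``empirical``: the observed values, resampled with replacement

    ``truncation`` optionally clips support to [low, high] by rejection.
    """

    kind: str
    params: tuple[float, ...]
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown distribution kind {self.kind!r}")
        p = self.params
        ok = {
            "point": lambda: len(p) == 1,
            "normal": lambda: len(p) == 2 and p[1] >= 0,
            "lognormal": lambda: len(p) == 2 and p[1] >= 0,
            "uniform": lambda: len(p) == 2 and p[0] < p[1],
            "triangular": lambda: len(p) == 3 and p[0] <= p[1] <= p[2] and p[0] < p[2],
            "empirical": lambda: len(p) >= 1,
        }[self.kind]
        if not ok():
            raise ValidationError(f"invalid params {p} for {self.kind} distribution")
        if self.truncation is not None and not self.truncation[0] < self.truncation[1]:
            raise ValidationError(f"invalid truncation bounds {self.truncation}")

    @property
    def is_point(self) -> bool:
        return self.kind == "point" or (
            self.kind == "empirical" and len(set(self.params)) == 1
        )

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Raw draws ignoring truncation (see :func:`_truncated_draw`)."""
        p = self.params
        if self.kind == "point":
            return np.full(size, p[0])
        if self.kind == "normal":
            return rng.normal(p[0], p[1], size)
        if self.kind == "lognormal":
            return rng.lognormal(p[0], p[1], size)
        if self.kind == "uniform":
            return rng.uniform(p[0], p[1], size)
        if self.kind == "triangular":
            return rng.triangular(p[0], p[1], p[2], size)
        return rng.choice(np.asarray(p, dtype=float), size=size, replace=True)


def _truncated_draw(spec: DistributionSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw ``size`` values honouring the spec's truncation by rejection."""
    if spec.truncation is None:
        return spec.draw(rng, size)
    lo, hi = spec.truncation
    base = replace(spec, truncation=None)
    out = np.empty(size)
    filled = 0
    attempts = 0
    while filled < size:
        attempts += 1
        if attempts > 1000:
            raise ValidationError(
                f"truncation {spec.truncation} incompatible with {spec.kind} distribution"
            )
        cand = base.draw(rng, size - filled)
        keep = cand[(cand >= lo) & (cand <= hi)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


@dataclass(frozen=True)
class MCConfig:
    """Simulation settings: iteration count, seed, percentiles, input specs.

    ``input_specs`` maps the symbols ``cf``, ``cd``, ``bw`` to
    :class:`DistributionSpec`; a missing entry means a point mass at the
    exposure group's nominal value.
    """

    input_specs: dict[str, DistributionSpec] = field(default_factory=dict)
    n_iterations: int = 10_000
    seed: int = 0
    percentiles: tuple[float, ...] = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if not all(0 < p < 1 for p in self.percentiles):
            raise ValidationError("percentile probabilities must lie in (0, 1)")
        unknown = set(self.input_specs) - {"cf", "cd", "bw"}
        if unknown:
            raise ValidationError(f"unknown input symbols {sorted(unknown)}")


@dataclass(frozen=True)
class MCResult:
    group_name: str
    n_iterations: int
    mean: float
    sd: float
    percentile_table: dict[float, float]
    prob_exceedance: float
    sensitivity: dict[str, float]
    n_rejected: int
    hq_draws: np.ndarray = field(repr=False)


def fit_concentration_distribution(
    samples: Sequence[Sample],
    candidates: Sequence[str] = ("lognormal", "normal"),
) -> DistributionSpec:
    """Fit candidate families to observed concentrations, pick the best.

    Each candidate is fitted by maximum likelihood; the winner has the
    smallest Kolmogorov-Smirnov statistic, ties broken by log-likelihood.
    Constant data collapse to a point mass; if every candidate fit fails,
    the empirical distribution of the data is returned with a warning.
    """
    x = np.array([s.cf for s in samples], dtype=float)
    x = x[x > 0]
    if x.size < 5:
        raise ValidationError("need at least 5 positive concentrations to fit")
    if np.ptp(x) == 0:
        return DistributionSpec("point", (float(x[0]),))

    fits: list[tuple[float, float, DistributionSpec]] = []
    for kind in candidates:
        try:
            if kind == "lognormal":
                s, _, scale = stats.lognorm.fit(x, floc=0)
                spec = DistributionSpec("lognormal", (float(np.log(scale)), float(s)))
                frozen = stats.lognorm(s, 0, scale)
            elif kind == "normal":
                mu, sd = stats.norm.fit(x)
                spec = DistributionSpec("normal", (float(mu), float(sd)))
                frozen = stats.norm(mu, sd)
            elif kind == "uniform":
                lo, w = stats.uniform.fit(x)
                spec = DistributionSpec("uniform", (float(lo), float(lo + w)))
                frozen = stats.uniform(lo, w)
            elif kind == "triangular":
                c, lo, w = stats.triang.fit(x)
                spec = DistributionSpec(
                    "triangular", (float(lo), float(lo + c * w), float(lo + w))
                )
                frozen = stats.triang(c, lo, w)
            elif kind == "empirical":
                fits.append((np.inf, -np.inf, DistributionSpec("empirical", tuple(x))))
                continue
            elif kind == "point":
                continue
            else:
                raise ValidationError(f"unknown candidate kind {kind!r}")
            ks = stats.kstest(x, frozen.cdf).statistic
            loglik = float(np.sum(frozen.logpdf(x)))
            if not (math.isfinite(ks) and math.isfinite(loglik)):
                raise ValueError("degenerate fit")
            fits.append((float(ks), loglik, spec))
        except ValidationError:
            raise
        except Exception:
            continue
    proper = [f for f in fits if math.isfinite(f[0])]
    if proper:
        proper.sort(key=lambda t: (t[0], -t[1]))
        return proper[0][2]
    if any(f[2].kind == "empirical" for f in fits):
        return next(f[2] for f in fits if f[2].kind == "empirical")
    warnings.warn(
        "all candidate fits degenerate; falling back to the empirical distribution",
        stacklevel=2,
    )
    return DistributionSpec("empirical", tuple(x))


def _spec_for(symbol: str, group: ExposureGroup, config: MCConfig) -> DistributionSpec:
    if symbol in config.input_specs:
        return config.input_specs[symbol]
    nominal = {"cf": None, "cd": group.cd, "bw": group.bw}[symbol]
    if nominal is None:
        raise ValidationError("no distribution specified for cf (concentration)")
    return DistributionSpec("point", (nominal,))


def simulate_hq(group: ExposureGroup, config: MCConfig) -> MCResult:
    """Propagate the input distributions through EDI/HQ for one group.

    Draws ``n_iterations`` independent (C_f, C_d, B_w) triples. Physically
    impossible values (negative concentration, non-positive weight or
    intake) are rejected and redrawn; the redraw count is reported and
    capped at ``MAX_REDRAW_FACTOR``x the iteration count. Results are
    bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_iterations
    specs = {sym: _spec_for(sym, group, config) for sym in ("cf", "cd", "bw")}

    draws = {sym: np.empty(n) for sym in specs}
    filled = 0
    rejected = 0
    while filled < n:
        want = n - filled
        block = {sym: _truncated_draw(sp, rng, want) for sym, sp in specs.items()}
        ok = (block["cf"] >= 0) & (block["cd"] > 0) & (block["bw"] > 0)
        nok = int(ok.sum())
        rejected += want - nok
        if rejected > MAX_REDRAW_FACTOR * n:
            raise ValidationError(
                "rejection resampling exceeded the redraw cap; "
                "check the input distributions' support"
            )
        for sym in specs:
            draws[sym][filled : filled + nok] = block[sym][ok]
        filled += nok

    edi = draws["cf"] * draws["cd"] / draws["bw"]
    hq = np.atleast_1d(np.asarray(compute_hq(edi, group.rfd), dtype=float))

    stochastic = {sym: d for sym, d in draws.items() if not specs[sym].is_point}
    sens = sensitivity_ctv(stochastic, hq) if stochastic and np.ptp(hq) > 0 else {}
    table = {p: percentile(hq, p) for p in config.percentiles}
    if np.ptp(hq) == 0:
        # degenerate output: report the common value exactly (mean of n
        # identical floats would otherwise pick up accumulation error)
        mean, sd = float(hq[0]), 0.0
    else:
        mean = float(hq.mean())
        sd = float(hq.std(ddof=1)) if hq.size > 1 else 0.0
    return MCResult(
        group_name=group.name,
        n_iterations=n,
        mean=mean,
        sd=sd,
        percentile_table=table,
        prob_exceedance=prob_exceedance(hq),
        sensitivity=sens,
        n_rejected=rejected,
        hq_draws=hq,
    )


def percentile(draws, p: float) -> float:
    """Empirical quantile with linear interpolation between order statistics.

    This is the "type 7" rule (the default of numpy, R and spreadsheets):
    for sorted draws x_1..x_n the p-quantile interpolates between the
    order statistics at rank 1 + p(n-1).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValidationError("empty draws")
    if not 0 < p < 1:
        raise ValidationError(f"probability must lie in (0, 1), got {p}")
    return float(np.quantile(draws, p, method="linear"))


def sensitivity_ctv(
    input_draws: dict[str, np.ndarray], hq_draws
) -> dict[str, float]:
    """Contribution-to-variance: normalised squared Spearman correlations.

    For each stochastic input the squared Spearman rank correlation with
    the output is computed; the squares are normalised to sum to 1. This
    is the rank-based "contribution to variance" sensitivity measure used
    by spreadsheet risk tools, robust to the multiplicative model.
    """
    hq = np.asarray(hq_draws, dtype=float)
    if np.unique(hq).size < 2:
        raise ValidationError("need >= 2 distinct output values for sensitivity")
    raw = {}
    for sym, x in input_draws.items():
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            continue
        rho = stats.spearmanr(x, hq).statistic
        raw[sym] = float(rho) ** 2
    total = sum(raw.values())
    if total == 0:
        return {sym: 0.0 for sym in raw}
    return {sym: v / total for sym, v in raw.items()}


def prob_exceedance(hq_draws, threshold: float = 1.0) -> float:
    """Fraction of draws strictly above ``threshold``."""
    hq = np.asarray(hq_draws, dtype=float)
    if hq.size == 0:
        raise ValidationError("empty draws")
    return float(np.mean(hq > threshold))
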