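"""Monte-Carlo engine: distribution fitting, simulation, percentiles, sensitivity."""

import math

import numpy as np
import pytest

from nitrarisk import (
    DEFAULT_GROUPS,
    DistributionSpec,
    MCConfig,
    Sample,
    ValidationError,
    assess,
    fit_concentration_distribution,
    percentile,
    prob_exceedance,
    sensitivity_ctv,
    simulate_hq,
)

GROUPS = {g.name: g for g in DEFAULT_GROUPS}
Z90 = 1.2815515655446004


def point(v):
    return DistributionSpec("point", (v,))


class TestDistributionSpec:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec("uniform", (3.0, 1.0))
        with pytest.raises(ValidationError):
            DistributionSpec("weibull", (1.0,))
        with pytest.raises(ValidationError):
            DistributionSpec("normal", (0.0, 1.0), truncation=(2.0, 1.0))

    def test_truncation_restricts_support(self):
        spec = DistributionSpec("normal", (0.0, 5.0), truncation=(0.0, 1.0))
        cfg = MCConfig(input_specs={"cf": spec}, n_iterations=500, seed=7)
        r = simulate_hq(GROUPS["adults"], cfg)
        cf_draws = r.hq_draws * GROUPS["adults"].bw * GROUPS["adults"].rfd / GROUPS["adults"].cd
        assert cf_draws.min() >= -1e-12 and cf_draws.max() <= 1.0 + 1e-12


class TestFitting:
    def test_right_skewed_survey_prefers_lognormal(self, survey_samples):
        spec = fit_concentration_distribution(survey_samples, ("lognormal", "normal"))
        assert spec.kind == "lognormal"
        mu, sigma = spec.params
        assert mu == pytest.approx(2.6519, abs=1e-3)
        assert sigma == pytest.approx(0.3436, abs=1e-3)

    def test_constant_data_collapse_to_point(self):
        samples = [Sample(str(i), 7.5) for i in range(10)]
        spec = fit_concentration_distribution(samples)
        assert spec.kind == "point" and spec.params == (7.5,)

    def test_empirical_candidate_identity(self, survey_samples):
        spec = fit_concentration_distribution(survey_samples, ("empirical",))
        assert spec.kind == "empirical"
        assert sorted(spec.params) == sorted(s.cf for s in survey_samples)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            fit_concentration_distribution([Sample("1", 3.0)])


class TestSimulateHq:
    def test_point_mass_collapse_matches_deterministic(self):
        """All-point-mass MC equals the deterministic result exactly."""
        g = GROUPS["children"]
        det = assess([Sample("1", 12.0)], [g])[0]
        cfg = MCConfig(input_specs={"cf": point(12.0)}, n_iterations=1000, seed=0)
        r = simulate_hq(g, cfg)
        assert r.mean == det.hq
        assert r.sd == 0.0
        assert all(v == det.hq for v in r.percentile_table.values())
        assert r.sensitivity == {}

    def test_seed_determinism(self):
        cfg = MCConfig(
            input_specs={"cf": DistributionSpec("lognormal", (2.65, 0.34))},
            n_iterations=2000,
            seed=42,
        )
        a = simulate_hq(GROUPS["teenager"], cfg)
        b = simulate_hq(GROUPS["teenager"], cfg)
        assert np.array_equal(a.hq_draws, b.hq_draws)
        assert a.percentile_table == b.percentile_table

    def test_lognormal_p90_matches_closed_form(self):
        """Simulated P90 lies within 3 MC standard errors of the analytic quantile."""
        mu, sigma = 2.65, 0.34
        g = GROUPS["children"]
        n = 10_000
        cfg = MCConfig(
            input_specs={"cf": DistributionSpec("lognormal", (mu, sigma))},
            n_iterations=n,
            seed=11,
        )
        r = simulate_hq(g, cfg)
        analytic = math.exp(mu + Z90 * sigma) * g.cd / (g.bw * g.rfd)
        # asymptotic SE of the p-quantile: sqrt(p(1-p)/n)/f(q)
        q_cf = math.exp(mu + Z90 * sigma)
        dens = math.exp(-Z90**2 / 2) / (q_cf * sigma * math.sqrt(2 * math.pi))
        se = math.sqrt(0.9 * 0.1 / n) / dens * g.cd / (g.bw * g.rfd)
        assert abs(r.percentile_table[0.90] - analytic) < 3 * se

    def test_convergence_rate_one_over_sqrt_n(self):
        """Mean error shrinks roughly as n^-1/2 from 1e3 to 1e5 iterations."""
        mu, sigma = 2.65, 0.34
        g = GROUPS["adults"]
        analytic = math.exp(mu + sigma**2 / 2) * g.cd / (g.bw * g.rfd)
        errs = {}
        for n in (10**3, 10**5):
            reps = [
                abs(
                    simulate_hq(
                        g,
                        MCConfig(
                            input_specs={"cf": DistributionSpec("lognormal", (mu, sigma))},
                            n_iterations=n,
                            seed=100 + k,
                        ),
                    ).mean
                    - analytic
                )
                for k in range(8)
            ]
            errs[n] = np.mean(reps)
        # 100x more draws should shrink error ~10x; allow generous slack
        assert errs[10**5] < errs[10**3] / 3

    def test_rejection_resampling_counts_negative_draws(self):
        g = GROUPS["adults"]
        cfg = MCConfig(
            input_specs={"cf": DistributionSpec("normal", (1.0, 2.0))},
            n_iterations=2000,
            seed=5,
        )
        r = simulate_hq(g, cfg)
        assert r.n_rejected > 0
        assert r.hq_draws.min() >= 0
        assert r.hq_draws.size == 2000

    def test_hopeless_support_hits_redraw_cap(self):
        g = GROUPS["adults"]
        cfg = MCConfig(
            input_specs={"cf": DistributionSpec("normal", (-100.0, 1.0))},
            n_iterations=200,
            seed=5,
        )
        with pytest.raises(ValidationError, match="redraw cap"):
            simulate_hq(g, cfg)

    def test_single_iteration(self):
        cfg = MCConfig(
            input_specs={"cf": DistributionSpec("uniform", (5.0, 10.0))},
            n_iterations=1,
            seed=3,
        )
        r = simulate_hq(GROUPS["infant"], cfg)
        assert r.sd == 0.0
        assert r.mean == r.hq_draws[0]


class TestPercentile:
    def test_linear_interpolation_rule(self):
        assert percentile(np.arange(1, 101), 0.90) == pytest.approx(90.1)
        assert percentile([0.0, 1.0], 0.5) == pytest.approx(0.5)

    def test_constant_draws(self):
        assert percentile([4.2] * 10, 0.37) == 4.2

    def test_monotone_in_probability(self):
        rng = np.random.default_rng(0)
        draws = rng.lognormal(0, 1, 500)
        ps = np.linspace(0.01, 0.99, 25)
        qs = [percentile(draws, p) for p in ps]
        assert all(a <= b for a, b in zip(qs, qs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            percentile([], 0.5)
        with pytest.raises(ValidationError):
            percentile([1.0], 1.5)


class TestSensitivity:
    def test_single_stochastic_input_takes_all_variance(self):
        g = GROUPS["children"]
        cfg = MCConfig(
            input_specs={"cf": DistributionSpec("lognormal", (2.65, 0.34))},
            n_iterations=4000,
            seed=9,
        )
        r = simulate_hq(g, cfg)
        assert r.sensitivity == {"cf": 1.0}

    def test_two_symmetric_inputs_split_evenly(self):
        """Two multiplicative inputs with equal relative variance each get ~50%."""
        rng = np.random.default_rng(21)
        n = 20_000
        a = rng.lognormal(0.0, 0.3, n)
        b = rng.lognormal(0.0, 0.3, n)
        ctv = sensitivity_ctv({"a": a, "b": b}, a * b)
        assert ctv["a"] == pytest.approx(0.5, abs=0.05)
        assert ctv["b"] == pytest.approx(0.5, abs=0.05)
        assert sum(ctv.values()) == pytest.approx(1.0, abs=0.01)

    def test_constant_output_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity_ctv({"a": np.arange(5.0)}, np.ones(5))


class TestProbExceedance:
    def test_fraction_strictly_above(self):
        assert prob_exceedance([0.5, 1.5]) == 0.5
        assert prob_exceedance([0.1, 0.9]) == 0.0
        assert prob_exceedance([1.0, 2.0]) == 0.5  # threshold itself not counted

    def test_empirical_survey_exceedance_near_one_in_66(self, survey_samples):
        """Resampling the survey, children HQ > 1 for ~1/66 of draws."""
        g = GROUPS["children"]
        spec = DistributionSpec("empirical", tuple(s.cf for s in survey_samples))
        cfg = MCConfig(input_specs={"cf": spec}, n_iterations=20_000, seed=13)
        r = simulate_hq(g, cfg)
        p = 1 / 66
        se = math.sqrt(p * (1 - p) / 20_000)
        assert abs(r.prob_exceedance - p) < 4 * se
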