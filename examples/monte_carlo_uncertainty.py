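"""Probabilistic hazard quotients via Monte-Carlo simulation.

Fits a concentration distribution to the packaged survey, propagates it
through the exposure model for each age group (10,000 draws), and prints
mean, SD, P90, the probability of exceeding HQ = 1, and the
contribution-to-variance sensitivity of each stochastic input.
"""

from nitrarisk import (
    DEFAULT_GROUPS,
    MCConfig,
    fit_concentration_distribution,
    fixture_table2,
    simulate_hq,
)

samples = fixture_table2()
spec = fit_concentration_distribution(samples, ("lognormal", "normal"))
print(f"fitted concentration model: {spec.kind}{tuple(round(p, 4) for p in spec.params)}\n")

print(f"{'group':<10} {'mean':>7} {'sd':>7} {'P90':>7} {'P(HQ>1)':>8}  sensitivity")
for i, g in enumerate(DEFAULT_GROUPS):
    cfg = MCConfig(input_specs={"cf": spec}, n_iterations=10_000, seed=100 + i)
    r = simulate_hq(g, cfg)
    ctv = ", ".join(f"{k}={v:.2f}" for k, v in r.sensitivity.items())
    print(f"{g.name:<10} {r.mean:7.4f} {r.sd:7.4f} {r.percentile_table[0.90]:7.4f} "
          f"{r.prob_exceedance:8.4f}  {ctv}")

# P90 is the hazard quotient not exceeded in 90% of simulated exposure
# scenarios; with only the concentration stochastic, it carries 100% of
# the output variance.
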