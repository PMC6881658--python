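# nitrarisk

Non-carcinogenic health-risk assessment of nitrate in drinking water:
deterministic hazard quotients for age-stratified exposure groups,
Monte-Carlo uncertainty propagation, and inverse-distance-weighted
mapping of well concentrations. Written for environmental-health
analysts who have a table of groundwater nitrate measurements and want
defensible risk numbers, not a GIS suite.

## The model

For a well with nitrate concentration `C_f` (mg/L) and an exposure group
with daily water intake `C_d` (L/day) and body weight `B_w` (kg):

```
EDI = C_f · C_d / B_w          estimated daily intake, mg/kg/day
HQ  = EDI / RfD                hazard quotient, dimensionless
```

`RfD` is the oral reference dose, 1.6 mg/kg/day for nitrate (IRIS).
`HQ > 1` flags intake above the dose considered safe over a lifetime.
Four built-in groups follow common Iranian survey practice: infant
(0.08 L/day, 10 kg), children (0.85, 15), teenager (2, 50), adults
(2.5, 78), all with RfD 1.6.

The Monte-Carlo engine treats any of `C_f`, `C_d`, `B_w` as a
distribution (point mass, normal, lognormal, uniform, triangular, or
empirical resampling), draws independent triples, and summarises the
resulting HQ distribution by mean, SD, percentiles (P90), probability
of exceeding 1, and a contribution-to-variance sensitivity share per
input (normalised squared Spearman rank correlations). The spatial
module interpolates georeferenced wells onto a regular grid with IDW
weights `d^-p` (p = 2 by default) and writes ESRI ASCII rasters plus
guideline-exceedance masks.

The package ships the 66-well rural groundwater survey (nitrate
6–49 mg/L) that its numerical results are validated against, and a
seeded synthetic generator for wells with the same statistical and
spatial structure.

## Worked example

```python
from nitrarisk import DEFAULT_GROUPS, assess, fixture_table2, summarize

results = assess(fixture_table2(), DEFAULT_GROUPS)
for g in DEFAULT_GROUPS:
    s = summarize(results, by=g.name)
    print(g.name, round(s.hq["mean"], 4), round(s.hq["max"], 4))
```

Running `python examples/deterministic_assessment.py` prints:

```
66 wells, nitrate 6.00-49.00 mg/L (mean 15.10, sd 6.15)

group       mean HQ   min HQ   max HQ       sd
infant       0.0755   0.0300   0.2450   0.0307
children     0.5347   0.2125   1.7354   0.2177
teenager     0.3774   0.1500   1.2250   0.1537
adults       0.3024   0.1202   0.9816   0.1232

wells above the HQ = 1 safety threshold:
  well 35 (children): HQ = 1.7354
  well 35 (teenager): HQ = 1.2250
```

Mean HQ ranks children > teenager > adults > infant; only the single
49 mg/L well pushes children and teenagers past the acceptable limit.
The other scripts in `examples/` demonstrate the Monte-Carlo engine,
IDW mapping, and the synthetic generator the same way.

A thin CLI wraps the same functions:

```
nitrarisk fixture -o wells.csv
nitrarisk assess wells.csv -o risk.csv --summary summary.csv
nitrarisk mc wells.csv -o mc.csv --iterations 10000 --seed 1
nitrarisk map wells.csv -o nitrate.asc --cell-size 0.01 --guideline 50
nitrarisk report wells.csv -o report/ --seed 1
```

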