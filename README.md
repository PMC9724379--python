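# qalytree

Decision-tree cost-utility analysis in Python: deterministic expected-value
rollback, ICER / net-monetary-benefit comparison with dominance handling,
one-way deterministic sensitivity analysis (tornado ordering), and
second-order Monte Carlo probabilistic sensitivity analysis (PSA) with
cost-effectiveness-plane and acceptability-curve (CEAC) summaries.

A complete worked model ships with the package: OM-85 BV (a bacterial-lysate
immunostimulant) versus placebo for pediatric recurrent respiratory tract
infections, evaluated over a six-month horizon at a willingness-to-pay of
US$5180 per QALY (`src/qalytree/data/om85.json`).

## Design notes

- **QALY scale.** QALYs are reported as expected health-state utility over
  the model horizon; they are **not** multiplied by the horizon length in
  years. The death state carries utility 0.
- **Distributions.** Uncertain inputs are specified as (mean, SD) pairs and
  parameterized by the method of moments: beta for probabilities and
  utilities, gamma for costs, lognormal for the treatment-effect reduction.
  Draws of probability-like quantities are clamped to [0, 1] with a counted
  warning.
- **PSA.** Each replication samples every non-fixed parameter once and
  evaluates both strategies on the shared binding (common parameters are
  correlated across arms). One master seed is split into independent
  per-parameter substreams, so runs are bitwise reproducible.
- **Tornado.** The outcome metric is the incremental net monetary benefit
  at the configured threshold; the default variation is ±25% of the base
  value, except lognormal effect parameters, which use the central 95%
  interval of their fitted distribution. Explicit `dsa_low`/`dsa_high`
  bounds override both.
- **Dominance.** ICER values are withheld when the incremental cost and
  QALY deltas have opposing signs (or the QALY delta is zero); strict
  inequalities define dominance.

## Command line

```sh
qalytree validate src/qalytree/data/om85.json
qalytree base-case src/qalytree/data/om85.json
qalytree dsa src/qalytree/data/om85.json -o out/
qalytree psa src/qalytree/data/om85.json --n 10000 --seed 42 -o out/
qalytree ceac src/qalytree/data/om85.json --n 10000 --seed 42 -o out/
qalytree reproduce -o om85_report --seed 0 --n 10000   # full bundled study
qalytree simulate-cohort -o cohort.csv --n-per-arm 10000 --seed 0
```

`reproduce` writes `base_case.csv`, `tornado.csv`, `psa_draws.csv`,
`ceac.csv`, `psa_summary.json` and `metadata.json` (config hash, seed,
replication count, versions); add `--plots` for PNG figures. All outputs
are a pure function of (configuration, seed).

## Library use

```python
from qalytree import om85
from qalytree.sensitivity import run_psa, quadrant_summary, ceac

model = om85.build_om85_model()
print(model.base_case())            # dominant: lower cost, higher QALYs
psa = run_psa(model, n=10_000, seed=42)
print(quadrant_summary(psa))
print(ceac(psa, [0.0, 5180.0]))
```

Custom models are JSON configurations with a strict schema: a parameter
table, a tree (`decision` / `chance` / `terminal` nodes whose probabilities
and payoffs may be arithmetic expressions over parameter names), the two
compared strategies and analysis settings. See the bundled `om85.json`.

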