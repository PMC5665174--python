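# dentaccess

Capacitated optimization model of children's spatial access to
preventive dental care.

Low-income children are far more likely to carry untreated tooth decay
than high-income children, and a major barrier is finding a dentist who
accepts public insurance (Medicaid/CHIP). `dentaccess` is a
census-tract-level pipeline for quantifying that access gap and for
evaluating policies meant to close it. It is written for health-services
and oral-health researchers and state program analysts who want a
reproducible, data-free-to-test implementation of the approach: a
synthetic state generator stands in for the census, licensure,
directory, and claims inputs, which are not redistributable.

## The model

Children are split by family income into a publicly insured group
(≤ 247% of the federal poverty level) and a privately insured group
(> 400% FPL); the band in between is excluded. Tract need (annual
provider-hours) is assigned to dentists by a two-stage linear program
over flows x(d, p) ≥ 0 from demand cells d (tract × group × vehicle
class) to provider sites p:

1. maximize Σ x(d, p) — serve as much need as possible, subject to
   * supply: assigned hours ≤ the provider's pool for the group, where
     the public pool is capacity × caseload at accepting providers and
     the private pool is the complementary capacity × (1 − caseload);
   * travel: x(d, p) > 0 only if the distance from d's tract to p is
     within the state standard (30 mi urban / 45 mi rural with a
     vehicle; 8 / 15 mi without);
2. fix the served total and minimize Σ x(d, p)·miles(d, p).

From the solved assignment the pipeline computes three access measures
per tract and group — percent met need, mean 1-way travel distance, and
provider scarcity (assigned/pool hours over reachable providers) — plus
served/underserved/unserved classes (met need ≥ 90% / 50–90% / < 50%).
A microsimulation (65 replicates by default) propagates uncertainty in
caseload fractions and the high-risk share of children; Holm-corrected
one-sided t-tests flag tracts whose public–private gap exceeds
disparity thresholds (2/6/8/10 mi travel; 0/0.1/0.2/0.3 scarcity) at
α = .05. Policy sweeps trace median access over acceptance rates
(20–80%), caseload levels (20–75%), and travel standards (30–60 mi).
See `docs/methods.md` for assumptions and design choices.

## Worked example

```python
from dentaccess import PreventiveDentalAccessModel, SyntheticConfig

model = PreventiveDentalAccessModel.from_synthetic(
    SyntheticConfig.test_profile(seed=1))   # ~200 tracts, ~150 dentists
print(model.fit().summary())
```

```
Preventive Dental Care Access — assignment results
==========================================================
Tracts: 200 (155 urban, 45 rural)   Providers: 139 (51 accepting public insurance)
Solver status: optimal   total child-miles: 139,693

group        children      served  met need  mean travel  scarcity
public         52,388      13,581     25.9%        3.7mi      1.00
private        20,312      18,617     91.7%        4.8mi      0.35
```

Reading the numbers: only 25.9% of public-insurance-eligible children
can be served within the travel standards — the accepting minority of
dentists (51 of 139) caps the public capacity pool — while 91.7% of
privately insured children are served. Public scarcity of 1.00 says
every reachable public pool is saturated; private scarcity of 0.35 says
private-side capacity is ample. The served public children travel a
short mean distance (3.7 mi) because the distance-minimizing stage
serves the closest need first. The microsimulation view adds
uncertainty bands:

```python
sim = model.simulate(n_replicates=8, seed=1)
print(sim.summary())                     # means with 10th–90th percentiles
flags = sim.flag_disparities("travel")   # Holm-corrected tract flags
curve = model.sweep_acceptance([0.2, 0.5, 0.8], n_per_rate=4, seed=1)
```

The same stages are scriptable from a shell:

```sh
access-opt generate --seed 1 --out runs/state
access-opt solve --instance runs/state --out runs/solve
access-opt simulate --instance runs/state --out runs/sim -n 65 --seed 1
access-opt sweep --instance runs/state --out runs/sweep --param acceptance
access-opt report --run runs/sim --style table2
```

`access-opt generate --full-scale` produces the 1,969-tract,
~4,100-provider default state (minutes per replicate on one CPU).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the pipeline from scratch — synthetic state, nominal assignment
with conservation checks, an 8-replicate microsimulation with disparity
inference on both measures, and an acceptance-rate sweep — and writes
the results JSON to `--out`. All randomness derives from `--seed`.
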