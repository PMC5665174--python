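# Methods

`dentaccess` estimates local access to preventive dental care for
children by solving a capacitated, distance-minimizing assignment of
need to provider capacity under state travel standards, and compares two
insurance groups: children income-eligible for public insurance
(Medicaid/CHIP, family income ≤ 247% of the federal poverty level) and
children assumed privately insured or able to pay (> 400% FPL). Children
in the 247–400% band are excluded from the assignment entirely: they are
assumed to have neither public eligibility nor reliable means to pay.

## Demand

Need is denominated in annual provider-hours. A `NeedModel` carries a
small table of (age band × caries-risk class) cells with hours per child
per year; the expected hours per child are the mixture over fixed age
weights and a statewide high-risk fraction. Defaults are two age bands
(0–5 at 32% weight, 6–18 at 68%) with 0.9/1.8 h (low/high risk) for the
younger band and 0.7/1.5 h for the older — in the range implied by
twice-yearly preventive visits with additional contact time for
high-risk children. These are configuration, not constants: the
published estimation methodology they stand in for is external to this
package and its tables are not distributed.

Each tract yields four demand cells: 2 insurance groups × 2 mobility
classes, with children split by the tract's vehicle-ownership fraction.
Whether the high-risk proportion varies by tract is not identifiable
from the source material; it is implemented as a statewide scalar
re-sampled per microsimulation replicate (range 0.20–0.40 by default).

## Supply

A provider site is one dentist at a geocoded office. Capacity is annual
chair time × a preventive share × a pediatric share
(`provider_capacity`), with a mean-1 lognormal multiplier (CV 0.2)
providing heterogeneity so scarcity is non-degenerate. Public-insurance
acceptance comes either from the synthetic generator (i.i.d. at the
configured rate, default 27.9%) or from record linkage between a
licensure roster and a public-insurance directory: normalized token-set
similarity (lowercasing, punctuation stripping, credential-suffix
removal; default threshold 0.90, configurable and calibration-sensitive)
with greedy one-to-one matching, deterministic tie-breaks, and
propagation of a match to every dentist sharing the matched office.
Accepting dentists draw a public caseload fraction uniformly from
rurality-specific ranges: 35–50% urban, 55–65% rural.

## Distances and standards

Distances are great-circle statute miles (Earth radius 3958.8 mi)
between tract centroids and provider addresses. This understates road
miles; a long-format external distance table (e.g. street-network
distances) can be supplied and is passed through untouched. Travel
standards attach to the tract of residence and are boundary-inclusive:
30 mi urban / 45 mi rural with a vehicle, 8 mi urban / 15 mi rural
without. Only the distance arm of "miles or minutes" standards is
implemented — travel times would require road-network routing, which is
out of scope.

## Assignment model

Within each insurance group, flows of children from demand cells to
providers solve a two-stage lexicographic LP over the feasible
(within-standard) pairs: stage 1 maximizes served children; stage 2 pins
the served total (equality, with a 1e-7 relative fallback) and minimizes
total child-miles. A pure distance minimizer would trivially serve no
one; the two-stage reading is what lets "patients prefer nearer
providers" coexist with reported unmet need. Flows are continuous;
populations are large and the transportation structure is integral
whenever inputs are, so fractional children are a numerical convenience,
not a modelling claim. The LP is assembled sparsely over mask-true pairs
(scipy sparse + HiGHS); dense formulation would be millions of variables
at state scale.

The two groups are assigned separately on **disjoint capacity pools**
defined by the caseload split: the public pool is capacity × caseload at
accepting providers, the private pool the complementary capacity ×
(1 − caseload). Two properties drove this choice over the main
alternative (private assignment first, public on the residual):

* the private solution is exactly invariant to the acceptance mask — the
  central policy lever — because the private pool depends on the
  caseload fraction only, never on the acceptance flag;
* each group's pools are fixed inputs to its own program, so raising a
  caseload, an acceptance rate, or a travel standard can only grow that
  group's served total. Under a residual design, widening travel
  standards lets the private program absorb capacity and can *reduce*
  public access, breaking the monotone policy curves the model is meant
  to produce.

The cost is that the caseload share of a non-saturated accepting
provider is reserved for public patients even when idle. Whether the
source model solved one joint program or two is not stated; the
disjoint-pool reading is implemented and the joint alternative noted
here. Ties among equidistant providers are left to the solver; only
objective values are contractual.

A brute-force enumeration oracle (integer flows, depth-first with
memoization on the used-capacity vector) provides an independent
reference on tiny instances (≤ 6 demands, ≤ 4 providers, ≤ 12 children
per demand); the LP must match its served totals exactly and its
distance objective to 1e-6 on instances with integral pools.

## Access measures

Per tract and group:

* **met need** — served children / children; defined as 1.0 for a group
  with no children (no unmet need exists; the alternative, a missing
  value, is noted in the output schema).
* **travel distance** — flow-weighted mean 1-way miles over served
  children. When nobody in the cell is served, the value is censored at
  the tract's with-vehicle standard (30/45 mi) and flagged, so ensemble
  means stay finite; the uncensored convention is recoverable from the
  flag column.
* **scarcity** — assigned hours / pool hours aggregated over the
  providers reachable within the with-vehicle standard, using the
  group-relevant pool (public pool for the public group). This
  capacity-weighted aggregation reduces to the per-dentist definition
  for a single provider; an empty or zero-hour reachable pool counts as
  fully scarce (1.0).

Service levels follow the met-need cut points: served ≥ 90%,
underserved 50–90%, unserved < 50%. (The alternative prose definition
involving unaffordability of care for uninsured children is not
formalizable from the source text and is out of scope.)

## Uncertainty and disparity inference

The microsimulation (65 replicates by default) re-draws every provider's
caseload fraction and the statewide high-risk fraction, rebuilds demand,
re-solves, and stacks access reports. Replicate streams are derived from
(master seed, replicate index) only, so draws are coupled across policy
levels: moving a lever, not re-rolling luck, changes a curve. Caseloads
are drawn for *all* providers so the same draws apply under any
acceptance mask a sweep imposes.

Disparity flagging tests, per tract, H0: mean |public − private| ≤ τ
against one-sided exceedance using the across-replicate one-sample t
statistic (a zero-variance gap is strict exceedance), with Holm
correction across tracts per (measure, τ) family at α = 0.05. Default
thresholds: 2/6/8/10 miles for travel, 0/0.1/0.2/0.3 for scarcity. The
original simultaneous-inference procedure is not specified in the
source; Holm-corrected t-tests are the implemented stand-in and control
the familywise error under the stated normal-theory conditions — the
calibration test verifies empirical FWER ≤ 0.05 + 3 SE on boundary-null
ensembles. Percentile summaries use linear interpolation.

## Policy sweeps

* **acceptance rate** (20–80%): accepting sets are *nested* — providers
  are put in one seeded random order per rurality class and rate r
  accepts the first ⌈r·n⌉ — so public pools grow monotonically with the
  rate and curves are comparable across rates. The resampling scheme of
  the original analysis is unstated; nesting is this package's choice.
  The accepting set is fixed per level, with caseloads re-drawn per
  replicate.
* **caseload** (20–75%): the caseload fraction of the accepting set is
  pinned at each level.
* **maximum travel distance** (30–60 mi): both rurality classes'
  with-vehicle standards are overridden; no-vehicle standards are kept
  (clipped if the vehicle standard drops below them).

Sweeps report medians by region × group pooled over tracts and
replicates and persist the full distributions. The observed ~28%
participation rate is a plotting annotation, not a computation.

## Synthetic state

The generator emulates a Georgia-like state: 1,969 tracts (1,527 urban)
by default, ~1,320 children per tract (lognormal, CV 0.45), an income
split of 58% public-eligible / 19% excluded / 23% private (matching the
published ~1.5M and ~0.6M of ~2.6M children), urban tracts clustered
around 8 synthetic city centers and rural tracts dispersed, counties
synthesized only to drive the < 35,000-population rurality rule, vehicle
ownership ~93% urban / 88% rural, provider densities of 17.5 (urban) and
9.0 (rural) per 10,000 children giving ~4,100 dentists, offices of 1–8
dentists (truncated geometric, mean ~2), acceptance 27.9%, and the
caseload ranges above. Values the source states are taken as stated;
the remainder (vehicle ownership, densities, capacity parameters, need
hours, dispersion) are fixed once at levels a health-services researcher
would call plausible and are not tuned to any output.

What a green run does **not** establish: the synthetic state has no
fidelity to actual geography, road networks, ACS margins of error, or
claims-based caseload distributions, and its absolute access levels are
not calibrated to the published Georgia estimates (which require
undistributed census, licensure, directory, and claims data). Tests
therefore assert structural properties (conservation, oracle
equivalence, monotonicity, calibration of the inference) and the
*direction* of the published findings — public < private met need,
rural public < urban public, public travel > private travel — never
their magnitudes.

## Numerical choices

* LP backend HiGHS via `scipy.optimize.linprog`; flows below 1e-9
  children are zeroed; served is clipped to demand to absorb round-off.
* Stage-2 pin: equality at the stage-1 optimum, falling back to an
  inequality at 1e-7 relative slack if the equality is reported
  infeasible.
* Met need and scarcity are clipped to [0, 1] (1e-9 numerical guard).
* Solver failure in a replicate marks it failed and is reported via
  ensemble completeness — never silently zeroed.
* Oracle comparisons require integral pools; the generator of oracle
  instances constructs capacity = public pool + private pool from
  integers so the split is exact in floating point.

## Scaling of shipped checks

The test suite runs the sweep-monotonicity checks on a ~200-tract / ~150
provider profile (8 replicates per level) and the directional check on a
~590-tract reduction of the default state (2 replicates); the full
1,969-tract state (~4,100 providers) runs in minutes per replicate on one
CPU via `access-opt generate --full-scale` + `simulate` but exceeds the
suite's time budget.

## Known limitations

* Haversine distances understate road miles, more so in rural areas;
  the external-table escape hatch exists for users with network
  distances. Travel-time standards are unimplemented.
* One business address per dentist; no multi-office practices.
* The caseload share of an accepting provider is unavailable to private
  patients even when idle (disjoint pools).
* Record-linkage quality is threshold-sensitive and unvalidated against
  any labelled match set.
* The 247–400% FPL group is excluded by construction; measures for the
  combined population ("all") cover the two modelled groups only.
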