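# Methods

`audcea` implements a two-part Markov cohort model for the cost-utility
comparison of two psychological treatments for alcohol use disorder (AUD)
with controlled-drinking goals: Behavioral Self-Control Training (BSCT,
the intervention) versus Motivational Enhancement Therapy (MET, the
comparator). This note records the model, its assumptions, the defaults,
and the design choices made where the design was genuinely open.

## Model structure

The state space has 22 states:

* four **drinking-risk-level (DRL)** states — low, medium, high, very
  high — the WHO categories of mean daily pure-alcohol intake, with
  sex-specific gram bands;
* five **permanent complication states** (ischemic heart disease,
  ischemic stroke, hemorrhagic stroke, liver cirrhosis, chronic
  pancreatitis): absorbing except for death, entered from a DRL state on
  a non-fatal chronic event;
* twelve **tunnel states** — three temporary events (lower respiratory
  infections, transport injuries, other injuries) × four origin DRLs —
  occupied for exactly one cycle, after which survivors return to the
  origin DRL;
* one absorbing **death** state.

Time runs in two phases over a 5-year horizon: one year of quarterly
cycles driven by the trial-estimated DRL transition matrices (three
follow-up intervals: baseline–12, 12–26, 26–52 weeks), then four annual
cycles in which a literature-informed relapse probability (14%/year,
applied as low→medium and medium→high one-step worsening) and the
alcohol-attributable event risks act. The trial has three intervals but
the first year has four quarters; the 26–52-week matrix spans two
quarters and is converted to a one-quarter step by halving each row's
off-diagonal exit probability on the constant-hazard scale
(q = 1 − (1 − p)^0.5) and re-spreading it proportionally. Supplying four
quarterly matrices directly overrides this.

Complication risks act only in the medium-term phase; the first year
carries DRL movement plus background mortality only (a configuration
flag can enable year-1 events for exploration). Competing risks within a
cycle resolve in a fixed order — death (all-cause plus fatal events),
non-fatal event exits, then DRL movement over the event-free remainder —
which guarantees row-stochastic matrices by construction. Improvement
transitions (e.g. medium→low) in the medium-term phase default to zero;
only the worsening rule is active.

Each arm is simulated separately for male and female strata (baseline
DRL occupancy, risks, mortality and utilities are all sex-specific) and
aggregated with the arm's trial sex mix (BSCT 42% female, MET 54%).
Age advances deterministically from the arm's baseline mean (52.2 /
51.4 years); mortality is looked up at floor(age). No half-cycle
correction is applied; occupancy is valued at cycle ends.

## Risks

Per-person event risk is `population incidence × relative risk`, with
chronic events keyed by the three-tier medium-term category (very high
collapses onto high, the only order-preserving surjection) and acute
events by the four-tier DRL. Register-style rates are converted to
per-cycle probabilities by `1 − exp(−rate·t)`; inputs flagged as
probabilities instead rescale by `1 − (1 − p)^t`. A case-fatality
fraction splits each event probability into fatal and non-fatal parts,
so event incidence enters once and cannot double-count between morbidity
and mortality inputs. All-cause mortality applies in every living state,
including tunnels and permanent states (flag to disable).

## Economics

QALYs accrue as cycle-end occupancy × state utility × cycle length,
discounted at the cycle end by `(1+r)^(−t)` with r = 3% (0% and 5% as
scenarios). Short-term cycles use the trial utility block matched to the
measurement occasion (cycle 1: 12-week values; cycle 2: 26-week; cycles
3–4: 52-week); all medium-term cycles carry the 52-week block forward.
Complication states use literature utilities. The trial recorded no
very-high-risk utilities for men (and none for either sex at 52 weeks);
those cells inherit the high-risk value of the matching sex/timepoint,
with a logged warning — the nearest ordered category, overridable by
editing the utility table.

Intervention costs are charged in full at model start (treatment spans
the first 12 weeks) and are not discounted. The supervision/coding
component is kept separable so the "no supervision costs" scenario
removes exactly it; the shipped split (BSCT \$1.78, MET \$1.68 of the
\$1,447.79 / \$1,511.37 totals) is this package's decomposition of the
published totals, sized from the published scenario deltas. Complication
costs — direct medical and productivity, in 2024 USD — are charged once
on entry into the event state (per-episode costing; a `per_cycle` option
exists for chronic states). Healthcare perspective = intervention +
direct medical; limited societal adds productivity losses. Incremental
results report Δcost/ΔQALY as an ICER unless the sign pattern implies
dominance, which is flagged rather than reported numerically.

## Uncertainty

The probabilistic sensitivity analysis draws every uncertain parameter
independently per iteration — Beta for utilities (method of moments from
mean + SE), Gamma for costs published with an SD, Triangular for costs
published as mode + [min, max] — and evaluates *both arms on the same
draw*, so incremental uncertainty reflects paired differences. 1000
iterations by default; 95% uncertainty intervals are 2.5th/97.5th
percentiles (numpy linear interpolation). Iteration i uses an
independent substream spawned from the run seed, making results
order-independent and bit-reproducible. One published cirrhosis cost
row prints a mode marginally above its own range maximum; the mode is
clamped into the range with a logged warning rather than rejected.
Items without published uncertainty are held fixed. Short-term
transition matrices are held fixed in the PSA by default (no published
sampling scheme); transition counts are exported by the estimator for an
optional Dirichlet treatment.

## Synthetic data

The individual-level trial data and the register-derived appendix tables
are not publicly deposited, so the package ships clearly labelled
synthetic stand-ins (files prefixed `synthetic_`) and a generator that
emulates the trial's statistical structure: 125 participants/arm, sex
mix and age per arm, baseline weekly consumption ~ Normal(23.65, 12.44)
and (24.34, 12.75) standard drinks truncated at zero (12 g/drink), DRL
trajectories sampled from known per-arm transition matrices, consumption
decorated uniformly within the occupied gram band (shifted exponential,
scale 15 g/day, in the unbounded top band), utilities anchored at the
published DRL × sex × timepoint means with Normal noise (SD 0.05,
truncated at 1), and missing-at-random dropout at the published rates
(15/16.7%, 30/27.8%, 40/38.9% per follow-up), tilted by baseline DRL
(slope 0.05/step, mean-centred so the marginal rate is preserved) to
make imputation informative. The default ground-truth matrices encode a
modest BSCT advantage in moving occupancy toward lower DRLs; magnitudes
were chosen once as plausible for a controlled-drinking trial.

Estimators recover the model's trial-derived inputs: interval transition
matrices by observed-pair counting (identity fallback with a warning for
never-observed rows), baseline DRL occupancy by classification, and the
utility table by cell means pooled over imputed datasets. The imputation
is a deliberately simplified chained-equations scheme — linear
regressions of each missing follow-up variable on arm, sex, age,
baseline consumption/utility and the other follow-ups, predictive draws
with residual noise, 10 fixed sweeps, m = 5 sets — standing in for the
trial's MICE, whose exact specification is not published.

What the synthetic fixtures do **not** emulate: real register incidence
levels, true relative-risk profiles, Swedish life-table mortality, or
the trial's actual effect sizes. Passing tests therefore demonstrate the
*correctness of the machinery* (classification, matrix construction,
accounting, estimation, uncertainty propagation) and internal
consistency — not the published point estimates, which depend on
non-public inputs.

## Numerical choices

* Tier bounds are half-open: the printed integer anchors are upper
  bounds of their tier ([0,20], (20,40], … for women), so every
  non-negative consumption maps to exactly one tier.
* Row sums are validated to 1e−10 (transition matrices) and occupancy
  conservation to 1e−9 per cycle; violations raise naming the row.
* Beta/Gamma shapes below an SE of 1e−12 degenerate to point masses.
* All outputs are plain delimited text at six significant digits;
  every results directory carries a manifest (seed, config hash, input
  checksums, package version).

## Validation problem sizes

The test suite validates the cohort engine against an independent
100,000-person microsimulation stepping through the same matrices
(occupancies within 3 Monte-Carlo SEs, undiscounted costs and QALYs
within 1%), checks distribution moment recovery at 10^6 draws, runs
parameter recovery on a 2,000-per-arm noise-free synthetic trial (1%
agreement on base-case outputs), and exercises the full 1000-iteration
PSA for bit-reproducibility under a fixed seed.

## Known limitations

* The shipped risk, mortality, transition and baseline tables are
  synthetic; absolute cost/QALY levels are illustrative.
* No correlation structure between sampled parameters; no Dirichlet
  sampling of transition rows by default; no value-of-information
  analysis.
* The cohort carries no age distribution and no individual heterogeneity
  beyond the two sex strata.
* Tunnel exits return to the origin DRL — a memory-preserving
  convention; the alternative (re-entry at a fixed DRL) is not modelled.
* The 5-year horizon omits longer-run sequelae; costs and utilities
  beyond 52 weeks extrapolate the last trial measurement.
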