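# audcea

A Markov cost-utility model for psychological treatments of alcohol use
disorder (AUD) with controlled-drinking goals, comparing **Behavioral
Self-Control Training (BSCT)** against **Motivational Enhancement
Therapy (MET)** from healthcare and limited societal perspectives.

It is written for health economists and trial analysts who need a
tested, scriptable implementation of this class of decision model:
WHO drinking-risk-level (DRL) classification of consumption data,
alcohol-attributable event risks, a two-phase cohort simulation with
tunnel and absorbing complication states, discounted cost/QALY
accounting, paired probabilistic sensitivity analysis (PSA), and
univariate scenario analysis — plus a synthetic trial generator and
estimators for the model's trial-derived inputs, since the original
individual-level data are not publicly deposited.

## The model

Individuals occupy one of 22 states: four DRL states (low/medium/high/
very high, sex-specific gram-per-day bands), five permanent complication
states, twelve one-cycle tunnel states (3 temporary events × 4 origin
DRLs), and death. Time runs as one year of quarterly cycles driven by
trial-estimated DRL transitions, then four annual cycles with a 14%
annual one-step worsening ("relapse") probability and event risks

    personal risk(i, x) = population risk(i) × relative risk(i, x),

converted to per-cycle probabilities by 1 − exp(−rate·t) and split into
fatal/non-fatal parts by a case-fatality fraction. Costs (2024 USD) and
utilities attach to the resulting occupancy trace; future amounts are
discounted at rate r by (1 + r)^(−t) with r = 3% in the base case. The
incremental comparison reports Δcost/ΔQALY as an ICER, or a dominance
flag when one arm is both cheaper and more effective. The PSA draws
Beta/Gamma/Triangular parameters and evaluates both arms on common
draws, yielding paired 95% uncertainty intervals, the cost-effectiveness
plane, and the acceptability curve CEAC(λ) = Pr(λ·ΔQALY − Δcost > 0).

See `docs/methods.md` for assumptions, defaults and limitations. The
shipped risk/mortality/transition tables are clearly-labelled synthetic
stand-ins (`src/audcea/data/synthetic_*.csv`); published cost, utility
and threshold tables are shipped as-is.

## Worked example

```sh
audcea run --out-dir results/
```

prints the deterministic base case on the default (synthetic) inputs:

```
        row  intervention_cost  direct_medical_cost  productivity_cost  total_healthcare_cost  total_societal_cost    qalys icer_healthcare icer_societal
       BSCT            1447.79           611.121698        1179.010075            2058.911698          3237.921774 3.914724
        MET            1511.37           617.527733        1194.092750            2128.897733          3322.990483 3.913407
incremental             -63.58            -6.406035         -15.082674             -69.986035           -85.068709 0.001317        dominant      dominant
```

Reading the incremental row: BSCT costs \$63.58 less to deliver per
enrollee, saves a further \$6.41 in complication healthcare costs and
\$15.08 in productivity losses (so \$69.99 and \$85.07 per person from
the healthcare and societal perspectives), and yields 0.0013 more QALYs
over five years — cheaper *and* more effective, hence "dominant" and no
numeric ICER.

The same library surface is available in Python:

```python
import audcea

params, config = audcea.load_default_parameters()
res = audcea.run_base_case(params, config)
print(res["incremental"].icer_societal)   # 'dominant'

draws = audcea.run_psa(params, config, seed=7)          # 1000 paired iterations
plane, ceac = audcea.ce_plane_and_ceac(draws, range(0, 100001, 5000))
```

Other subcommands: `audcea generate-data` (synthetic trial records),
`audcea estimate` (transition matrices, baseline occupancy and utilities
from records, with multiple imputation), `audcea psa` (CE plane, CEAC,
uncertainty intervals), `audcea sensitivity` (discount 0%/5%, 19%
relapse, supervision-cost removal, alternative utility set). Every
output directory includes a `manifest.json` with the seed, config hash
and input checksums.

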