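# healthexpect

Multistate healthy life expectancy from interval-censored health panels.

Population health studies of older adults ask not just how long people live
but how much of that remaining life is spent in good health.  Cohort panels
such as the Chinese Longitudinal Healthy Longevity Survey interview people
every few years, record a binary health state (ADL independence, or
self-rated health), a time-varying exposure such as loneliness, and exact
death dates reported by informants — leaving the health trajectory between
interviews unobserved.  `healthexpect` is for biostatisticians and
demographers who want to turn such panels into age-specific life expectancy
(LE), healthy life expectancy (HLE) and the HLE/LE share, by group.

## Model

States are healthy (1), unhealthy (2) and dead (3, absorbing), with both
transitions between the living states allowed.  Between interviews the
process is an embedded Markov chain on a fine step *h* (an interpolated
Markov chain, in the multistate life-table sense), with per-step multinomial
logits in age and covariates:

    ₕp_x^{jk} = exp(η_jk) / (1 + Σ_{k'≠j} exp(η_jk')),   η_jk = a_jk + b_jk(x−80) + c_jk′z

Interval probabilities ₜp_x^{jk} are ordered products of one-step matrices;
an episode ending in death at a known age contributes survival in the living
states up to the death step and the transition to death within it.  The
weighted pseudo-likelihood is maximized by L-BFGS with an exact gradient.
From the fit, the package computes the stable (period) prevalence
w²(x), conditional expectancies

    e_x^{ij} = h/2·δ_ij + h·Σ_{u≥1} ᵤp_x^{ij}

population-based e_x^{·j} = (1−w²)e^{1j} + w²e^{2j}, LE = e^{·1} + e^{·2},
HLE/LE in percent, and parametric-bootstrap confidence intervals.  A
synthetic cohort generator with a known ground-truth model makes every stage
testable without restricted survey data, and the reporting layer computes
the derived comparison statistics — gender difference (GD, men − women) and
age decrement (AD, value at 65 minus value at 99) — used in published
multistate HLE tables.

## Worked example

```python
from healthexpect import (
    MultistateLogitModel, SimulationConfig, generate_cohort,
    build_histories, recode_cohort, population_expectancies,
)
from healthexpect.coding import CodingRules
from healthexpect.simulate import recovery_true_model

truth_model = recovery_true_model(0.25)          # quarter-year step
cohort, truth = generate_cohort(SimulationConfig(n=4000, seed=1,
                                                 true_model=truth_model))
rules = CodingRules(indicator="adl")
_, episodes = build_histories(recode_cohort(cohort, rules))
model = MultistateLogitModel(h=0.25, covariates=("lonely",)).fit(episodes)
for lonely in (0, 1):
    r = population_expectancies(model.coefficients_, 65.0, {"lonely": lonely})
    print(f"lonely={lonely}  LE={r.le:.2f}  HLE={r.hle:.2f}  HLE/LE={r.hle_pct:.1f}%")
```

prints (seed 1):

```
lonely=0  LE=18.11  HLE=16.34  HLE/LE=90.2%
lonely=1  LE=16.51  HLE=14.55  HLE/LE=88.1%
```

The generator plants a harmful loneliness effect on the death and morbidity
logits, and the fitted pipeline recovers the expected pattern: lonely
individuals at 65 lose ~1.6 years of life expectancy and ~1.8 years of
healthy life expectancy relative to the non-lonely, with a slightly lower
healthy share of remaining life.

There is also a CLI for the end-to-end pipeline:

```sh
healthexpect all --seed 1 --outdir out          # simulate, code, fit, report
healthexpect simulate --n 2000 --seed 1 --outdir out
healthexpect fit --cohort out/cohort.csv --indicator adl --outdir out
```

which writes cohort/episode CSVs, the fitted model (JSON), one-year
transition tables with bootstrap SEs, LE/HLE/HLE-ratio tables with 95% CIs,
gender-specific HLE/LE schedules with GD/AD columns, weighted baseline
descriptives, figures, and a run log.

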