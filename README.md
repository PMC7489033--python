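# demcost

A discrete-time Markov chain (DTMC) cost-of-illness model for outpatient
dementia care, built for health economists and care planners who need
stage-specific cost projections for home-dwelling dementia cohorts.

Clients of outpatient dementia services are staged on the Global
Deterioration Scale (GDS, 1–7) and collapsed into three severity states:
mild (GDS 3–4), moderate (GDS 5), severe (GDS 6–7). Annual severity
transitions follow a time-homogeneous chain

    Pr(X_{t+1} = s_j | X_t = s_i) = p_ij,

whose 3×3 matrix **P** is estimated by maximum likelihood from paired
baseline/one-year observations, `p̂_ij = n_ij / n_i`, with per-cell 95%
confidence bounds (Wald by default, Clopper–Pearson optionally). Each state
carries an annual per-person cost of treatment, long-term care benefit, and
indirect cost (informal-care hours × hourly wage, net of the benefit);
cohort occupancy is propagated with `x_{t+1} = x_t P` and converted into
yearly, per-state, and total cost, with optional discounting or compound
cost growth at rate r. A one-way ±50% sensitivity analysis ranks the cost
components in a tornado table. Because the underlying clinical registry is
not public, a synthetic registry generator reproduces its statistical
structure (baseline mix, transition law, dropout, a weak
severity–care-benefit rank correlation), so the whole pipeline is testable
end to end.

## Worked example

```python
import numpy as np
from demcost import *

# 1. synthesize a registry and select the paired analysis sample
records = generate_cohort(GeneratorConfig(seed=1))
pairs, report = select_analysis_sample(records)
print(report)

# 2. estimate the annual transition matrix
model = fit_transition_model(pairs)
print(np.round(model.point, 3))

# 3. cost schedule and ten-year projection for the 784/413/144 cohort
schedule = build_cost_schedule(CostParameters())
trajectory = simulate_cohort(model.point, schedule, SimulationConfig())
print(f"year-1 total: {trajectory.total_cost[0]:,.2f} EUR")
print(f"mild/severe share, year 1: {trajectory.share[0,0]:.1%} / {trajectory.share[0,2]:.1%}")

# 4. tornado of the first-year total cost
print(tornado_table(one_way_sensitivity(schedule, (784, 413, 144))))
```

prints

```
SelectionReport(n_input=4817, n_excluded_no_followup=3515, n_excluded_predementia=0,
                n_excluded_followup_remission=0, n_analysis=1302)
[[0.813 0.152 0.035]
 [0.069 0.652 0.279]
 [0.007 0.036 0.957]]
year-1 total: 67,294,910.94 EUR
mild/severe share, year 1: 50.6% / 15.7%
          parameter          low         high        range  rank
0   indirect_annual  42238880.34  92350941.54  50112061.20     1
1    benefit_annual  61072858.74  73516963.14  12444104.40     2
2  treatment_annual  64925538.27  69664283.61   4738745.34     3
```

Of 4817 synthetic baseline clients, 1302 have a usable follow-up pair; the
estimated matrix shows strong diagonal persistence and mostly-forward
movement. The first-year cost of the 1341-person cohort is 67.3M EUR —
50.6% of it attributable to mild and 15.7% to severe dementia — and the
tornado shows that the indirect (informal-care) cost dominates the outcome
uncertainty, with the care benefit out-ranking the treatment cost.

The same pipeline runs from the shell:

```bash
demcost run-all --out results/ --seed 1        # synth → … → sensitivity
demcost costs                                   # print the cost schedule
demcost synth --out registry.csv --seed 1       # individual stages
demcost ingest --in registry.csv
```

All parameters (cost rates, care hours, wages, discount rate and mode,
horizon, generator settings) can be overridden from a YAML config passed
with `--config`; see `demcost.config`.

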