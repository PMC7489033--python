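# Methods

## Model

The model is a prevalence-based, three-state, discrete-time Markov cohort
model with yearly cycles. The state space is dementia severity — mild
(GDS 3–4), moderate (GDS 5), severe (GDS 6–7) — with GDS 1–2 (pre-dementia)
outside the model. The chain is time-homogeneous and closed: there is no
death, institutionalization, or incident-entry state, so total cohort
occupancy is conserved across the horizon. These are strong assumptions;
in real cohorts mortality and residential-care transfer would remove
people (and add end-of-life cost), so long-horizon totals from this model
should be read as the cost of the modeled three-state process, not as a
population forecast.

### Transition estimation

Each analysis client contributes exactly one (baseline, one-year follow-up)
state pair — the first annual follow-up; later visits are ignored. The MLE
of the transition matrix is the row-wise count ratio `p̂_ij = n_ij / n_i`
(multinomial rows are independent). Per-cell 95% bounds use the Wald
interval `p̂ ± z·√(p̂(1−p̂)/n_i)` clamped to [0, 1] by default; exact
Clopper–Pearson bounds are available via `ci_method="clopper-pearson"`.
Bound matrices are not row-stochastic and are never used directly for
projection; `scenario_matrix` builds directional worst/best-case matrices
from them (upper bound on worsening moves, lower bound on improving moves,
rows renormalized). That directional construction, combined with the
severity-monotone cost schedule, guarantees the point-estimate cost
trajectory lies between the two scenario trajectories — a plain row
renormalization of the bound matrices does not (it breaks the stochastic
ordering of rows, and in experiments the point trajectory exits such a band
by a few tenths of a percent mid-horizon).

Degenerate inputs: a row with zero observations gets a self-loop point row
(p_ii = 1) with a logged warning, or an error with `empty_row="error"`; its
bounds are reported missing. "Steady state reached" in `classify_states` is
a horizon-bounded statement — the occupancy distribution changed by less
than a tolerance (default 1e-9, max-norm) between successive years within
the horizon — not a claim about the limiting distribution, which every
irreducible finite chain possesses.

### Cost schedule

Per-person annual cost by state (EUR, 2018 price level):

| component | mild | moderate | severe |
|---|---|---|---|
| treatment | 3 533.74 | 3 533.74 | 3 533.74 |
| care benefit (monthly × 12) | 6 776.40 | 11 043.60 | 17 850.00 |
| informal care (hours × wage × 12) | 39 933.60 | 51 343.20 | 69 746.40 |
| indirect = informal − benefit | 33 157.20 | 40 299.60 | 51 896.40 |
| **total** | **43 467.34** | **54 876.94** | **73 280.14** |

Monthly care hours are 140 (mild) and 180 (moderate, severe). Mild and
moderate hours are valued at the opportunity-cost wage (23.77 EUR/h, the
average gross market wage with employer on-costs); severe hours at the
replacement-cost wage (32.29 EUR/h, a registered nurse's wage), because
severe care requires professional-grade caregiving. The severe valuation
can be switched to opportunity cost for exploration. Subtracting the care
benefit from informal cost avoids double counting the hours the public
allowance already pays for; total = treatment + benefit + indirect, which
equals treatment + informal algebraically and is cross-checked at build
time. The published table's moderate-indirect cell reads 40 299.40, but the
defining subtraction (51 343.20 − 11 043.60) and the accompanying text give
40 299.60; the schedule implements the arithmetic.

`hourly_rate_with_oncosts` exposes the wage build-up
`base × (1 + ss) × contracted / (contracted − absences)` with default
loadings of 25 vacation days, 11.2 public holidays, 6.3 sickness days and a
22.51% employer social-security contribution; the underlying base gross
income behind 23.77/32.29 EUR/h is not published, so those two rates are
config defaults rather than derived values.

Schedule cells are exact `Decimal` values at cent precision; floating point
enters only in the projection stage.

### Projection and discounting

Occupancy is a row vector; `x_{t+1} = x_t P`; year t = 1 is the baseline
year and carries no rate factor. Three per-year factor modes exist:
`none`, `present_value` (divide by (1+r)^(t−1)), and `compound_growth`
(multiply by (1+r)^(t−1)); r defaults to 0.05. The default mode is
`compound_growth`: the stated 5% "discount rate" of the source analysis is
irreconcilable with its own multi-year totals under present-value
discounting (the reported year-10 total exceeds the undiscounted ceiling of
1341 × the severe per-person total), so the rate evidently acted as
compound cost growth there; users doing genuine economic evaluation should
select `present_value`. Fractional persons are retained (no rounding).
Fold-increase is cumulative-cost-to-year-k over year-1 cost — the only
reading under which multi-year fold factors of ~7 at five years are
possible with bounded yearly cost.

`microsimulate` is the stochastic counterpart: each replicate moves every
person by multinomial sampling, giving integer trajectories whose mean
converges to the deterministic projection (tested at 2% with 1000
replicates).

### Sensitivity

One-way ±50% variation of the three cost-component aggregates (treatment,
care benefit, indirect) on first-year total cost, each varied with the
others held fixed. Holding indirect fixed while benefit varies (rather
than re-deriving indirect = informal − benefit) is deliberate: under
re-derivation the benefit would cancel out of the total and its tornado
bar would vanish, whereas treating the components as independent inputs
matches how the tornado is actually read. With the default cohort the
ranges are 50.11M (indirect) > 12.44M (benefit) > 4.74M (treatment) EUR.
Ties in the tornado ordering break alphabetically. Finer decompositions
(wage rate vs. hours) would be plausible alternative parameters; the
three-component version is what the model exposes by default.

## Synthetic registry

The generator emulates the registry the analysis assumes rather than any
deposited data: 4817 baseline clients with ~72% follow-up dropout leaving
~1341 pairs; baseline severity mix 784:413:144; transitions from a
configurable row-stochastic matrix; GDS drawn uniformly within a state's
levels (the model never uses within-state granularity); age ~ N(77.9,
9.7²), 65.9% female; benefit level as an ordinal 1–7 from a discretized
latent Gaussian whose default loading (0.21) yields a Spearman rank
correlation of ≈0.2 with severity — a realism knob, not a validated
quantity. Dropout is missing-completely-at-random by default; an odds
multiplier (`dropout_severity_multiplier`) makes it severity-dependent for
robustness exploration, since informative dropout is a known limitation of
such registries. One PRNG stream per run makes output byte-identical under
a fixed seed.

The generator's default transition matrix
([[.78,.18,.04],[.08,.68,.24],[.01,.05,.94]]) is a plausibility choice —
strong persistence, mostly-forward movement, slight mild↔moderate
back-flow, essentially no recovery from severe. The real registry's
estimated matrix is not published, so the multi-year headline figures that
depend on it (five- and ten-year fold increases and totals, late-year
shares) are not reproduction targets; what passing tests show is that the
machinery recovers whatever matrix generated the data and propagates it
correctly, not that real dementia cohorts follow the default matrix. The
generator also omits features of real registries: repeated follow-ups,
measurement error in GDS staging, covariate-dependent transitions, and
informative dropout (by default).

## Problem sizes and numerical choices

Test and acceptance runs use: 100 000 complete pairs for parameter
recovery (max-abs error < 0.01 asserted, ~0.001–0.008 observed), 2000
replicates × 3 rows × 200 observations for CI coverage (expected Wald
coverage for the reference matrix is 93.9%, inside the 93–97% band
asserted), 1000 microsimulation replicates, and hypothesis property suites
of 100–200 examples. The whole suite runs in a few seconds on one CPU.
Row-stochasticity is checked at 1e-9 (projection inputs) and 1e-12
(estimated rows); report rounding is display-only. Negative indirect cost
(benefit exceeding informal value) warns and is kept by default,
clamped to zero behind `clamp_negative_indirect`.
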