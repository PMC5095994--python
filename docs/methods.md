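# Methods

## Model structure

`demsim` is a longitudinal microsimulation of an open population. Each
actor carries a sampling weight (persons represented per actor, equal
across actors: total scheduled entrants / n_actors) and a continuous
birth date uniform within its birth year. Actors enter at the January 1
following birth or immigration, and leave by death or emigration.
Within each calendar year events resolve in a fixed order:

1. emigration (Bernoulli at January 1, hazard per age group × sex × year);
2. dementia-onset draw (January 1, annual probability 1 − e^(−i), onset
   date uniform within the year, absorbing state);
3. death test: the year's hazard — baseline m₀, or m₀·HR from the onset
   date onward — is added to the actor's cumulative hazard and compared
   with a per-actor Exponential(1) threshold drawn once at entry; the
   crossing time is inverted exactly on the piecewise-constant path;
4. annual HUI3 assignment (normal around the age/sex/status mean,
   clipped to [−0.36, 1]);
5. caregiving in force this year (drawn at the end of the previous
   year) and cost accrual;
6. end-of-year caregiving draw for the following year.

Ages used for rate lookups are whole years attained at January 1; rates
are step functions (no interpolation), ages above 110 clamp to the last
row and years outside a table's span clamp to its endpoints. Every
actor dies by their 110th birthday (forced death at the cap). An actor
can onset and die within one year; the onset is counted as an incident
case and the death as a dementia death even when the sampled death time
precedes the sampled onset date — the January-1 onset commitment takes
precedence, mirrored exactly by the oracle.

## Common random numbers and counterfactual twins

All randomness is counter-based: a draw is a SplitMix64 hash of
(master seed, actor id, purpose stream, calendar year) mapped to (0,1).
Identical actor id and seed therefore give identical draws regardless
of scenario, actor ordering, or how a run is partitioned — which makes
scenario comparisons variance-free at the actor level and lets tests
assert orderings exactly (delayed incidence never advances an onset; a
hazard-ratio multiplier below one never shortens a life). Sequential
generators were not used for the per-actor-year draws because draw
identity under reordering and scenario change is a contract here, not
an optimisation.

Each actor's no-dementia twin reuses the same death threshold with
HR ≡ 1. YLL is twin death age minus factual death age (exactly zero,
bitwise, for actors who never onset — the code collapses the
onset-year hazard split whenever the effective HR is 1 so the two
paths stay arithmetically identical). HYLL subtracts HUI3-weighted
years lived, with partial death years prorated. The twin follows the
**non-dementia HUI3 path** by default: the counterfactual is "never
developed dementia", so it escapes both the excess mortality and the
utility decrement. Under this definition HYLL generally *exceeds* YLL
when the decrement is large (the lost years are healthy years, and the
lived dementia years are down-weighted in the factual sum). The
alternative convention — twin keeps the factual utility path, so HYLL
only reflects the HR — is available as
`counterfactual_hui3="factual_status"`. Emigration beyond the factual
lifecourse is ignored for the twin: YLL/HYLL are only recorded for
actors whose factual death is observed (emigration censors).

## Oracle

The cohort-component oracle propagates expected weighted occupancies
N(age, sex, dementia state) at each January 1 with the same event
ordering. Survival through a year is e^(−A) for the dementia-free,
e^(−B) for the prevalent (B = A·HR), and for the onset-year group the
exact uniform-onset-date integral e^(−B)·φ(A−B) with
φ(x) = (1−e^(−x))/x. July-1 occupancies use the half-year analogues;
because birth dates are uniform, half of each January-1 age cohort has
passed its birthday by July 1, which the age-stratified outputs account
for. Caregiving-receipt expectations marginalise the HUI3 band through
the clipped-normal CDF. The microsimulation's expectation equals the
oracle exactly for prevalence, onsets, deaths and caregiving
recipients; z-scores use a pooled-binomial standard error (conservative
for heterogeneous cell probabilities) and skip cells whose expected
actor count is below 5, where a normal z is meaningless. Sector-cost
expectations are not reproduced in the oracle; the cost engine is
instead validated against hand-derived phase-proration closed forms in
the unit tests.

## Synthetic worlds

The generator emulates a developed-country setting on a desk-scale
span (rate tables 1950–2040, birth cohorts back to 1900 so the horizon
has a full age pyramid; earlier years clamp to the 1950 rates):

| parameter | default | rationale |
|---|---|---|
| Gompertz mortality α, β | 3.5e-5, 0.092 /yr | ≈5 %/yr hazard at age 80; male ×1.35 |
| improvement ρ | 0.01 /yr | ≈1 %/yr secular mortality decline; variants 0.5×/1×/1.5× |
| incidence at 65 | 0.004 /yr | doubling every 5.5 y of age, zero below 40, cap 0.35 |
| hazard ratio | 2.0 | matches a ≈146/1000 dementia death rate at prevalent ages |
| HUI3 | 0.95 − 0.0022·(a−20), −0.35 with dementia, sd 0.05 | gentle age decline, large dementia decrement |
| care receipt (dementia) | 0.77 | with hour-bin mix concentrated in 15–70 and ≥71 h/week |
| sector costs | $27k/yr per prevalent person | 46 % long-term care, 27 % hospitalization; incident ×1.5 for acute sectors |
| demography | 190k births/sex/yr, 120k immigrants/yr, emigration 0.002/yr | stationary open population |

The seed drives mild per-sex level jitter (2 % lognormal) on mortality
and incidence so seeds produce distinct worlds without breaking the
monotonicity invariants. Deliberately *not* emulated: birth-cohort
bulges (so prevalence growth ratios are smaller than an aging-boom
demography would give), secular incidence trends, dementia severity
stages, provincial stratification, and under-diagnosis. Passing tests
therefore demonstrate the simulator's internal correctness and
calibration machinery, not the burden level of any real population.

## Numerical choices

- Hazard→probability conversion uses `expm1`; uniforms are
  `((hash >> 11) + 0.5)·2^-53`, open at both ends, so `log1p` and
  `ndtri` never see 0 or 1.
- The death inversion divides only by strictly positive hazards;
  all-zero paths fall through to the cap.
- Weighted aggregates are sums over actors in ascending-id order after
  an internal sort, making every output byte-identical across actor
  permutations and run splits; event logs also carry raw integer
  counts, on which the conservation identity
  prevalent(t+1) = prevalent(t) + onsets − dementia deaths − dementia
  emigrants is exact.
- Bundle CSVs round-trip bit-exactly (full-precision write,
  `float_precision="round_trip"` read).
- The φ(x) integral uses a series below |x| < 1e-8.

## Design choices on open points

- The hazard ratio may vary by age/sex/year; the default is constant.
- Immigrants enter dementia-free and acquire risk from arrival.
- Point prevalence is measured at July 1 (demographic convention; it
  also makes deaths/prevalence arithmetic consistent with the death
  rate as reported).
- "Working age" is 25–65 inclusive at mid-year.
- Caregiving percentages are over all persons with dementia at July 1,
  including "no care"; an actor's first year has no caregiving (the
  draw happens at the preceding year end, when the actor was not yet
  present).
- Onset-year HUI3 uses the dementia mean (the decrement applies from
  the onset year).
- The calibration harness compares cumulative "age X and older" strata
  (40+/65+/75+/85+ by sex): finer cells at feasible actor counts carry
  Monte Carlo errors larger than the ±10 % decision band, which would
  turn the check into a coin flip rather than a calibration statement.

## Problem sizes

Validation runs use 200 000 actors against the oracle over a 30-year
reporting window (seconds on one CPU; the engine is vectorised over
actors with one pass per calendar year). Closed-form YLL recovery uses
100 000 single-cohort actors; at m = 0.05, HR = 2.5 the age-110 cap
truncates the twin's lifetime, so the reference value is the
cap-adjusted closed form 11.916 (0.7 % below the uncapped
1/m − 1/(m·HR) = 12.0), evaluated by independent numerical integration.

## Known limitations

- No remission or misdiagnosis; no risk-factor dependence of incidence.
- No monetary discounting or inflation adjustment; single currency year.
- No uncertainty intervals: sensitivity scenarios stand in for formal
  parameter uncertainty.
- Caregiver HUI3 is a constant model value, not a sampled trajectory.
- The oracle validates first moments; higher-order behaviour (e.g.
  variance of annual aggregates) is checked only implicitly through the
  binomial z-scores.
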