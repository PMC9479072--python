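# Methods

This note records the modelling conventions, parameter semantics and design
choices behind `cohortcea`, in the spirit of a model appendix.

## State-transition structure

The cohort model tracks the expected fraction of a closed cohort (start age
66) across five states: NYHA I–IV and death (absorbing), in 3-month cycles.
Within a cycle, three processes apply to the start-of-cycle alive
occupancy:

1. **Death.** Cardiovascular death (strategy-specific, age-constant — the
   underlying trial provides no age interaction) competes with
   non-cardiovascular death (age-banded annual probabilities, cycle-converted
   under a constant hazard). The combined probability is
   `d = 1 − (1 − p_cv)(1 − p_noncv)`; cause attribution splits `d`
   proportionally to the cause-specific hazards `−ln(1 − p)`. The split
   affects only the cardiovascular-mortality readout, never costs or QALYs.
2. **Hospitalization.** An expectation-counted overlay: expected index
   admissions = `p_hosp ×` alive occupancy; each index admission carries
   `p_readmit = 0.417` expected same-cycle readmissions (no
   readmission-of-readmission chain). Hospitalization does not change state
   membership or mortality; it has cost and disutility consequences only.
3. **NYHA transition.** Survivors move by the shared 4×4 row-stochastic
   matrix at cycle end; the full 5×5 matrix is the NYHA block scaled by
   `1 − d` with a death column `d` and an absorbing dead row.

Death and hospitalization are independent overlays on the same
start-of-cycle population: patients who die during a cycle still
contribute that cycle's expected drug cost, admissions and utility, which
the half-cycle correction then approximately re-times (below).

Background mortality outside the printed 65–79 age bands is total by
construction: ages under 65 use the first band and ages 80+ carry the
75–79 value forward. This is needed for the 15/20-year scenario horizons
and the 40-year survival runs; it understates very-old-age mortality, so
extended-horizon survival should be read as a face-validity check, not a
life-table projection.

## Economics

- **Discounting** at 5%/year, compounded at cycle granularity:
  `(1.05)^(−k/4)` for cycle `k`.
- **Half-cycle correction**: half weight on the first and the terminal
  cycle's (discounted) cost and QALY amounts, full weight between — the
  trapezoid approximation to mid-cycle event timing. A single-cycle run
  gets weight 0.5.
- **Costs**: drug therapy accrues to the alive fraction
  (standard $131.96/cycle both arms; add-on $59.625/cycle = $0.6625 per
  10 mg × 90 days); each expected admission — index or readmission — costs
  $1,783.39.
- **QALYs**: occupancy × NYHA utility × 0.25 years, minus a
  hospitalization disutility per admission. The published inputs state the
  disutility as "−0.1" without a time basis, which admits two readings:
  an absolute 0.1 QALY loss per event, or a −0.1 utility-weight decrement
  over the event's cycle (0.025 QALY). The package implements both
  (`disutility_convention: absolute | per_cycle`). **Default: absolute.**
  The absolute reading reproduces the published incremental QALY gain
  (ΔE ≈ 0.111 vs the printed 0.11, ICER within 5%); the per-cycle reading
  gives ΔE ≈ 0.097 and an ICER ~19% high. The disutility applies to
  readmissions as well as index admissions, as the published input table
  labels it.
- The **initial NYHA distribution is not published**; the default
  (I: 0.00, II: 0.81, III: 0.18, IV: 0.01) emulates the NYHA-II-dominant
  enrolment mix of the anchoring trial and is fully configurable. Base-case
  results shift by roughly ±5% across plausible mixes (compare the
  single-class scenario ICERs).

Parameters carry the printed per-cycle event probabilities as given. The
constant-hazard conversions (`rate_to_probability`,
`annual_to_cycle_probability`) are provided for re-derivation and for the
background-mortality conversion; re-deriving the per-cycle values from the
trial's cumulative incidences gives slightly different numbers (e.g.
0.00951 vs 0.00975 for control cardiovascular death), so the printed
values are authoritative for the base case.

## Incremental comparison

ICER = ΔC/ΔE with weak-inequality dominance flags (dominant: no costlier
and no less effective, not both equal; dominated: the reverse). The WHO
GDP-multiple verdict uses half-open intervals: ICER < 1×GDP is very
cost-effective, 1×GDP ≤ ICER < 3×GDP cost-effective, ICER ≥ 3×GDP not
cost-effective; dominance overrides the ratio. Net monetary benefit is
`WTP × ΔE − ΔC`, with "cost-effective" meaning NMB strictly positive.

## Sensitivity analyses

**One-way (tornado).** Each uncertain input in turn is set to the low and
high end of its 95% CI (or assumed range; discount rate swept 0–8%), all
else at base, and the ICER recomputed through the full pipeline. Each
arm's event probabilities are varied separately (two bars per clinical
parameter). Only the varied value's own support is checked, so sweep
endpoints inside overlapping CIs (e.g. NYHA IV's upper bound above NYHA
III's base) remain usable.

**Probabilistic.** Each repetition redraws every uncertain input:
probabilities and utilities from betas, costs from gammas (both fitted by
method of moments treating the interval as a normal-approximate 95% CI,
SE = width/3.92; the disutility beta is fitted on the magnitude and
negated), and the four transition rows jointly from Dirichlets with
concentration = base row × N_eff (default 1,000; structural zeros
preserved). N_eff is a modelling assumption, not a published value; the
acceptability curve is insensitive to it within a factor of ~2 because the
matrix is common to both arms.

**Between-arm correlation.** By default each strategy's full parameter set
is drawn independently within a repetition, the way a two-arm spreadsheet
model resamples every input cell per arm. This matters: with fully shared
common inputs, the QALY gain is positive in ~98% of draws and the
acceptability curve saturates above 90% at the 3×GDP threshold; with
independent arms the curve stays flat (~50% at 1×GDP, ~70% at 3×GDP),
which is the behaviour of the published analysis this package reproduces.
Analysts who prefer the correlated scheme — arguably better practice, since
it prevents the shared utilities and costs from masquerading as
between-arm uncertainty — can pass `share_arms=True`.

Reproducibility: one root seed; repetition `i` always draws from the
`i`-th spawned substream in a fixed parameter order, so a sample is a pure
function of `(seed, i)`.

**Scenarios.** A whitelisted override set (initial NYHA mix, empagliflozin
unit price, hospitalization cost per event, horizon) rerun through the
base-case pipeline; the standard battery covers single-class NYHA cohorts,
the $0.275/10 mg national purchase price, five hospital-level admission
costs ($1,029.73–$3,336.39) and 10/15/20-year horizons. NYHA scenarios
override the initial distribution only — the cohort remains subject to the
full transition matrix afterwards.

## Synthetic parameter sets and the microsimulation oracle

`generate_parameter_set` draws random, validation-clean inputs with the
same statistical structure as the real set: Dirichlet-perturbed transition
rows with structural zeros preserved, strictly decreasing utilities built
from positive decrements, nondecreasing mortality bands, beta/gamma-style
interval specs, and values within ±50% (relative) of the base case by
default. Toggles construct sign-constrained dominant/dominated pairs for
testing the dominance logic. The generator exercises parameter structure,
not clinical realism: it does not emulate between-parameter clinical
correlations (e.g. sicker cohorts having both higher mortality and higher
admission rates), so passing property tests demonstrate engine
correctness, not calibration to any population.

`microsimulate` is an independent individual-level implementation of the
*same* event-ordering conventions (deliberately so — disagreement between
it and the cohort engine signals an implementation bug, not a modelling
choice). It simulates patients with per-cycle Bernoulli draws and
aggregates occupancies, events and per-patient discounted cost/QALY with
Monte-Carlo standard errors; tests require cohort/microsimulation
agreement within 3 SE on the base case (10,000 patients) and on 20 random
parameter sets (4,000 patients each — sizes chosen to keep the suite
fast while leaving standard errors well below the effects tested).

## Numerical conventions

- Stochasticity tolerances: transition rows and occupancy vectors must sum
  to 1 within 1e-9; traces conserve mass to the same tolerance.
- `median_survival` interpolates linearly within the crossing cycle and
  returns infinity when the dead fraction never reaches 0.5 within the
  extended horizon (default 40 years).
- `cv_mortality_at` interpolates cumulative expected CV deaths linearly
  between cycle boundaries for off-cycle months.
- Degenerate comparisons (ΔC = ΔE = 0) raise rather than emit a 0/0 ICER.
- Money is kept at full precision internally; reports round to cents only
  at presentation.

## Known limitations

- No treatment discontinuation, crossover, adverse events, indirect costs
  or non-HF hospitalizations (all outside the modelled decision problem).
- Event probabilities are age-constant; only background mortality ages.
- The 27-month cardiovascular-mortality readout compounds the printed
  per-cycle probabilities and lands ~1 percentage point below the
  published model's figure (8.4% vs 9.5% for control) — within the
  published model's own tolerance to its trial anchor, but a reminder that
  the original's occupancy weighting is not fully specified.
- The one-way tornado ranks the control-arm hospitalization probability
  and the hospitalization cost essentially tied (widths within 1.5%);
  under the absolute disutility convention the probability bar edges ahead,
  whereas the published ranking narrative places the cost bar fourth.
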