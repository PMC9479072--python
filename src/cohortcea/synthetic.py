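"""Synthetic parameter sets and an individual-level simulation oracle.

``generate_parameter_set`` draws random, fully valid model inputs with the
same statistical structure the analysis assumes — row-stochastic Dirichlet
transition matrices, beta-interval probabilities and utilities, gamma-style
cost ranges — so every pipeline stage can be property-tested without any
external data.  ``microsimulate`` pushes simulated individual patients
through the *same* per-cycle event ordering as the cohort engine (death and
hospitalization as independent overlays on the start-of-cycle alive
population, NYHA transition for survivors at cycle end), giving an
independent Monte-Carlo check of occupancies, event counts, discounted costs
and QALYs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .economics import discount_factors, half_cycle_weights
from .engine import cycle_death_probability, death_cause_split
from .params import (
    BackgroundMortality,
    CohortSpec,
    CostInputs,
    EventProbabilities,
    ModelParameters,
    ParamDistribution,
    UtilityInputs,
    annual_to_cycle_probability,
    default_parameters,
)

__all__ = ["SyntheticSpec", "generate_parameter_set", "MicrosimTrace", "microsimulate"]


@dataclass
class SyntheticSpec:
    """Controls for the random parameter-set generator.

    ``jitter`` scales how far (relative) values may wander from the built-in
    base case; ``ci_width_scale`` widens or narrows the generated 95%
    intervals; ``force`` may be ``"dominant"`` or ``"dominated"`` to build
    sign-constrained comparisons for testing the dominance logic.
    """

    seed: int = 0
    jitter: float = 0.5
    ci_width_scale: float = 1.0
    n_eff_range: tuple[float, float] = (500.0, 2000.0)
    force: str | None = None


def _jittered(rng: np.random.Generator, base: float, jitter: float,
              lo: float | None = None, hi: float | None = None) -> float:
    value = base * (1.0 + jitter * rng.uniform(-1.0, 1.0))
    if lo is not None:
        value = max(value, lo)
    if hi is not None:
        value = min(value, hi)
    return value


def generate_parameter_set(spec: SyntheticSpec) -> ModelParameters:
    """Draw one random, validation-clean parameter set.

    Values stay within ``spec.jitter`` (relative) of the base case; the
    transition matrix is a Dirichlet perturbation of the base rows
    (structural zeros preserved); utilities keep their strict NYHA ordering
    by construction.  Same seed, same output.
    """
    rng = np.random.default_rng(spec.seed)
    base = default_parameters()
    j = spec.jitter

    def event_block(base_ev: EventProbabilities) -> EventProbabilities:
        return EventProbabilities(
            p_cv_death=_jittered(rng, base_ev.p_cv_death, j, 1e-5, 0.2),
            p_hosp=_jittered(rng, base_ev.p_hosp, j, 1e-5, 0.5),
            p_readmit=_jittered(rng, base_ev.p_readmit, j, 0.0, 0.95),
        )

    control = event_block(base.strategies["control"])
    emp = event_block(base.strategies["empagliflozin"])
    emp.p_readmit = control.p_readmit  # shared input, as in the base case

    costs = CostInputs(
        standard_therapy_per_cycle=_jittered(
            rng, base.costs.standard_therapy_per_cycle, j, 1.0
        ),
        empagliflozin_per_cycle=_jittered(
            rng, base.costs.empagliflozin_per_cycle, j, 1.0
        ),
        hospitalization_per_event=_jittered(
            rng, base.costs.hospitalization_per_event, j, 10.0
        ),
    )

    if spec.force == "dominant":
        # Cheaper and more effective: no drug add-on cost, strictly lower
        # event probabilities than the comparator.
        costs.empagliflozin_per_cycle = 0.0
        emp.p_cv_death = 0.5 * control.p_cv_death
        emp.p_hosp = 0.5 * control.p_hosp
    elif spec.force == "dominated":
        # Costlier and less effective.
        costs.empagliflozin_per_cycle = max(costs.empagliflozin_per_cycle, 50.0)
        emp.p_cv_death = min(1.5 * control.p_cv_death + 1e-4, 0.3)
        emp.p_hosp = min(1.5 * control.p_hosp + 1e-4, 0.6)

    # Strictly decreasing utilities built from positive decrements.
    u1 = rng.uniform(0.70, 0.95)
    drops = rng.uniform(0.02, 0.12, size=3)
    nyha = (u1, u1 - drops[0], u1 - drops[0] - drops[1], u1 - sum(drops))
    utilities = UtilityInputs(
        nyha=tuple(float(max(u, 0.05)) for u in nyha),
        hospitalization_disutility=-_jittered(rng, 0.1, j, 0.01, 0.5),
    )

    # Dirichlet-perturbed transition rows; structural zeros preserved.
    n_eff = rng.uniform(*spec.n_eff_range)
    tm = np.zeros((4, 4))
    base_tm = np.asarray(base.transition_matrix)
    for i, row in enumerate(base_tm):
        pos = row > 0
        tm[i, pos] = rng.dirichlet(row[pos] * n_eff)

    # Nondecreasing annual background mortality.
    m0 = rng.uniform(0.001, 0.004)
    increments = rng.uniform(0.0, 0.002, size=2)
    mortality = BackgroundMortality(
        bands={
            65: m0,
            70: m0 + increments[0],
            75: m0 + increments[0] + increments[1],
        }
    )

    init = rng.dirichlet(np.array([1.0, 8.0, 2.0, 0.5]))
    cohort = CohortSpec(
        start_age=float(rng.uniform(60, 75)),
        horizon=float(rng.integers(4, 16)),
        cycle_length=0.25,
        initial_distribution=tuple(init.tolist()),
        annual_discount_rate=float(rng.uniform(0.0, 0.08)),
    )

    def interval(mean: float, rel: float, lo: float, hi: float,
                 family: str) -> ParamDistribution:
        half = rel * spec.ci_width_scale * mean
        return ParamDistribution(
            family, mean, max(mean - half, lo), min(mean + half, hi)
        )

    distributions = {
        "p_cv_death.control": interval(control.p_cv_death, 0.1, 0.0, 1.0, "beta"),
        "p_cv_death.empagliflozin": interval(emp.p_cv_death, 0.1, 0.0, 1.0, "beta"),
        "p_hosp.control": interval(control.p_hosp, 0.1, 0.0, 1.0, "beta"),
        "p_hosp.empagliflozin": interval(emp.p_hosp, 0.1, 0.0, 1.0, "beta"),
        "p_readmit": interval(control.p_readmit, 0.1, 0.0, 1.0, "beta"),
        "utility.nyha1": interval(utilities.nyha[0], 0.04, 0.0, 1.0, "beta"),
        "utility.nyha2": interval(utilities.nyha[1], 0.04, 0.0, 1.0, "beta"),
        "utility.nyha3": interval(utilities.nyha[2], 0.06, 0.0, 1.0, "beta"),
        "utility.nyha4": interval(utilities.nyha[3], 0.1, 0.0, 1.0, "beta"),
        "disutility.hospitalization": interval(
            -utilities.hospitalization_disutility, 0.2, 0.0, 1.0, "beta"
        ),
        "cost.standard_therapy": interval(
            costs.standard_therapy_per_cycle, 0.2, 0.0, np.inf, "gamma"
        ),
        "cost.hospitalization": interval(
            costs.hospitalization_per_event, 0.4, 0.0, np.inf, "gamma"
        ),
    }
    if costs.empagliflozin_per_cycle > 0:
        distributions["cost.empagliflozin"] = interval(
            costs.empagliflozin_per_cycle, 0.2, 0.0, np.inf, "gamma"
        )

    return ModelParameters(
        strategies={"control": control, "empagliflozin": emp},
        transition_matrix=tm,
        mortality=mortality,
        utilities=utilities,
        costs=costs,
        cohort=cohort,
        distributions=distributions,
        dirichlet_n_eff=float(n_eff),
    ).validate()


@dataclass
class MicrosimTrace:
    """Empirical aggregates from an individual-level simulation.

    Occupancy rows are fractions of ``n_patients`` at each cycle start;
    ``*_se`` fields are Monte-Carlo standard errors of the matching
    estimates.  Cost/QALY totals use the same discounting and half-cycle
    weighting as the cohort pipeline, so they estimate the
    ``evaluate_strategy`` totals directly.
    """

    n_patients: int
    occupancy: np.ndarray            # (n_cycles + 1, 5) fractions
    occupancy_se: np.ndarray
    index_hospitalizations: np.ndarray  # per-cycle mean per patient
    readmissions: np.ndarray
    cv_deaths: np.ndarray
    noncv_deaths: np.ndarray
    mean_cost: float
    mean_cost_se: float
    mean_qaly: float
    mean_qaly_se: float


def microsimulate(
    params: ModelParameters,
    strategy: str,
    n_patients: int = 10_000,
    seed: int = 0,
    horizon: float | None = None,
) -> MicrosimTrace:
    """Simulate individual patients with the cohort engine's event ordering.

    Per cycle, for each alive patient: an independent death draw (cause
    attributed by the proportional-hazards split), an independent
    hospitalization draw (with one possible readmission), then — for
    survivors — a NYHA transition draw.  Vectorized over patients.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    spec = params.cohort
    ev = params.events(strategy)
    if horizon is None:
        horizon = spec.horizon
    n_cycles = int(round(horizon / spec.cycle_length))
    rng = np.random.default_rng(seed)

    tm = np.asarray(params.transition_matrix, dtype=float)
    tm_cum = np.cumsum(tm, axis=1)
    init_cum = np.cumsum(np.asarray(spec.initial_distribution))
    states = np.searchsorted(init_cum, rng.random(n_patients), side="right")
    states = np.minimum(states, 3).astype(np.int64)

    disc = discount_factors(n_cycles, spec.annual_discount_rate, spec.cycle_length)
    w = half_cycle_weights(n_cycles)
    drug = params.costs.drug_cost_per_cycle(strategy)
    hosp_cost = params.costs.hospitalization_per_event
    nyha_u = np.asarray(params.utilities.nyha)
    loss_per_event = -params.utilities.hospitalization_disutility
    if params.disutility_convention == "per_cycle":
        loss_per_event *= spec.cycle_length

    occupancy = np.zeros((n_cycles + 1, 5))
    hosp_mean = np.zeros(n_cycles)
    readmit_mean = np.zeros(n_cycles)
    cv_mean = np.zeros(n_cycles)
    noncv_mean = np.zeros(n_cycles)
    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)

    def record_occupancy(k: int) -> None:
        counts = np.bincount(states, minlength=5)
        occupancy[k] = counts / n_patients

    record_occupancy(0)
    for k in range(n_cycles):
        age = spec.start_age + k * spec.cycle_length
        p_noncv = annual_to_cycle_probability(
            params.mortality.annual_probability(age), spec.cycle_length
        )
        d = cycle_death_probability(ev.p_cv_death, p_noncv)
        share_cv, _ = death_cause_split(ev.p_cv_death, p_noncv)

        alive = states < 4
        n_alive = int(alive.sum())
        if n_alive == 0:
            record_occupancy(k + 1)
            continue

        dies = alive & (rng.random(n_patients) < d)
        cv = dies & (rng.random(n_patients) < share_cv)
        hosp = alive & (rng.random(n_patients) < ev.p_hosp)
        readmit = hosp & (rng.random(n_patients) < ev.p_readmit)
        events = hosp.astype(float) + readmit.astype(float)

        hosp_mean[k] = hosp.sum() / n_patients
        readmit_mean[k] = readmit.sum() / n_patients
        cv_mean[k] = cv.sum() / n_patients
        noncv_mean[k] = (dies & ~cv).sum() / n_patients

        weight = w[k] * disc[k]
        cost += weight * (alive * drug + events * hosp_cost)
        qaly += w[k] * disc[k] * (
            np.where(alive, nyha_u[np.minimum(states, 3)], 0.0) * spec.cycle_length
            - events * loss_per_event
        )

        # NYHA transitions for survivors at cycle end; deaths become absorbed.
        survivors = alive & ~dies
        if survivors.any():
            u = rng.random(n_patients)
            new_states = states.copy()
            for s in range(4):
                mask = survivors & (states == s)
                if mask.any():
                    new_states[mask] = np.minimum(
                        np.searchsorted(tm_cum[s], u[mask], side="right"), 3
                    )
            states = new_states
        states[dies] = 4
        record_occupancy(k + 1)

    occ_se = np.sqrt(occupancy * (1.0 - occupancy) / n_patients)
    return MicrosimTrace(
        n_patients=n_patients,
        occupancy=occupancy,
        occupancy_se=occ_se,
        index_hospitalizations=hosp_mean,
        readmissions=readmit_mean,
        cv_deaths=cv_mean,
        noncv_deaths=noncv_mean,
        mean_cost=float(cost.mean()),
        mean_cost_se=float(cost.std(ddof=1) / np.sqrt(n_patients)),
        mean_qaly=float(qaly.mean()),
        mean_qaly_se=float(qaly.std(ddof=1) / np.sqrt(n_patients)),
    )
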