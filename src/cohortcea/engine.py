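"""Markov cohort engine: full transition dynamics and the cohort trace.

Each 3-month cycle combines three processes for an alive patient:

* death, from two competing causes — a strategy-specific cardiovascular
  per-cycle probability and an age-banded non-cardiovascular annual
  probability converted to the cycle length;
* hospitalization for heart failure, an expectation-counted event overlay
  (with one possible same-cycle readmission) that does not change state
  membership;
* NYHA class transition among survivors, applied at the end of the cycle via
  the shared 4x4 matrix.

Death and hospitalization are independent overlays on the start-of-cycle
alive occupancy.  Cause of death is attributed by the proportional-hazards
split, which affects only the cardiovascular-mortality readout, not costs or
QALYs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    ALIVE_STATES,
    HealthState,
    ModelParameters,
    ParameterError,
    annual_to_cycle_probability,
)

__all__ = [
    "cycle_death_probability",
    "death_cause_split",
    "build_full_matrix",
    "run_cohort",
    "cv_mortality_at",
    "median_survival",
    "CohortTrace",
]

N_STATES = 5
DEAD = int(HealthState.DEAD)


def cycle_death_probability(p_cv: float, p_noncv_cycle: float) -> float:
    """Combined per-cycle death probability from two independent competing
    causes: ``1 - (1 - p_cv) * (1 - p_noncv)``."""
    for name, p in (("p_cv", p_cv), ("p_noncv_cycle", p_noncv_cycle)):
        if not (0.0 <= p <= 1.0):
            raise ParameterError(f"{name} out of [0, 1]: {p}")
    return 1.0 - (1.0 - p_cv) * (1.0 - p_noncv_cycle)


def death_cause_split(p_cv: float, p_noncv_cycle: float) -> tuple[float, float]:
    """Fraction of combined deaths attributed to each cause, split
    proportionally to the cause-specific hazards."""
    if p_cv == 0.0 and p_noncv_cycle == 0.0:
        return 0.0, 0.0
    if p_cv >= 1.0 or p_noncv_cycle >= 1.0:
        # A sure cause absorbs everything; split equally if both are sure.
        if p_cv >= 1.0 and p_noncv_cycle >= 1.0:
            return 0.5, 0.5
        return (1.0, 0.0) if p_cv >= 1.0 else (0.0, 1.0)
    h_cv = -math.log1p(-p_cv)
    h_noncv = -math.log1p(-p_noncv_cycle)
    total = h_cv + h_noncv
    return h_cv / total, h_noncv / total


def build_full_matrix(
    params: ModelParameters, strategy: str, age: float
) -> np.ndarray:
    """One-cycle 5x5 transition matrix over (NYHA I..IV, dead) at one age.

    Every alive state shares the same death probability ``d`` (NYHA class
    does not modify mortality in this model); the alive block is the NYHA
    matrix scaled by ``1 - d`` and the dead row is absorbing.
    """
    ev = params.events(strategy)
    p_noncv = annual_to_cycle_probability(
        params.mortality.annual_probability(age), params.cohort.cycle_length
    )
    d = cycle_death_probability(ev.p_cv_death, p_noncv)
    tm = np.asarray(params.transition_matrix, dtype=float)
    if np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-9):
        raise ParameterError("NYHA transition matrix rows must sum to 1")
    full = np.zeros((N_STATES, N_STATES))
    full[:4, :4] = (1.0 - d) * tm
    full[:4, DEAD] = d
    full[DEAD, DEAD] = 1.0
    return full


@dataclass
class CohortTrace:
    """Per-cycle bookkeeping of one strategy's cohort run.

    ``occupancy`` has ``n_cycles + 1`` rows: row ``k`` is the state
    distribution at the start of cycle ``k`` (row ``n_cycles`` is the end of
    the horizon).  Event expectations (index hospitalizations, readmissions,
    CV and non-CV deaths) are per cycle and refer to events occurring during
    cycle ``k``.
    """

    strategy: str
    cycle_length: float
    occupancy: np.ndarray          # (n_cycles + 1, 5)
    ages: np.ndarray               # (n_cycles + 1,)
    index_hospitalizations: np.ndarray  # (n_cycles,)
    readmissions: np.ndarray
    cv_deaths: np.ndarray
    noncv_deaths: np.ndarray
    params_digest: str = field(default="", repr=False)

    @property
    def n_cycles(self) -> int:
        return len(self.index_hospitalizations)

    @property
    def alive(self) -> np.ndarray:
        """Alive fraction at each cycle start (length ``n_cycles + 1``)."""
        return self.occupancy[:, :4].sum(axis=1)

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, DEAD]

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        pad = lambda a: np.append(a, np.nan)  # noqa: E731 - events undefined at horizon end
        return pd.DataFrame(
            {
                "cycle": np.arange(n + 1),
                "age": self.ages,
                "nyha1": self.occupancy[:, 0],
                "nyha2": self.occupancy[:, 1],
                "nyha3": self.occupancy[:, 2],
                "nyha4": self.occupancy[:, 3],
                "dead": self.occupancy[:, 4],
                "index_hospitalizations": pad(self.index_hospitalizations),
                "readmissions": pad(self.readmissions),
                "cv_deaths": pad(self.cv_deaths),
                "noncv_deaths": pad(self.noncv_deaths),
            }
        )

    def to_csv(self, path) -> None:
        """Tidy CSV export with a comment header naming strategy/parameters."""
        with open(path, "w") as fh:
            fh.write(f"# strategy: {self.strategy}\n")
            if self.params_digest:
                fh.write(f"# parameters_sha256: {self.params_digest}\n")
            self.to_frame().to_csv(fh, index=False)


def run_cohort(
    params: ModelParameters,
    strategy: str,
    horizon: float | None = None,
) -> CohortTrace:
    """Run the deterministic cohort trace over the horizon.

    The cohort starts fully alive in the configured initial NYHA mix and ages
    by one cycle length per cycle; expected index hospitalizations in cycle
    ``k`` are ``p_hosp`` times the alive occupancy at the start of ``k`` and
    each carries ``p_readmit`` expected same-cycle readmissions.
    """
    spec = params.cohort
    ev = params.events(strategy)
    if horizon is None:
        horizon = spec.horizon
    n_ratio = horizon / spec.cycle_length
    if horizon <= 0 or abs(n_ratio - round(n_ratio)) > 1e-9:
        raise ParameterError(
            f"horizon must be a positive multiple of cycle_length: {horizon}"
        )
    n_cycles = int(round(n_ratio))

    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0, :4] = spec.initial_distribution
    ages = spec.start_age + spec.cycle_length * np.arange(n_cycles + 1)
    index_hosp = np.zeros(n_cycles)
    readmit = np.zeros(n_cycles)
    cv_deaths = np.zeros(n_cycles)
    noncv_deaths = np.zeros(n_cycles)

    for k in range(n_cycles):
        age = ages[k]
        occ = occupancy[k]
        alive = occ[:4].sum()
        p_noncv = annual_to_cycle_probability(
            params.mortality.annual_probability(age), spec.cycle_length
        )
        d = cycle_death_probability(ev.p_cv_death, p_noncv)
        share_cv, share_noncv = death_cause_split(ev.p_cv_death, p_noncv)
        index_hosp[k] = ev.p_hosp * alive
        readmit[k] = index_hosp[k] * ev.p_readmit
        cv_deaths[k] = alive * d * share_cv
        noncv_deaths[k] = alive * d * share_noncv
        occupancy[k + 1] = occ @ build_full_matrix(params, strategy, age)

    return CohortTrace(
        strategy=strategy,
        cycle_length=spec.cycle_length,
        occupancy=occupancy,
        ages=ages,
        index_hospitalizations=index_hosp,
        readmissions=readmit,
        cv_deaths=cv_deaths,
        noncv_deaths=noncv_deaths,
    )


def cv_mortality_at(trace: CohortTrace, months: float) -> float:
    """Cumulative expected cardiovascular deaths up to ``months``.

    Months that are not a multiple of the cycle length are linearly
    interpolated between the bracketing cycle boundaries.
    """
    if months < 0:
        raise ParameterError(f"months must be nonnegative: {months}")
    cycles = months / (12.0 * trace.cycle_length)
    if cycles > trace.n_cycles + 1e-9:
        raise ParameterError(
            f"{months} months exceeds the trace horizon "
            f"({trace.n_cycles * trace.cycle_length * 12:g} months)"
        )
    cum = np.concatenate([[0.0], np.cumsum(trace.cv_deaths)])
    return float(np.interp(cycles, np.arange(len(cum)), cum))


#: Sentinel returned by :func:`median_survival` when the cohort's dead
#: fraction never reaches one half within the extended horizon.
NOT_REACHED = math.inf


def median_survival(
    params: ModelParameters, strategy: str, extended_horizon: float = 40.0
) -> float:
    """Median survival time (years) from an extended-horizon run.

    Runs the cohort over ``extended_horizon`` years (independent of the
    economic horizon) and returns the first time the dead-state occupancy
    reaches 0.5, linearly interpolated within the crossing cycle;
    :data:`NOT_REACHED` (infinity) if it never does.
    """
    trace = run_cohort(params, strategy, horizon=extended_horizon)
    dead = trace.dead
    idx = np.nonzero(dead >= 0.5)[0]
    if len(idx) == 0:
        return NOT_REACHED
    k = int(idx[0])
    if k == 0:
        return 0.0
    frac = (0.5 - dead[k - 1]) / (dead[k] - dead[k - 1])
    return (k - 1 + frac) * trace.cycle_length
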