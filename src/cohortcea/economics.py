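"""Costs and QALYs: discounting, per-cycle valuation, half-cycle correction.

Costs comprise per-cycle drug therapy (standard therapy for everyone alive,
plus the empagliflozin add-on under that strategy) and a per-event
hospitalization cost applied to index admissions and readmissions alike.
QALYs weight state occupancy by NYHA utilities over the cycle length and
subtract a hospitalization disutility per event.

Both streams are discounted at cycle granularity and half-cycle corrected by
half-weighting the first and the terminal cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import CohortTrace, run_cohort
from .params import CostInputs, ModelParameters, UtilityInputs

__all__ = [
    "discount_factor",
    "discount_factors",
    "half_cycle_weights",
    "cycle_cost",
    "cycle_qaly",
    "evaluate_strategy",
    "StrategyResult",
]


def discount_factor(
    cycle_index: int, annual_rate: float, cycle_length: float
) -> float:
    """Per-cycle discount factor ``(1 + r) ** -(k * cycle_length)``.

    Cycle 0 is undiscounted; a 5% annual rate over 3-month cycles compounds
    smoothly rather than in annual blocks.
    """
    if cycle_index < 0:
        raise ValueError(f"cycle_index must be nonnegative: {cycle_index}")
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be nonnegative: {annual_rate}")
    return float((1.0 + annual_rate) ** (-cycle_index * cycle_length))


def discount_factors(
    n_cycles: int, annual_rate: float, cycle_length: float
) -> np.ndarray:
    k = np.arange(n_cycles)
    return (1.0 + annual_rate) ** (-k * cycle_length)


def half_cycle_weights(n_cycles: int) -> np.ndarray:
    """Half weight on the first and the terminal cycle, full weight between.

    A single-cycle horizon gets the single weight 0.5 (the cycle is both
    first and terminal).
    """
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    w = np.ones(n_cycles)
    w[0] = 0.5
    w[-1] = 0.5
    return w


def _qaly_loss_per_event(
    utilities: UtilityInputs, cycle_length: float, convention: str
) -> float:
    loss = -utilities.hospitalization_disutility
    if convention == "per_cycle":
        return loss * cycle_length
    if convention == "absolute":
        return loss
    raise ValueError(f"unknown disutility convention {convention!r}")


def cycle_cost(
    occupancy: np.ndarray,
    index_hospitalizations: float,
    readmissions: float,
    costs: CostInputs,
    strategy: str,
) -> float:
    """Undiscounted cost of one cycle from its start-of-cycle occupancy.

    Drug costs accrue to the alive fraction only; hospitalization costs to
    every expected admission (index or readmission).
    """
    alive = float(np.asarray(occupancy)[:4].sum())
    events = index_hospitalizations + readmissions
    return alive * costs.drug_cost_per_cycle(strategy) + events * costs.hospitalization_per_event


def cycle_qaly(
    occupancy: np.ndarray,
    index_hospitalizations: float,
    readmissions: float,
    utilities: UtilityInputs,
    cycle_length: float,
    convention: str = "absolute",
) -> float:
    """Undiscounted QALYs accrued in one cycle.

    State occupancy is valued at the NYHA utilities over ``cycle_length``;
    each expected hospitalization (index or readmission) subtracts the
    disutility, either as an absolute QALY loss per event or as a
    cycle-length-scaled utility decrement depending on ``convention``.
    """
    occ = np.asarray(occupancy)
    base = float(occ[:4] @ np.asarray(utilities.nyha)) * cycle_length
    events = index_hospitalizations + readmissions
    return base - events * _qaly_loss_per_event(utilities, cycle_length, convention)


@dataclass
class StrategyResult:
    """Discounted and undiscounted totals for one strategy.

    The per-cycle streams are already discounted and half-cycle weighted, so
    the totals are exact sums of the streams.
    """

    strategy: str
    total_cost: float
    total_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    cost_stream: np.ndarray
    qaly_stream: np.ndarray
    trace: CohortTrace

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "total_cost": self.total_cost,
            "total_qaly": self.total_qaly,
            "undiscounted_cost": self.undiscounted_cost,
            "undiscounted_qaly": self.undiscounted_qaly,
        }


def evaluate_strategy(
    params: ModelParameters,
    strategy: str,
    horizon: float | None = None,
) -> StrategyResult:
    """Run the cohort and turn the trace into discounted totals.

    Per-cycle costs and QALYs are computed from start-of-cycle occupancy and
    that cycle's expected events, discounted by the per-cycle factor and
    half-cycle weighted; totals are the stream sums.
    """
    trace = run_cohort(params, strategy, horizon=horizon)
    n = trace.n_cycles
    spec = params.cohort
    disc = discount_factors(n, spec.annual_discount_rate, spec.cycle_length)
    w = half_cycle_weights(n)

    raw_cost = np.array(
        [
            cycle_cost(
                trace.occupancy[k],
                trace.index_hospitalizations[k],
                trace.readmissions[k],
                params.costs,
                strategy,
            )
            for k in range(n)
        ]
    )
    raw_qaly = np.array(
        [
            cycle_qaly(
                trace.occupancy[k],
                trace.index_hospitalizations[k],
                trace.readmissions[k],
                params.utilities,
                spec.cycle_length,
                params.disutility_convention,
            )
            for k in range(n)
        ]
    )
    cost_stream = w * disc * raw_cost
    qaly_stream = w * disc * raw_qaly
    return StrategyResult(
        strategy=strategy,
        total_cost=float(cost_stream.sum()),
        total_qaly=float(qaly_stream.sum()),
        undiscounted_cost=float((w * raw_cost).sum()),
        undiscounted_qaly=float((w * raw_qaly).sum()),
        cost_stream=cost_stream,
        qaly_stream=qaly_stream,
        trace=trace,
    )
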