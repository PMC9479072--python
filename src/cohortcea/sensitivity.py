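"""Sensitivity and scenario analyses.

* One-way deterministic sensitivity (tornado): each uncertain input is set to
  its low and high value in turn, everything else at base, and the ICER
  recomputed through the full pipeline.
* Probabilistic sensitivity analysis: Monte-Carlo draws of every uncertain
  input from its stated family (beta for probabilities/utilities, gamma for
  costs, Dirichlet for the NYHA transition rows), 1,000 iterations by
  default, summarized as a cost-effectiveness plane and an acceptability
  curve.
* Scenario engine: whitelisted overrides (initial NYHA mix, empagliflozin
  price, hospitalization cost, horizon) rerun through the base-case pipeline.

Reproducibility: one root seed; each PSA iteration draws from its own
deterministically spawned substream, in a fixed parameter order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compare import ICERResult, compare, net_monetary_benefit
from .economics import evaluate_strategy
from .params import (
    DAYS_PER_CYCLE,
    ModelParameters,
    ParamDistribution,
    ParameterError,
)

__all__ = [
    "TornadoEntry",
    "one_way_dsa",
    "fit_distribution",
    "PSASample",
    "run_psa",
    "CEACCurve",
    "ceac",
    "ScenarioSpec",
    "run_scenario",
    "standard_scenarios",
    "apply_override",
    "base_icer",
]


# ---------------------------------------------------------------------------
# Parameter override registry
# ---------------------------------------------------------------------------

def _support_probability(v: float) -> bool:
    return 0.0 <= v <= 1.0


def _support_nonneg(v: float) -> bool:
    return v >= 0.0


def _support_discount(v: float) -> bool:
    return 0.0 <= v <= 0.08


def _set_utility(i: int) -> Callable[[ModelParameters, float], None]:
    def setter(p: ModelParameters, v: float) -> None:
        nyha = list(p.utilities.nyha)
        nyha[i] = v
        p.utilities.nyha = tuple(nyha)

    return setter


def _set_disutility(p: ModelParameters, v: float) -> None:
    # Stored distribution is on the magnitude; the input weight is negative.
    p.utilities.hospitalization_disutility = -abs(v)


#: name -> (setter, support check).  Names match ``ModelParameters.distributions``
#: keys, plus the discount rate which is swept in the one-way analysis only.
_OVERRIDES: dict[str, tuple[Callable[[ModelParameters, float], None], Callable[[float], bool]]] = {
    "p_cv_death.control": (
        lambda p, v: setattr(p.strategies["control"], "p_cv_death", v),
        _support_probability,
    ),
    "p_cv_death.empagliflozin": (
        lambda p, v: setattr(p.strategies["empagliflozin"], "p_cv_death", v),
        _support_probability,
    ),
    "p_hosp.control": (
        lambda p, v: setattr(p.strategies["control"], "p_hosp", v),
        _support_probability,
    ),
    "p_hosp.empagliflozin": (
        lambda p, v: setattr(p.strategies["empagliflozin"], "p_hosp", v),
        _support_probability,
    ),
    "p_readmit": (
        lambda p, v: [setattr(ev, "p_readmit", v) for ev in p.strategies.values()],
        _support_probability,
    ),
    "utility.nyha1": (_set_utility(0), _support_probability),
    "utility.nyha2": (_set_utility(1), _support_probability),
    "utility.nyha3": (_set_utility(2), _support_probability),
    "utility.nyha4": (_set_utility(3), _support_probability),
    "disutility.hospitalization": (_set_disutility, _support_probability),
    "cost.standard_therapy": (
        lambda p, v: setattr(p.costs, "standard_therapy_per_cycle", v),
        _support_nonneg,
    ),
    "cost.empagliflozin": (
        lambda p, v: setattr(p.costs, "empagliflozin_per_cycle", v),
        _support_nonneg,
    ),
    "cost.hospitalization": (
        lambda p, v: setattr(p.costs, "hospitalization_per_event", v),
        _support_nonneg,
    ),
    "discount_rate": (
        lambda p, v: setattr(p.cohort, "annual_discount_rate", v),
        _support_discount,
    ),
}


def apply_override(
    params: ModelParameters, name: str, value: float
) -> ModelParameters:
    """Return a copy of ``params`` with one named scalar input replaced.

    Only the value's own support is checked (probabilities in [0, 1], costs
    nonnegative, discount rate in [0, 0.08]); cross-field orderings such as
    strictly decreasing utilities are deliberately not re-imposed so that
    sampled or swept values near overlapping ranges remain usable.
    """
    try:
        setter, support = _OVERRIDES[name]
    except KeyError:
        raise ParameterError(f"unknown parameter name {name!r}") from None
    if not support(value):
        raise ParameterError(f"value {value} outside the valid range for {name}")
    out = params.copy()
    setter(out, value)
    return out


def base_icer(params: ModelParameters) -> ICERResult:
    """Full-pipeline incremental comparison of empagliflozin vs control."""
    return compare(
        evaluate_strategy(params, "empagliflozin"),
        evaluate_strategy(params, "control"),
    )


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


#: Discount-rate sweep bounds used when no explicit range is supplied.
DISCOUNT_RANGE = (0.0, 0.08)


def one_way_dsa(
    params: ModelParameters,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: ICER with each input at its low and high bound.

    ``ranges`` defaults to the 95% intervals / assumed ranges carried in
    ``params.distributions`` plus the 0-8% discount-rate sweep.  Entries are
    sorted by descending bar width.
    """
    if ranges is None:
        ranges = {
            name: (dist.low, dist.high)
            for name, dist in params.distributions.items()
        }
        ranges["discount_rate"] = DISCOUNT_RANGE

    entries = []
    for name, (low, high) in ranges.items():
        icers = []
        for value in (low, high):
            result = base_icer(apply_override(params, name, value))
            icers.append(result.icer if result.icer is not None else math.nan)
        entries.append(
            TornadoEntry(
                parameter=name, low=low, high=high,
                icer_low=icers[0], icer_high=icers[1],
            )
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "width": e.width,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------

class Sampler:
    """A fitted one-parameter sampler with a known mean."""

    mean: float

    def rvs(self, rng: np.random.Generator) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class PointMass(Sampler):
    def __init__(self, value: float):
        self.mean = value

    def rvs(self, rng: np.random.Generator) -> float:
        return self.mean


class BetaSampler(Sampler):
    def __init__(self, a: float, b: float):
        self.a, self.b = a, b
        self.mean = a / (a + b)

    def rvs(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.a, self.b))


class GammaSampler(Sampler):
    def __init__(self, shape: float, scale: float):
        self.shape, self.scale = shape, scale
        self.mean = shape * scale

    def rvs(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, self.scale))


def fit_distribution(spec: ParamDistribution, name: str = "") -> Sampler:
    """Method-of-moments fit treating (low, high) as a 95% central interval.

    The standard error is ``(high - low) / 3.92``; beta shapes come from the
    mean/variance identity, gamma from shape = (mean/se)^2.  A degenerate
    interval collapses to a point mass.
    """
    spec.validate(prefix=f"distributions.{name or '<anon>'}")
    m, se = spec.mean, (spec.high - spec.low) / 3.92
    label = name or spec.family
    if se == 0.0:
        return PointMass(m)
    var = se * se
    if spec.family == "beta":
        if not (0.0 < m < 1.0):
            raise ParameterError(f"beta mean for {label} must be in (0, 1): {m}")
        nu = m * (1.0 - m) / var - 1.0
        if nu <= 0.0:
            raise ParameterError(
                f"variance too large for a beta fit of {label}: mean {m}, se {se}"
            )
        return BetaSampler(m * nu, (1.0 - m) * nu)
    if spec.family == "gamma":
        if m <= 0.0:
            raise ParameterError(f"gamma mean for {label} must be positive: {m}")
        return GammaSampler((m / se) ** 2, var / m)
    raise ParameterError(f"unsupported family for {label}: {spec.family}")


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSASample:
    """One Monte-Carlo repetition: the incremental cost and QALY pair."""

    iteration: int
    delta_cost: float
    delta_qaly: float


def _sample_transition_matrix(
    base: np.ndarray, n_eff: float, rng: np.random.Generator
) -> np.ndarray:
    """Row-wise Dirichlet draw with concentration = base row x n_eff.

    Structural zeros in a row stay zero; the positive entries of each row are
    drawn jointly so every sampled row is stochastic.
    """
    out = np.zeros_like(base)
    for i, row in enumerate(base):
        pos = row > 0
        out[i, pos] = rng.dirichlet(row[pos] * n_eff)
    return out


def sample_parameters(
    params: ModelParameters, rng: np.random.Generator
) -> ModelParameters:
    """Draw one full parameter set for a PSA iteration.

    Common inputs (transition matrix, utilities, disutility, costs,
    readmission probability) are drawn once and shared by both strategies;
    the strategy-specific event probabilities are drawn independently.
    Draws follow the sorted parameter-name order, then the transition rows,
    so results do not depend on dictionary insertion order.
    """
    sampled = params.copy()
    for name in sorted(params.distributions):
        value = fit_distribution(params.distributions[name], name).rvs(rng)
        setter, _ = _OVERRIDES[name]
        setter(sampled, value)
    if params.sample_transition_matrix:
        sampled.transition_matrix = _sample_transition_matrix(
            np.asarray(params.transition_matrix), params.dirichlet_n_eff, rng
        )
    return sampled


def run_psa(
    params: ModelParameters,
    n_iter: int = 1000,
    seed: int = 0,
    share_arms: bool = False,
) -> list[PSASample]:
    """Monte-Carlo PSA: ``n_iter`` repetitions of draw-and-rerun.

    Every repetition draws the full set of uncertain inputs from the fitted
    distributions, runs both strategies through the cohort pipeline and
    records (delta cost, delta QALYs).  By default each arm's parameter set
    is drawn independently within an iteration, the way a two-arm
    spreadsheet model resamples every input cell per arm; ``share_arms=True``
    instead draws one set and evaluates both strategies on it, preserving
    full between-arm correlation of the common inputs.

    Deterministic given ``seed``; iteration ``i`` always uses the ``i``-th
    spawned substream, so results do not depend on execution order.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    # Fail fast if any distribution cannot be fitted.
    for name, dist in params.distributions.items():
        fit_distribution(dist, name)
    streams = np.random.SeedSequence(seed).spawn(n_iter)
    samples = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        drawn_int = sample_parameters(params, rng)
        drawn_comp = drawn_int if share_arms else sample_parameters(params, rng)
        intervention = evaluate_strategy(drawn_int, "empagliflozin")
        comparator = evaluate_strategy(drawn_comp, "control")
        samples.append(
            PSASample(
                iteration=i,
                delta_cost=intervention.total_cost - comparator.total_cost,
                delta_qaly=intervention.total_qaly - comparator.total_qaly,
            )
        )
    return samples


def psa_frame(samples: Iterable[PSASample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "iteration": s.iteration,
                "delta_cost": s.delta_cost,
                "delta_qaly": s.delta_qaly,
            }
            for s in samples
        ]
    )


def probability_cost_effective(samples: Sequence[PSASample], wtp: float) -> float:
    """Fraction of PSA repetitions with positive net monetary benefit."""
    if not samples:
        raise ParameterError("no PSA samples")
    wins = sum(
        1
        for s in samples
        if net_monetary_benefit(s.delta_cost, s.delta_qaly, wtp) > 0.0
    )
    return wins / len(samples)


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness across a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(samples: Sequence[PSASample], wtp_grid: Sequence[float]) -> CEACCurve:
    """Acceptability curve: at each WTP, the fraction of samples whose net
    monetary benefit is positive (same sample set at every point)."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    probs = np.array([probability_cost_effective(samples, w) for w in grid])
    return CEACCurve(wtp=grid, probability=probs)


# ---------------------------------------------------------------------------
# Scenario engine
# ---------------------------------------------------------------------------

#: Fields a scenario may override; everything else stays at base case.
SCENARIO_FIELDS = frozenset(
    {
        "initial_distribution",
        "empagliflozin_unit_price",
        "empagliflozin_per_cycle",
        "hospitalization_per_event",
        "horizon",
    }
)


@dataclass
class ScenarioSpec:
    """A named, whitelisted set of parameter overrides."""

    name: str
    overrides: dict = field(default_factory=dict)

    def validate(self) -> "ScenarioSpec":
        unknown = set(self.overrides) - SCENARIO_FIELDS
        if unknown:
            raise ParameterError(
                f"scenario {self.name!r}: unknown override(s) {sorted(unknown)}"
            )
        return self


def apply_scenario(params: ModelParameters, scenario: ScenarioSpec) -> ModelParameters:
    scenario.validate()
    out = params.copy()
    ov = scenario.overrides
    if "initial_distribution" in ov:
        out.cohort.initial_distribution = tuple(ov["initial_distribution"])
    if "empagliflozin_unit_price" in ov:
        out.costs.empagliflozin_per_cycle = ov["empagliflozin_unit_price"] * DAYS_PER_CYCLE
    if "empagliflozin_per_cycle" in ov:
        out.costs.empagliflozin_per_cycle = float(ov["empagliflozin_per_cycle"])
    if "hospitalization_per_event" in ov:
        out.costs.hospitalization_per_event = float(ov["hospitalization_per_event"])
    if "horizon" in ov:
        out.cohort.horizon = float(ov["horizon"])
    return out.validate()


def run_scenario(params: ModelParameters, scenario: ScenarioSpec) -> ICERResult:
    """Full pipeline under the scenario's overrides."""
    return base_icer(apply_scenario(params, scenario))


#: Per-event hospitalization cost by hospital level (USD).
HOSPITAL_LEVEL_COSTS = {
    "town": 1029.73,
    "county": 1231.06,
    "municipal": 1783.39,
    "provincial": 1949.55,
    "ministerial": 3336.39,
}

#: National centralized-purchase price of empagliflozin, USD per 10 mg.
NATIONAL_PURCHASE_PRICE = 0.275


def standard_scenarios() -> dict[str, ScenarioSpec]:
    """The published scenario battery: single-class initial NYHA cohorts,
    the national purchase price, the five hospital-level costs, and 10/15/20
    year horizons."""
    scenarios: dict[str, ScenarioSpec] = {}
    for i, cls in enumerate(("nyha1", "nyha2", "nyha3", "nyha4")):
        dist = [0.0] * 4
        dist[i] = 1.0
        scenarios[f"initial_{cls}"] = ScenarioSpec(
            f"initial_{cls}", {"initial_distribution": dist}
        )
    scenarios["purchase_price"] = ScenarioSpec(
        "purchase_price", {"empagliflozin_unit_price": NATIONAL_PURCHASE_PRICE}
    )
    for level, cost in HOSPITAL_LEVEL_COSTS.items():
        scenarios[f"hospital_{level}"] = ScenarioSpec(
            f"hospital_{level}", {"hospitalization_per_event": cost}
        )
    for horizon in (10, 15, 20):
        scenarios[f"horizon_{horizon}y"] = ScenarioSpec(
            f"horizon_{horizon}y", {"horizon": float(horizon)}
        )
    return scenarios
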