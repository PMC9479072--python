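"""Model inputs: base-case values, ranges, distribution families, validation.

All inputs of the cost-utility model live in a single :class:`ModelParameters`
object: per-strategy clinical event probabilities, the shared 3-month NYHA
transition matrix, age-banded background (non-cardiovascular) mortality,
NYHA utilities and the hospitalization disutility, per-cycle costs, the cohort
specification (start age, horizon, cycle length, initial NYHA mix, discount
rate) and the willingness-to-pay thresholds.  The built-in defaults are the
published base case for add-on empagliflozin in HFpEF from the Chinese
healthcare-system perspective; every field can be overridden through a YAML or
JSON configuration file.
"""

from __future__ import annotations

import copy
import dataclasses
import enum
import io
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "EventProbabilities",
    "BackgroundMortality",
    "UtilityInputs",
    "CostInputs",
    "CohortSpec",
    "ParamDistribution",
    "ModelParameters",
    "ParameterError",
    "default_parameters",
    "load_parameters",
    "dump_parameters",
    "rate_to_probability",
    "annual_to_cycle_probability",
]


class ParameterError(ValueError):
    """A model input failed validation; the message names the field."""


class HealthState(enum.IntEnum):
    """The five Markov states: NYHA functional classes I-IV and death.

    Death is absorbing.  Integer values double as row/column indices of the
    full 5x5 transition matrix.
    """

    NYHA1 = 0
    NYHA2 = 1
    NYHA3 = 2
    NYHA4 = 3
    DEAD = 4


#: Alive states in matrix order (NYHA I..IV).
ALIVE_STATES = (
    HealthState.NYHA1,
    HealthState.NYHA2,
    HealthState.NYHA3,
    HealthState.NYHA4,
)

#: Row-sum tolerance for stochastic matrices / probability vectors.
ROW_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# Probability conversions
# ---------------------------------------------------------------------------

def rate_to_probability(S: float, t: float, T: float) -> float:
    """Convert a surviving fraction over duration ``t`` to an event
    probability over duration ``T`` assuming a constant hazard.

    The constant event rate is ``r = -ln(S) / t`` and the probability of at
    least one event in ``T`` is ``P = 1 - exp(-r * T)``.

    Parameters
    ----------
    S : float
        Fraction event-free after duration ``t`` (0 < S <= 1).
    t : float
        Duration over which ``S`` was observed (same unit as ``T``).
    T : float
        Target duration (e.g. one 3-month model cycle).
    """
    if not (0.0 < S <= 1.0):
        raise ParameterError(f"surviving fraction S must be in (0, 1], got {S}")
    if t <= 0 or T <= 0:
        raise ParameterError("durations t and T must be positive")
    r = -math.log(S) / t
    return 1.0 - math.exp(-r * T)


def annual_to_cycle_probability(p_annual: float, cycle_length: float) -> float:
    """Convert an annual probability to a per-cycle probability under a
    constant hazard: ``1 - (1 - p_annual) ** cycle_length``.

    ``cycle_length`` is in years (0.25 for a 3-month cycle).
    """
    if not (0.0 <= p_annual < 1.0):
        raise ParameterError(
            f"annual probability must be in [0, 1), got {p_annual}"
        )
    if cycle_length <= 0:
        raise ParameterError("cycle_length must be positive")
    return 1.0 - (1.0 - p_annual) ** cycle_length


# ---------------------------------------------------------------------------
# Input blocks
# ---------------------------------------------------------------------------

@dataclass
class EventProbabilities:
    """Per-cycle clinical event probabilities for one strategy.

    ``p_cv_death`` and ``p_hosp`` are 3-month probabilities of cardiovascular
    death and of an index hospitalization for heart failure.  ``p_readmit`` is
    the probability of one readmission given an index hospitalization; all
    readmissions are assumed to fall inside the same 3-month cycle.
    """

    p_cv_death: float
    p_hosp: float
    p_readmit: float

    def validate(self, prefix: str = "event_probabilities") -> None:
        for name in ("p_cv_death", "p_hosp", "p_readmit"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{prefix}.{name} out of [0, 1]: {v}")


@dataclass
class BackgroundMortality:
    """Annual non-cardiovascular death probability by age band.

    ``bands`` maps the lower edge of each 5-year age band to the annual
    probability.  Lookup is total: ages below the first band use the first
    band, ages beyond the last band carry the last band's value forward
    (needed for extended-horizon runs).
    """

    bands: dict[int, float] = field(
        default_factory=lambda: {65: 0.002430, 70: 0.003042, 75: 0.004185}
    )

    def annual_probability(self, age: float) -> float:
        edges = sorted(self.bands)
        chosen = edges[0]
        for lo in edges:
            if age >= lo:
                chosen = lo
        return self.bands[chosen]

    def validate(self, prefix: str = "background_mortality") -> None:
        if not self.bands:
            raise ParameterError(f"{prefix}.bands must not be empty")
        prev = 0.0
        for lo in sorted(self.bands):
            p = self.bands[lo]
            if p <= 0.0 or p >= 1.0:
                raise ParameterError(f"{prefix}.bands[{lo}] out of (0, 1): {p}")
            if p < prev:
                raise ParameterError(
                    f"{prefix}.bands[{lo}] decreases with age: {p} < {prev}"
                )
            prev = p


@dataclass
class UtilityInputs:
    """Health-state utilities (annual weights) and hospitalization disutility.

    ``nyha`` holds the utility of NYHA classes I-IV; utilities must be in
    [0, 1] and strictly decreasing with worsening class.
    ``hospitalization_disutility`` (negative) is applied once per
    hospitalization or readmission; see ``ModelParameters.disutility_convention``
    for how it is turned into a QALY decrement.
    """

    nyha: tuple[float, float, float, float] = (0.825, 0.780, 0.650, 0.585)
    hospitalization_disutility: float = -0.1

    def utility(self, state: HealthState) -> float:
        if state == HealthState.DEAD:
            return 0.0
        return self.nyha[int(state)]

    def validate(self, prefix: str = "utilities") -> None:
        if len(self.nyha) != 4:
            raise ParameterError(f"{prefix}.nyha must have 4 entries")
        for i, u in enumerate(self.nyha, start=1):
            if not (0.0 <= u <= 1.0):
                raise ParameterError(f"{prefix}.nyha[{i}] out of [0, 1]: {u}")
        if not all(a > b for a, b in zip(self.nyha, self.nyha[1:])):
            raise ParameterError(
                f"{prefix}.nyha must be strictly decreasing I->IV: {self.nyha}"
            )
        if self.hospitalization_disutility >= 0.0:
            raise ParameterError(
                f"{prefix}.hospitalization_disutility must be negative: "
                f"{self.hospitalization_disutility}"
            )


#: Days of drug supply per 3-month (90-day) cycle, at one 10 mg dose per day.
DAYS_PER_CYCLE = 90


@dataclass
class CostInputs:
    """Per-cycle and per-event costs in USD (converted at 6.4 yuan per USD).

    ``standard_therapy_per_cycle`` accrues to every alive patient in both
    strategies; ``empagliflozin_per_cycle`` (unit price x 90 daily doses)
    accrues additionally under the empagliflozin strategy;
    ``hospitalization_per_event`` applies to each index admission and each
    readmission.
    """

    standard_therapy_per_cycle: float = 131.96
    empagliflozin_per_cycle: float = 0.6625 * DAYS_PER_CYCLE
    hospitalization_per_event: float = 1783.39

    @classmethod
    def with_unit_price(cls, unit_price: float, **kwargs: float) -> "CostInputs":
        """Build costs from the per-10 mg empagliflozin unit price."""
        return cls(empagliflozin_per_cycle=unit_price * DAYS_PER_CYCLE, **kwargs)

    def drug_cost_per_cycle(self, strategy: str) -> float:
        base = self.standard_therapy_per_cycle
        if strategy == "empagliflozin":
            return base + self.empagliflozin_per_cycle
        return base

    def validate(self, prefix: str = "costs") -> None:
        for name in (
            "standard_therapy_per_cycle",
            "empagliflozin_per_cycle",
            "hospitalization_per_event",
        ):
            v = getattr(self, name)
            if v < 0.0:
                raise ParameterError(f"{prefix}.{name} must be nonnegative: {v}")


@dataclass
class CohortSpec:
    """Cohort and simulation settings.

    The initial NYHA distribution is not published; the default emulates the
    EMPEROR-Preserved NYHA II-dominant enrolment mix and is fully
    configurable.
    """

    start_age: float = 66.0
    horizon: float = 10.0
    cycle_length: float = 0.25
    initial_distribution: tuple[float, float, float, float] = (0.0, 0.81, 0.18, 0.01)
    annual_discount_rate: float = 0.05

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))

    def validate(self, prefix: str = "cohort") -> None:
        if self.start_age <= 0:
            raise ParameterError(f"{prefix}.start_age must be positive")
        if self.cycle_length <= 0:
            raise ParameterError(f"{prefix}.cycle_length must be positive")
        n = self.horizon / self.cycle_length
        if self.horizon <= 0 or abs(n - round(n)) > 1e-9:
            raise ParameterError(
                f"{prefix}.horizon must be a positive multiple of cycle_length "
                f"({self.cycle_length}): {self.horizon}"
            )
        if len(self.initial_distribution) != 4:
            raise ParameterError(f"{prefix}.initial_distribution must have 4 entries")
        if any(p < 0 for p in self.initial_distribution):
            raise ParameterError(
                f"{prefix}.initial_distribution has negative entries: "
                f"{self.initial_distribution}"
            )
        if abs(sum(self.initial_distribution) - 1.0) > ROW_SUM_TOL:
            raise ParameterError(
                f"{prefix}.initial_distribution must sum to 1: "
                f"{self.initial_distribution}"
            )
        if not (0.0 <= self.annual_discount_rate <= 0.08):
            raise ParameterError(
                f"{prefix}.annual_discount_rate out of [0, 0.08]: "
                f"{self.annual_discount_rate}"
            )


@dataclass
class ParamDistribution:
    """Distribution family and 95% interval for one uncertain scalar input.

    ``family`` is ``beta`` for probabilities and utilities and ``gamma`` for
    costs (transition-matrix rows are sampled jointly as Dirichlet and are
    handled separately).  ``low``/``high`` are read as a normal-approximate
    95% central interval, so the standard error is ``(high - low) / 3.92``.
    For the (negative) hospitalization disutility the beta is fitted on the
    magnitude and the draw negated.
    """

    family: str
    mean: float
    low: float
    high: float

    def validate(self, prefix: str = "distribution") -> None:
        if self.family not in ("beta", "gamma"):
            raise ParameterError(f"{prefix}.family must be beta or gamma: {self.family}")
        if not (self.low <= self.mean <= self.high):
            raise ParameterError(
                f"{prefix}: low <= mean <= high violated: "
                f"({self.low}, {self.mean}, {self.high})"
            )


#: Base 3-month NYHA transition probabilities conditional on surviving the
#: cycle (rows: from class I..IV, columns: to class I..IV).
DEFAULT_TRANSITION_MATRIX = (
    (0.977, 0.019, 0.004, 0.000),
    (0.008, 0.981, 0.010, 0.001),
    (0.000, 0.034, 0.960, 0.006),
    (0.000, 0.000, 0.055, 0.945),
)

#: Willingness-to-pay thresholds: 1x and 3x China's 2021 GDP per capita (USD).
DEFAULT_WTP = (12652.5, 37957.5)


@dataclass
class ModelParameters:
    """The complete input set for one model run (two strategies).

    ``strategies`` maps the strategy names ``"control"`` and
    ``"empagliflozin"`` to their event probabilities; all other blocks are
    shared.  ``distributions`` carries the one-way ranges / probabilistic
    distribution specs keyed by dotted parameter names (see
    :func:`default_parameters`).
    """

    strategies: dict[str, EventProbabilities]
    transition_matrix: np.ndarray
    mortality: BackgroundMortality
    utilities: UtilityInputs
    costs: CostInputs
    cohort: CohortSpec
    wtp_thresholds: tuple[float, float] = DEFAULT_WTP
    #: "absolute": each hospitalization removes 0.1 QALY outright;
    #: "per_cycle": the utility weight drops by 0.1 for the event's cycle
    #: (QALY loss 0.1 x cycle_length per event).
    disutility_convention: str = "absolute"
    distributions: dict[str, ParamDistribution] = field(default_factory=dict)
    dirichlet_n_eff: float = 1000.0
    sample_transition_matrix: bool = True
    yuan_per_usd: float = 6.4

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)

    # -- access helpers -----------------------------------------------------

    @property
    def strategy_names(self) -> tuple[str, ...]:
        return tuple(self.strategies)

    def events(self, strategy: str) -> EventProbabilities:
        try:
            return self.strategies[strategy]
        except KeyError:
            raise ParameterError(
                f"unknown strategy {strategy!r}; have {sorted(self.strategies)}"
            ) from None

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ModelParameters":
        for required in ("control", "empagliflozin"):
            if required not in self.strategies:
                raise ParameterError(f"strategies must include {required!r}")
        for name, ev in self.strategies.items():
            ev.validate(prefix=f"strategies.{name}")
        tm = self.transition_matrix
        if tm.shape != (4, 4):
            raise ParameterError(f"transition_matrix must be 4x4, got {tm.shape}")
        if np.any(tm < 0) or np.any(tm > 1):
            raise ParameterError("transition_matrix entries must be in [0, 1]")
        sums = tm.sum(axis=1)
        for i, s in enumerate(sums, start=1):
            if abs(s - 1.0) > ROW_SUM_TOL:
                raise ParameterError(
                    f"transition_matrix row {i} (NYHA {i}) sums to {s!r}, not 1"
                )
        self.mortality.validate()
        self.utilities.validate()
        self.costs.validate()
        self.cohort.validate()
        if len(self.wtp_thresholds) != 2 or not (
            0 < self.wtp_thresholds[0] <= self.wtp_thresholds[1]
        ):
            raise ParameterError(
                f"wtp_thresholds must be increasing positive pair: {self.wtp_thresholds}"
            )
        if self.disutility_convention not in ("absolute", "per_cycle"):
            raise ParameterError(
                "disutility_convention must be 'absolute' or 'per_cycle': "
                f"{self.disutility_convention}"
            )
        for key, dist in self.distributions.items():
            dist.validate(prefix=f"distributions.{key}")
        if self.dirichlet_n_eff <= 0:
            raise ParameterError("dirichlet_n_eff must be positive")
        if self.yuan_per_usd <= 0:
            raise ParameterError("yuan_per_usd must be positive")
        return self

    # -- serialization ------------------------------------------------------

    @staticmethod
    def _plain(obj: Any) -> Any:
        """Coerce numpy scalars/containers to YAML-safe builtins."""
        if isinstance(obj, dict):
            return {ModelParameters._plain(k): ModelParameters._plain(v)
                    for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [ModelParameters._plain(v) for v in obj]
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "strategies": {
                name: dataclasses.asdict(ev) for name, ev in self.strategies.items()
            },
            "transition_matrix": self.transition_matrix.tolist(),
            "mortality": {"bands": dict(self.mortality.bands)},
            "utilities": {
                "nyha": list(self.utilities.nyha),
                "hospitalization_disutility": self.utilities.hospitalization_disutility,
            },
            "costs": dataclasses.asdict(self.costs),
            "cohort": {
                "start_age": self.cohort.start_age,
                "horizon": self.cohort.horizon,
                "cycle_length": self.cohort.cycle_length,
                "initial_distribution": list(self.cohort.initial_distribution),
                "annual_discount_rate": self.cohort.annual_discount_rate,
            },
            "wtp_thresholds": list(self.wtp_thresholds),
            "disutility_convention": self.disutility_convention,
            "distributions": {
                key: dataclasses.asdict(dist)
                for key, dist in self.distributions.items()
            },
            "dirichlet_n_eff": self.dirichlet_n_eff,
            "sample_transition_matrix": self.sample_transition_matrix,
            "yuan_per_usd": self.yuan_per_usd,
        }
        return self._plain(d)


# ---------------------------------------------------------------------------
# Defaults (published base case)
# ---------------------------------------------------------------------------

def default_parameters() -> ModelParameters:
    """The published base-case parameter set.

    Clinical event probabilities are the printed 3-month values (derived by
    the source from EMPEROR-Preserved cumulative incidences; kept as printed
    rather than re-derived).  Costs are USD at 6.4 yuan per USD; the
    empagliflozin cycle cost is the $0.6625 per-10 mg national negotiation
    price times 90 daily doses.
    """
    distributions = {
        "p_cv_death.control": ParamDistribution("beta", 0.00975, 0.00877, 0.01072),
        "p_cv_death.empagliflozin": ParamDistribution("beta", 0.00864, 0.00778, 0.00951),
        "p_hosp.control": ParamDistribution("beta", 0.02003, 0.01803, 0.02204),
        "p_hosp.empagliflozin": ParamDistribution("beta", 0.01466, 0.01319, 0.01613),
        "p_readmit": ParamDistribution("beta", 0.417, 0.3753, 0.4587),
        "utility.nyha1": ParamDistribution("beta", 0.825, 0.790, 0.860),
        "utility.nyha2": ParamDistribution("beta", 0.780, 0.750, 0.810),
        "utility.nyha3": ParamDistribution("beta", 0.650, 0.610, 0.690),
        "utility.nyha4": ParamDistribution("beta", 0.585, 0.510, 0.660),
        # Beta fitted on the magnitude; draws are negated.
        "disutility.hospitalization": ParamDistribution("beta", 0.1, 0.08, 0.13),
        "cost.standard_therapy": ParamDistribution("gamma", 131.96, 131.957, 310.832),
        "cost.empagliflozin": ParamDistribution("gamma", 59.625, 47.7, 71.55),
        "cost.hospitalization": ParamDistribution("gamma", 1783.39, 1029.73, 3336.39),
    }
    return ModelParameters(
        strategies={
            "control": EventProbabilities(
                p_cv_death=0.00975, p_hosp=0.02003, p_readmit=0.417
            ),
            "empagliflozin": EventProbabilities(
                p_cv_death=0.00864, p_hosp=0.01466, p_readmit=0.417
            ),
        },
        transition_matrix=np.array(DEFAULT_TRANSITION_MATRIX),
        mortality=BackgroundMortality(),
        utilities=UtilityInputs(),
        costs=CostInputs(),
        cohort=CohortSpec(),
        distributions=distributions,
    ).validate()


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------

def _merge_block(obj: Any, mapping: Mapping[str, Any], prefix: str) -> None:
    """Set dataclass fields from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in mapping.items():
        if key not in names:
            raise ParameterError(f"unknown config key {prefix}.{key}")
        if isinstance(value, list):
            value = tuple(value)
        setattr(obj, key, value)


def load_parameters(config: str | Mapping[str, Any] | None = None) -> ModelParameters:
    """Build validated :class:`ModelParameters` from a configuration.

    ``config`` may be YAML/JSON text, an already-parsed mapping, or ``None``;
    any omitted field falls back to :func:`default_parameters`.  Unknown keys
    are rejected and invalid values raise :class:`ParameterError` naming the
    offending field.
    """
    if config is None:
        data: Mapping[str, Any] = {}
    elif isinstance(config, str):
        parsed = yaml.safe_load(io.StringIO(config))
        data = {} if parsed is None else parsed
    else:
        data = config
    if not isinstance(data, Mapping):
        raise ParameterError(f"config must be a mapping, got {type(data).__name__}")

    params = default_parameters()
    known_top = {
        "strategies",
        "transition_matrix",
        "mortality",
        "utilities",
        "costs",
        "cohort",
        "wtp_thresholds",
        "disutility_convention",
        "distributions",
        "dirichlet_n_eff",
        "sample_transition_matrix",
        "yuan_per_usd",
    }
    for key in data:
        if key not in known_top:
            raise ParameterError(f"unknown config key {key}")

    if "strategies" in data:
        for name, block in data["strategies"].items():
            if name not in params.strategies:
                raise ParameterError(f"unknown config key strategies.{name}")
            _merge_block(params.strategies[name], block, f"strategies.{name}")
    if "transition_matrix" in data:
        params.transition_matrix = np.asarray(data["transition_matrix"], dtype=float)
    if "mortality" in data:
        block = dict(data["mortality"])
        if set(block) - {"bands"}:
            raise ParameterError(
                f"unknown config key mortality.{sorted(set(block) - {'bands'})[0]}"
            )
        if "bands" in block:
            params.mortality.bands = {int(k): float(v) for k, v in block["bands"].items()}
    if "utilities" in data:
        _merge_block(params.utilities, data["utilities"], "utilities")
    if "costs" in data:
        _merge_block(params.costs, data["costs"], "costs")
    if "cohort" in data:
        _merge_block(params.cohort, data["cohort"], "cohort")
    if "wtp_thresholds" in data:
        params.wtp_thresholds = tuple(data["wtp_thresholds"])  # type: ignore[assignment]
    if "disutility_convention" in data:
        params.disutility_convention = data["disutility_convention"]
    if "distributions" in data:
        for key, block in data["distributions"].items():
            params.distributions[key] = ParamDistribution(**block)
    if "dirichlet_n_eff" in data:
        params.dirichlet_n_eff = float(data["dirichlet_n_eff"])
    if "sample_transition_matrix" in data:
        params.sample_transition_matrix = bool(data["sample_transition_matrix"])
    if "yuan_per_usd" in data:
        params.yuan_per_usd = float(data["yuan_per_usd"])

    return params.validate()


def dump_parameters(params: ModelParameters) -> str:
    """Serialize parameters to YAML; round-trips through
    :func:`load_parameters` unchanged."""
    return yaml.safe_dump(params.to_dict(), sort_keys=False)
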