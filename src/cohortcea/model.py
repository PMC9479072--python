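"""Model/Results facade over the cost-utility pipeline.

``CostUtilityModel`` bundles a parameter set with the full analysis surface:
``fit()`` produces a :class:`CEAResults` carrying per-strategy discounted
totals, the incremental comparison and WTP verdicts, with ``summary()``
rendering the familiar base-case table.  Sensitivity analyses, scenarios and
the clinical validation readouts hang off the model object.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import engine, sensitivity
from .compare import ICERResult, compare as compare_strategies, wtp_verdict
from .economics import StrategyResult, evaluate_strategy
from .params import ModelParameters, default_parameters, dump_parameters, load_parameters

__all__ = ["CostUtilityModel", "CEAResults", "ValidationReport"]


@dataclass
class ValidationReport:
    """Clinical face-validity readouts for both strategies.

    ``cv_mortality`` holds cumulative cardiovascular mortality (fraction) at
    the requested month; ``median_survival`` is in years from an
    extended-horizon run (infinite if not reached).
    """

    months: float
    cv_mortality: dict[str, float]
    median_survival: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "months": self.months,
            "cv_mortality": dict(self.cv_mortality),
            "median_survival": dict(self.median_survival),
        }


@dataclass
class CEAResults:
    """Fitted base-case results: strategy totals plus the incremental row."""

    params: ModelParameters
    strategies: dict[str, StrategyResult]
    icer: ICERResult

    @property
    def verdicts(self) -> dict[str, str]:
        gdp = self.params.wtp_thresholds[0]
        return {
            "gdp_rule": wtp_verdict(self.icer, gdp),
        }

    def net_monetary_benefit(self, wtp: float) -> float:
        return self.icer.net_monetary_benefit(wtp)

    def to_dict(self) -> dict:
        return {
            "strategies": {k: v.to_dict() for k, v in self.strategies.items()},
            "incremental": self.icer.to_dict(),
            "verdict": self.verdicts["gdp_rule"],
            "wtp_thresholds": list(self.params.wtp_thresholds),
        }

    def summary(self) -> str:
        """Base-case table: discounted totals, increments, ICER, verdict."""
        lines = [
            "Cost-utility results (discounted)",
            "=" * 64,
            f"{'Strategy':<16}{'Total cost ($)':>16}{'Total QALYs':>12}",
            "-" * 64,
        ]
        for name in ("empagliflozin", "control"):
            r = self.strategies[name]
            lines.append(f"{name:<16}{r.total_cost:>16,.2f}{r.total_qaly:>12.2f}")
        lines += [
            "-" * 64,
            f"Incremental cost   : $ {self.icer.delta_cost:,.2f}",
            f"Incremental QALYs  : {self.icer.delta_qaly:.4f}",
        ]
        if self.icer.icer is not None:
            lines.append(f"ICER               : $ {self.icer.icer:,.2f} per QALY")
        if self.icer.dominance:
            lines.append(f"Dominance          : {self.icer.dominance}")
        wtp1 = self.params.wtp_thresholds[0]
        lines.append(
            f"Verdict (GDP rule) : {self.verdicts['gdp_rule']} "
            f"(1x GDP = $ {wtp1:,.1f})"
        )
        return "\n".join(lines)


class CostUtilityModel:
    """A two-strategy Markov cohort cost-utility model.

    Parameters default to the published empagliflozin-for-HFpEF base case;
    use :meth:`from_config` / :meth:`from_yaml` to override any input.
    """

    def __init__(self, params: ModelParameters | None = None):
        self.params = (params or default_parameters()).validate()

    @classmethod
    def from_config(cls, config: str | Mapping | None) -> "CostUtilityModel":
        return cls(load_parameters(config))

    @classmethod
    def from_yaml(cls, path) -> "CostUtilityModel":
        with open(path) as fh:
            return cls(load_parameters(fh.read()))

    # -- core ---------------------------------------------------------------

    def fit(self, horizon: float | None = None) -> CEAResults:
        strategies = {
            name: evaluate_strategy(self.params, name, horizon=horizon)
            for name in self.params.strategy_names
        }
        icer = compare_strategies(strategies["empagliflozin"], strategies["control"])
        return CEAResults(params=self.params, strategies=strategies, icer=icer)

    # -- sensitivity surface ------------------------------------------------

    def one_way(self, ranges=None) -> list[sensitivity.TornadoEntry]:
        return sensitivity.one_way_dsa(self.params, ranges)

    def run_psa(
        self, n_iter: int = 1000, seed: int = 0, share_arms: bool = False
    ) -> list[sensitivity.PSASample]:
        return sensitivity.run_psa(
            self.params, n_iter=n_iter, seed=seed, share_arms=share_arms
        )

    def ceac(self, samples, wtp_grid: Sequence[float]) -> sensitivity.CEACCurve:
        return sensitivity.ceac(samples, wtp_grid)

    def scenario(self, scenario: sensitivity.ScenarioSpec) -> ICERResult:
        return sensitivity.run_scenario(self.params, scenario)

    def scenario_battery(self) -> dict[str, ICERResult]:
        return {
            name: self.scenario(s)
            for name, s in sensitivity.standard_scenarios().items()
        }

    # -- validation readouts ------------------------------------------------

    def clinical_validation(
        self, months: float = 27.0, extended_horizon: float = 40.0
    ) -> ValidationReport:
        cv = {}
        med = {}
        for name in self.params.strategy_names:
            trace = engine.run_cohort(self.params, name)
            cv[name] = engine.cv_mortality_at(trace, months)
            med[name] = engine.median_survival(
                self.params, name, extended_horizon=extended_horizon
            )
        return ValidationReport(months=months, cv_mortality=cv, median_survival=med)

    # -- misc ---------------------------------------------------------------

    def params_digest(self) -> str:
        return hashlib.sha256(dump_parameters(self.params).encode()).hexdigest()[:16]
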