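"""Incremental cost-effectiveness: ICER, dominance, NMB, WTP verdicts.

The verdict follows the WHO GDP-multiple convention: an ICER below one GDP
per capita per QALY is *very cost-effective*, between one and three times is
*cost-effective*, at or above three times is *not cost-effective*.
Boundary conventions (weak inequalities for dominance; the 3xGDP boundary
closed on the not-cost-effective side) are fixed here and documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

from .economics import StrategyResult

__all__ = [
    "ICERResult",
    "compare",
    "wtp_verdict",
    "net_monetary_benefit",
    "VERY_COST_EFFECTIVE",
    "COST_EFFECTIVE",
    "NOT_COST_EFFECTIVE",
]

VERY_COST_EFFECTIVE = "very cost-effective"
COST_EFFECTIVE = "cost-effective"
NOT_COST_EFFECTIVE = "not cost-effective"


@dataclass
class ICERResult:
    """Incremental comparison of an intervention against a comparator.

    ``icer`` is delta-cost over delta-QALY when the ratio is meaningful
    (delta-QALY nonzero) and ``None`` otherwise; ``dominance`` is
    ``"dominant"`` (cheaper, at least as effective), ``"dominated"``
    (costlier, at most as effective) or ``None``.
    """

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str | None

    def net_monetary_benefit(self, wtp: float) -> float:
        return net_monetary_benefit(self.delta_cost, self.delta_qaly, wtp)

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "comparator": self.comparator,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
        }


def compare(intervention: StrategyResult, comparator: StrategyResult) -> ICERResult:
    """Incremental cost, incremental QALYs and the ICER/dominance flag.

    Dominance uses weak inequalities: dominant if the intervention costs no
    more and yields no fewer QALYs (not both equal), dominated for the
    reverse.  Equal costs with a QALY gain give an ICER of 0 (and a dominant
    flag).  Exact equality of both increments is degenerate and raises.
    """
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qaly - comparator.total_qaly
    if dc == 0.0 and de == 0.0:
        raise ValueError(
            "strategies have identical cost and QALYs; ICER is undefined"
        )
    dominance = None
    if dc <= 0.0 and de >= 0.0:
        dominance = "dominant"
    elif dc >= 0.0 and de <= 0.0:
        dominance = "dominated"
    icer = dc / de if de != 0.0 else None
    return ICERResult(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qaly=de,
        icer=icer,
        dominance=dominance,
    )


def wtp_verdict(result: ICERResult, gdp_per_capita: float) -> str:
    """Classify a comparison against the WHO GDP-multiple thresholds.

    Dominant strategies are very cost-effective and dominated ones are not,
    regardless of the ratio; otherwise the ICER is compared against 1x and 3x
    GDP per capita (the 3x boundary itself counts as not cost-effective).
    """
    if gdp_per_capita <= 0:
        raise ValueError("gdp_per_capita must be positive")
    if result.dominance == "dominant":
        return VERY_COST_EFFECTIVE
    if result.dominance == "dominated":
        return NOT_COST_EFFECTIVE
    icer = result.icer
    if icer is None:
        raise ValueError("ICER undefined and no dominance flag; cannot classify")
    if icer < gdp_per_capita:
        return VERY_COST_EFFECTIVE
    if icer < 3.0 * gdp_per_capita:
        return COST_EFFECTIVE
    return NOT_COST_EFFECTIVE


def net_monetary_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """``wtp * delta_qaly - delta_cost``; positive iff the intervention is
    cost-effective at that willingness to pay (for a QALY gain)."""
    if wtp < 0:
        raise ValueError("wtp must be nonnegative")
    return wtp * delta_qaly - delta_cost
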