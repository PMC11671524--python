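"""Incremental cost-effectiveness statistics.

Turns per-strategy totals into the incremental cost-effectiveness ratio
(ICER, ``delta cost / delta QALY``), average cost-effectiveness ratios,
net monetary benefit (NMB, ``WTP * QALY - cost``) and a dominance label
when the ICER is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import ModelConfig, MarkovTrace, run_trace

__all__ = [
    "StrategyTotals",
    "CEResult",
    "compute_icer",
    "ce_ratio",
    "net_monetary_benefit",
    "evaluate",
]

QALY_TIE_TOL = 1e-12


@dataclass(frozen=True)
class StrategyTotals:
    """Discounted totals for one arm, optionally with per-state splits."""

    name: str
    total_cost: float
    total_qaly: float
    per_state_cost: dict[str, float] = field(default_factory=dict)
    per_state_qaly: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_trace(cls, trace: MarkovTrace) -> "StrategyTotals":
        return cls(
            name=trace.strategy,
            total_cost=trace.discounted_cost,
            total_qaly=trace.discounted_qaly,
            per_state_cost=dict(trace.per_state_cost),
            per_state_qaly=dict(trace.per_state_qaly),
        )


@dataclass(frozen=True)
class CEResult:
    """Two-arm incremental economics.

    ``icer`` is None when the incremental QALYs are (numerically) zero or
    when one arm dominates; ``dominance`` then carries the label
    ("dominant" = intervention cheaper and more effective, "dominated" =
    dearer and less effective, "undefined" = zero QALY difference).
    """

    intervention: StrategyTotals
    comparator: StrategyTotals
    incremental_cost: float
    incremental_qaly: float
    icer: Optional[float]
    dominance: Optional[str]
    wtp: float
    nmb_intervention: float
    nmb_comparator: float

    @property
    def incremental_nmb(self) -> float:
        return self.nmb_intervention - self.nmb_comparator

    @property
    def cost_effective(self) -> bool:
        """Is the intervention cost-effective at the configured WTP?
        Strict inequality: an incremental NMB of exactly zero counts no."""
        return self.incremental_nmb > 0.0

    def ce_ratios(self) -> dict[str, float]:
        return {
            t.name: ce_ratio(t.total_cost, t.total_qaly)
            for t in (self.intervention, self.comparator)
        }


def ce_ratio(total_cost: float, total_qaly: float) -> float:
    """Average cost-effectiveness ratio, cost per QALY."""
    if total_qaly <= 0:
        raise ValueError(f"total_qaly must be positive, got {total_qaly}")
    return total_cost / total_qaly


def net_monetary_benefit(total_cost: float, total_qaly: float, wtp: float) -> float:
    """``wtp * total_qaly - total_cost``; higher is better at that WTP."""
    if wtp < 0:
        raise ValueError(f"wtp must be non-negative, got {wtp}")
    return wtp * total_qaly - total_cost


def compute_icer(
    intervention: StrategyTotals,
    comparator: StrategyTotals,
    wtp: float = 0.0,
) -> CEResult:
    """Incremental cost-effectiveness of the intervention over the comparator.

    The ICER is reported only when the intervention gains QALYs at extra
    cost (or loses both, the other trade-off quadrant); strict dominance
    and zero QALY differences yield a label instead of a ratio.
    """
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly

    icer: Optional[float] = None
    dominance: Optional[str] = None
    if abs(d_qaly) <= QALY_TIE_TOL:
        dominance = "undefined"
    elif d_qaly > 0 and d_cost < 0:
        dominance = "dominant"
    elif d_qaly < 0 and d_cost > 0:
        dominance = "dominated"
    else:
        icer = d_cost / d_qaly

    return CEResult(
        intervention=intervention,
        comparator=comparator,
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        icer=icer,
        dominance=dominance,
        wtp=wtp,
        nmb_intervention=net_monetary_benefit(
            intervention.total_cost, intervention.total_qaly, wtp
        ),
        nmb_comparator=net_monetary_benefit(
            comparator.total_cost, comparator.total_qaly, wtp
        ),
    )


def evaluate(
    config: ModelConfig,
    intervention: Optional[str] = None,
    comparator: Optional[str] = None,
) -> CEResult:
    """Run both arms' traces under one configuration and compare them.

    Arm names default to ``config.intervention`` / ``config.comparator``,
    falling back to the first two strategies in declaration order.
    """
    names = [s.name for s in config.strategies]
    if len(names) < 2:
        raise ValueError("evaluation needs two strategies")
    iv = intervention or config.intervention or names[0]
    cp = comparator or config.comparator or names[1]
    if iv == cp:
        raise ValueError("intervention and comparator must differ")
    t_iv = StrategyTotals.from_trace(run_trace(config, iv))
    t_cp = StrategyTotals.from_trace(run_trace(config, cp))
    return compute_icer(t_iv, t_cp, wtp=config.wtp)
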