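"""Markov cohort state-transition model for cost-effectiveness analysis.

The model tracks a hypothetical cohort across mutually exclusive health
states (in the gallbladder-cancer application: progression-free survival,
progressive disease, and death) in discrete cycles.  Per-cycle transition
probabilities are either supplied directly or derived from median
time-to-event estimates under an exponential (constant-hazard) assumption.
Costs and quality-adjusted life years (QALYs) are accrued per cycle with
optional half-cycle correction and discounted back to present value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "StateSpec",
    "TransitionMatrix",
    "StrategyParams",
    "ModelConfig",
    "MarkovTrace",
    "median_to_cycle_prob",
    "build_transition_matrix",
    "discount_factor",
    "expected_ae_cycle_cost",
    "run_trace",
]

ROW_SUM_TOL = 1e-9


def median_to_cycle_prob(median: float, cycle_length: float = 1.0) -> float:
    """Per-cycle event probability implied by a median time-to-event.

    Assumes a constant hazard, so the survival curve is exponential and
    half the cohort has had the event by the median.  The per-cycle
    probability is ``p = 1 - exp(-cycle_length * ln 2 / median)``,
    equivalently ``1 - 0.5 ** (cycle_length / median)``.

    Parameters
    ----------
    median : float
        Median time to event, in the same time unit as ``cycle_length``
        (months in the gallbladder-cancer model).
    cycle_length : float
        Cycle length in the same unit, default one month.
    """
    if median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    if cycle_length <= 0:
        raise ValueError(f"cycle_length must be positive, got {cycle_length}")
    return 1.0 - 0.5 ** (cycle_length / median)


def discount_factor(
    cycle: int | np.ndarray,
    annual_rate: float,
    cycle_length: float = 1.0,
    compounding: Literal["annual", "monthly"] = "annual",
) -> float | np.ndarray:
    """Present-value factor for rewards accrued in a given cycle.

    ``annual`` compounding applies the rate in whole-year steps,
    ``(1+r)**(-floor(cycle * cycle_length / 12))`` — the convention of
    standard decision-tree software, so the first model year is
    undiscounted.  ``monthly`` compounding discounts continuously in
    fractional years, ``(1+r)**(-cycle * cycle_length / 12)``.
    """
    if annual_rate < 0:
        raise ValueError(f"annual_rate must be non-negative, got {annual_rate}")
    years = np.asarray(cycle, dtype=float) * cycle_length / 12.0
    if compounding == "annual":
        years = np.floor(years)
    elif compounding != "monthly":
        raise ValueError(f"unknown compounding {compounding!r}")
    out = (1.0 + annual_rate) ** (-years)
    return out if isinstance(cycle, np.ndarray) else float(out)


def expected_ae_cycle_cost(
    ae_probs: Mapping[str, float], ae_unit_costs: Mapping[str, float]
) -> float:
    """Expected per-cycle cost of adverse events, ``sum_i p_i * c_i``.

    Events absent from ``ae_unit_costs`` cost nothing.  An empty mapping
    yields 0, which lets an aggregate per-cycle figure be used directly
    instead (as in the published parameter table, which prints only the
    aggregate 1.26 USD/month for the intervention arm).
    """
    total = 0.0
    for name, p in ae_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {name!r} outside [0, 1]: {p}")
        c = ae_unit_costs.get(name, 0.0)
        if c < 0:
            raise ValueError(f"cost for {name!r} is negative: {c}")
        total += p * c
    return total


class StateSpec(BaseModel):
    """A named health state with a QALY weight and an absorbing flag."""

    name: str
    utility: float = Field(ge=0.0, le=1.0)
    absorbing: bool = False


class TransitionMatrix(BaseModel):
    """Row-stochastic per-cycle transition probabilities.

    Rows are from-states, columns to-states, in the order of ``labels``.
    """

    labels: tuple[str, ...]
    probs: tuple[tuple[float, ...], ...]

    @model_validator(mode="after")
    def _check(self) -> "TransitionMatrix":
        n = len(self.labels)
        if len(self.probs) != n or any(len(row) != n for row in self.probs):
            raise ValueError("probs must be square and match labels")
        for label, row in zip(self.labels, self.probs):
            if any(p < 0.0 or p > 1.0 for p in row):
                raise ValueError(f"row {label!r} has entries outside [0, 1]: {row}")
            if abs(sum(row) - 1.0) > ROW_SUM_TOL:
                raise ValueError(f"row {label!r} sums to {sum(row)}, not 1")
        return self

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)

    def entry(self, frm: str, to: str) -> float:
        return self.probs[self.labels.index(frm)][self.labels.index(to)]

    def with_entry(self, frm: str, to: str, value: float) -> "TransitionMatrix":
        """Return a copy with one off-diagonal entry replaced and the
        from-state self-loop adjusted to keep the row stochastic."""
        if frm == to:
            raise ValueError("set exit probabilities, not the self-loop")
        i, j = self.labels.index(frm), self.labels.index(to)
        row = list(self.probs[i])
        row[j] = value
        row[i] = 0.0
        resid = 1.0 - sum(row)
        if resid < -ROW_SUM_TOL or value < 0.0 or value > 1.0:
            raise ValueError(
                f"transition {frm}->{to}={value} makes row non-stochastic "
                f"(residual self-loop {resid:.6g})"
            )
        row[i] = max(resid, 0.0)
        probs = [list(r) for r in self.probs]
        probs[i] = row
        return TransitionMatrix(labels=self.labels, probs=tuple(tuple(r) for r in probs))


def build_transition_matrix(
    median_pfs: float,
    median_os: float,
    cycle_length: float = 1.0,
    labels: Sequence[str] = ("PFS", "PD", "DEATH"),
    rounded: bool = False,
) -> TransitionMatrix:
    """Three-state transition matrix from median PFS and OS.

    Progression risk comes from the PFS median, death-from-PFS risk from
    the OS median, and death-from-progression risk from the
    post-progression survival ``median_os - median_pfs``; self-loops are
    residuals and the death row is absorbing.  With ``rounded`` the three
    exit probabilities are rounded to 2 decimals before the residuals are
    formed, matching a parameter table printed at that precision.
    """
    if not median_os > median_pfs > 0:
        raise ValueError(
            f"need median_os > median_pfs > 0, got OS={median_os}, PFS={median_pfs} "
            "(post-progression survival would be undefined)"
        )
    p_prog = median_to_cycle_prob(median_pfs, cycle_length)
    p_death_pfs = median_to_cycle_prob(median_os, cycle_length)
    p_death_pd = median_to_cycle_prob(median_os - median_pfs, cycle_length)
    if rounded:
        p_prog, p_death_pfs, p_death_pd = (
            round(p_prog, 2),
            round(p_death_pfs, 2),
            round(p_death_pd, 2),
        )
    if p_prog + p_death_pfs > 1.0:
        raise ValueError(
            f"PFS exit probabilities sum to {p_prog + p_death_pfs:.4f} > 1; "
            "cycle length too long for these medians"
        )
    pfs, pd_, death = labels
    return TransitionMatrix(
        labels=tuple(labels),
        probs=(
            (1.0 - p_prog - p_death_pfs, p_prog, p_death_pfs),
            (0.0, 1.0 - p_death_pd, p_death_pd),
            (0.0, 0.0, 1.0),
        ),
    )


class StrategyParams(BaseModel):
    """One treatment arm: survival medians, per-cycle costs and transitions.

    ``cycle_costs`` maps state label to cost per cycle (USD/month at the
    default one-month cycle); ``ae_cost_per_cycle`` is an adverse-event
    cost added to the treatment (initial) state.  The transition matrix is
    either given explicitly or derived from the medians.
    """

    name: str
    median_pfs: Optional[float] = None
    median_os: Optional[float] = None
    cycle_costs: dict[str, float] = Field(default_factory=dict)
    ae_cost_per_cycle: float = 0.0
    transition: Optional[TransitionMatrix] = None
    cost_components: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "StrategyParams":
        if self.median_pfs is not None or self.median_os is not None:
            if self.median_pfs is None or self.median_os is None:
                raise ValueError("supply both medians or neither")
            if not self.median_os > self.median_pfs > 0:
                raise ValueError(
                    f"need median_os > median_pfs > 0, got "
                    f"{self.median_os} / {self.median_pfs}"
                )
        if self.transition is None and self.median_pfs is None:
            raise ValueError("strategy needs medians or an explicit transition matrix")
        if any(c < 0 for c in self.cycle_costs.values()) or self.ae_cost_per_cycle < 0:
            raise ValueError("costs must be non-negative")
        return self

    def resolve_transition(
        self,
        labels: Sequence[str],
        cycle_length: float = 1.0,
        use_rounded: bool = False,
    ) -> TransitionMatrix:
        """The matrix actually used by the trace: explicit if given, else
        derived from the medians (optionally rounded to 2 decimals)."""
        if self.transition is not None:
            if tuple(self.transition.labels) != tuple(labels):
                raise ValueError(
                    f"transition labels {self.transition.labels} do not match "
                    f"model states {tuple(labels)}"
                )
            return self.transition
        return build_transition_matrix(
            self.median_pfs, self.median_os, cycle_length, labels, rounded=use_rounded
        )


class ModelConfig(BaseModel):
    """Full model configuration: states, arms, time and economic settings."""

    states: list[StateSpec]
    strategies: list[StrategyParams]
    cycle_length: float = Field(default=1.0, gt=0.0, description="months per cycle")
    horizon: int = Field(default=120, ge=1, description="number of cycles")
    annual_discount: float = Field(default=0.05, ge=0.0, le=1.0)
    wtp: float = Field(default=37697.0, ge=0.0, description="USD per QALY")
    half_cycle_correction: bool = True
    discounting: Literal["annual", "monthly"] = "annual"
    use_rounded_table1: bool = False
    initial_state: str = "PFS"
    intervention: Optional[str] = None
    comparator: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        labels = [s.name for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate state names")
        if self.initial_state not in labels:
            raise ValueError(f"initial_state {self.initial_state!r} not among states")
        if len(self.strategies) < 1:
            raise ValueError("at least one strategy required")
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strategy names")
        for s in self.strategies:
            unknown = set(s.cycle_costs) - set(labels)
            if unknown:
                raise ValueError(f"strategy {s.name!r} costs unknown states {unknown}")
        for arm in (self.intervention, self.comparator):
            if arm is not None and arm not in names:
                raise ValueError(f"unknown strategy {arm!r}")
        return self

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def utilities(self) -> np.ndarray:
        return np.array([s.utility for s in self.states])

    def get_strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def get_state(self, name: str) -> StateSpec:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(f"no state named {name!r}")

    def resolved(self) -> "ModelConfig":
        """Deep copy with every strategy's transition matrix made explicit,
        so sensitivity analyses can address individual entries."""
        cfg = self.model_copy(deep=True)
        for s in cfg.strategies:
            s.transition = s.resolve_transition(
                cfg.state_labels, cfg.cycle_length, cfg.use_rounded_table1
            )
        return cfg


@dataclass
class MarkovTrace:
    """Cohort trace with discounted cost and QALY accrual.

    ``occupancy`` has ``horizon + 1`` rows (cycle boundaries 0..H);
    ``membership`` the per-cycle effective state membership used for
    accrual (half-cycle corrected when enabled); ``discount`` the
    per-cycle present-value factors.
    """

    labels: tuple[str, ...]
    occupancy: np.ndarray
    membership: np.ndarray
    discount: np.ndarray
    per_state_cost: dict[str, float]
    per_state_qaly: dict[str, float]
    strategy: str = ""

    @property
    def discounted_cost(self) -> float:
        return float(sum(self.per_state_cost.values()))

    @property
    def discounted_qaly(self) -> float:
        return float(sum(self.per_state_qaly.values()))

    def discounted_person_time(self, state: str) -> float:
        """Discounted effective cycles spent in ``state`` — the linear
        weight multiplying any per-cycle cost attached to that state."""
        if state not in self.labels:
            raise KeyError(f"no state named {state!r}")
        j = self.labels.index(state)
        return float(np.sum(self.membership[:, j] * self.discount))

    def to_frame(self) -> pd.DataFrame:
        """Per-cycle table: occupancy, discounted cost and QALY accrual."""
        h = self.membership.shape[0]
        out = pd.DataFrame(
            self.occupancy[1:], columns=[f"occ_{s}" for s in self.labels]
        )
        out.insert(0, "cycle", np.arange(1, h + 1))
        out["discount"] = self.discount
        return out


def run_trace(config: ModelConfig, strategy: StrategyParams | str) -> MarkovTrace:
    """Run the discounted cohort trace for one arm.

    The whole cohort starts in ``config.initial_state``; occupancy evolves
    by left-multiplication with the transition matrix each cycle.  Accrual
    for cycle ``t`` (t = 1..horizon) uses the half-cycle-corrected
    membership ``(occ[t-1] + occ[t]) / 2`` when enabled, otherwise the
    end-of-cycle occupancy; QALYs weight membership by state utility and
    cycle length in years, costs by the per-cycle state cost (plus the
    adverse-event cost in the treatment state).  Both are discounted per
    ``config.discounting``.
    """
    if isinstance(strategy, str):
        strategy = config.get_strategy(strategy)
    labels = config.state_labels
    tm = strategy.resolve_transition(
        labels, config.cycle_length, config.use_rounded_table1
    )
    P = tm.as_array()
    h = config.horizon
    n = len(labels)

    occ = np.zeros((h + 1, n))
    occ[0, labels.index(config.initial_state)] = 1.0
    for t in range(1, h + 1):
        occ[t] = occ[t - 1] @ P

    membership = (occ[:-1] + occ[1:]) / 2.0 if config.half_cycle_correction else occ[1:]
    cycles = np.arange(1, h + 1)
    df = discount_factor(
        cycles, config.annual_discount, config.cycle_length, config.discounting
    )

    costs = np.array([strategy.cycle_costs.get(s, 0.0) for s in labels])
    costs[labels.index(config.initial_state)] += strategy.ae_cost_per_cycle
    utils = config.utilities

    disc_membership = membership * df[:, None]
    per_state_cost = dict(zip(labels, (disc_membership * costs).sum(axis=0)))
    qaly_per_cycle_year = utils * config.cycle_length / 12.0
    per_state_qaly = dict(zip(labels, (disc_membership * qaly_per_cycle_year).sum(axis=0)))

    return MarkovTrace(
        labels=labels,
        occupancy=occ,
        membership=membership,
        discount=np.asarray(df),
        per_state_cost={k: float(v) for k, v in per_state_cost.items()},
        per_state_qaly={k: float(v) for k, v in per_state_qaly.items()},
        strategy=strategy.name,
    )
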