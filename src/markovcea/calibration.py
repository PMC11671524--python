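"""Back-solving per-cycle costs from published per-state totals.

The published cost table prints discounted per-state totals but not every
per-cycle input (the progression-free-state drug-acquisition cost is
absent).  Because the total cost attributed to a state is exactly linear
in its per-cycle cost — the slope being the discounted, half-cycle
corrected person-time spent there — the missing input can be recovered by
a single division.  This module performs that inversion and audits a
fixture's internal consistency against the printed result table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .economics import StrategyTotals, compute_icer, ce_ratio
from .model import MarkovTrace, ModelConfig, run_trace

__all__ = [
    "CalibrationProblem",
    "CellCheck",
    "ConsistencyReport",
    "discounted_person_time",
    "calibrate_cycle_cost",
    "validate_fixture",
]


@dataclass(frozen=True)
class CalibrationProblem:
    """Solve for the per-cycle cost of one state in one arm.

    ``target_total`` is the published discounted total for that state;
    ``known_components`` the sum of the printed per-cycle pieces (tests,
    hospitalisation, adverse events), used only to sanity-check that the
    residual drug component is non-negative.
    """

    strategy: str
    state: str
    target_total: float
    known_components: float = 0.0


def discounted_person_time(trace: MarkovTrace, state: str) -> float:
    """Discounted effective cycles spent in ``state``.

    This is the linear weight multiplying any per-cycle cost attached to
    the state: total state cost = per-cycle cost × this value.
    """
    return trace.discounted_person_time(state)


def calibrate_cycle_cost(problem: CalibrationProblem, trace: MarkovTrace) -> float:
    """Per-cycle cost that reproduces the target total exactly.

    An exact linear inversion — no iteration.  Plugging the solved cost
    back into the trace reproduces ``target_total`` to float precision.
    """
    pt = discounted_person_time(trace, problem.state)
    if pt <= 0.0:
        raise ValueError(
            f"state {problem.state!r} accrues no person-time in strategy "
            f"{problem.strategy!r}; cannot calibrate"
        )
    solved = problem.target_total / pt
    if solved < problem.known_components:
        raise ValueError(
            f"solved cost {solved:.4f} below known components "
            f"{problem.known_components:.4f} (negative residual)"
        )
    return solved


@dataclass(frozen=True)
class CellCheck:
    """One audited cell: recomputed vs printed, with its tolerance."""

    cell: str
    computed: float
    printed: float
    tolerance: float
    relative: bool

    @property
    def deviation(self) -> float:
        return self.computed - self.printed

    @property
    def relative_deviation(self) -> float:
        return self.deviation / self.printed if self.printed != 0 else float("inf")

    @property
    def ok(self) -> bool:
        err = abs(self.relative_deviation) if self.relative else abs(self.deviation)
        return err <= self.tolerance


@dataclass
class ConsistencyReport:
    """All audited cells plus convenience accessors."""

    checks: list[CellCheck] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.ok for c in self.checks)

    def failed(self) -> list[CellCheck]:
        return [c for c in self.checks if not c.ok]

    def as_dict(self) -> dict[str, dict[str, float | bool]]:
        return {
            c.cell: {
                "computed": c.computed,
                "printed": c.printed,
                "deviation": c.deviation,
                "relative_deviation": c.relative_deviation,
                "ok": c.ok,
            }
            for c in self.checks
        }

    def to_text(self) -> str:
        lines = [f"{'cell':42s} {'computed':>14s} {'printed':>12s} {'dev':>10s}  ok"]
        for c in self.checks:
            lines.append(
                f"{c.cell:42s} {c.computed:14.4f} {c.printed:12.4f} "
                f"{c.deviation:10.4f}  {'yes' if c.ok else 'NO'}"
            )
        return "\n".join(lines)


# default audit tolerances: QALY cells are absolute (the printed table has
# 2 decimals); cost cells are relative — 1% where an input was calibrated
# against the same table, 3% for the progressed-disease cells whose printed
# per-cycle costs do not exactly reproduce the printed totals.
QALY_ABS_TOL = 0.005
CAL_COST_REL_TOL = 0.01
PD_COST_REL_TOL = 0.03


def validate_fixture(
    config: ModelConfig,
    table3: Mapping[str, Mapping[str, float]],
    pd_state: str = "PD",
) -> ConsistencyReport:
    """Recompute every published result cell from the fixture and compare.

    ``table3`` maps strategy name to printed cells with keys among
    ``pfs_cost, pd_cost, total_cost, pfs_qaly, pd_qaly, total_qaly,
    ce_ratio`` plus top-level-per-intervention ``incremental_cost,
    incremental_qaly, icer`` on the intervention arm.  Report-only: cells
    outside tolerance are flagged, never raised.
    """
    report = ConsistencyReport()
    totals: dict[str, StrategyTotals] = {}
    init = config.initial_state

    for strat_name, cells in table3.items():
        trace = run_trace(config, strat_name)
        st = StrategyTotals.from_trace(trace)
        totals[strat_name] = st

        def add(cell: str, computed: float, printed: float, tol: float, rel: bool) -> None:
            report.checks.append(CellCheck(f"{strat_name}.{cell}", computed, printed, tol, rel))

        if "pfs_cost" in cells:
            add("pfs_cost", st.per_state_cost[init], cells["pfs_cost"], CAL_COST_REL_TOL, True)
        if "pd_cost" in cells:
            add("pd_cost", st.per_state_cost[pd_state], cells["pd_cost"], PD_COST_REL_TOL, True)
        if "total_cost" in cells:
            add("total_cost", st.total_cost, cells["total_cost"], CAL_COST_REL_TOL, True)
        if "pfs_qaly" in cells:
            add("pfs_qaly", st.per_state_qaly[init], cells["pfs_qaly"], QALY_ABS_TOL, False)
        if "pd_qaly" in cells:
            add("pd_qaly", st.per_state_qaly[pd_state], cells["pd_qaly"], QALY_ABS_TOL, False)
        if "total_qaly" in cells:
            add("total_qaly", st.total_qaly, cells["total_qaly"], QALY_ABS_TOL, False)
        if "ce_ratio" in cells:
            add(
                "ce_ratio",
                ce_ratio(st.total_cost, st.total_qaly),
                cells["ce_ratio"],
                PD_COST_REL_TOL,
                True,
            )

    iv, cp = config.intervention, config.comparator
    if iv in totals and cp in totals:
        res = compute_icer(totals[iv], totals[cp], wtp=config.wtp)
        cells = table3[iv]
        if "incremental_cost" in cells:
            report.checks.append(
                CellCheck(
                    f"{iv}.incremental_cost",
                    res.incremental_cost,
                    cells["incremental_cost"],
                    CAL_COST_REL_TOL,
                    True,
                )
            )
        if "incremental_qaly" in cells:
            report.checks.append(
                CellCheck(
                    f"{iv}.incremental_qaly",
                    res.incremental_qaly,
                    cells["incremental_qaly"],
                    QALY_ABS_TOL,
                    False,
                )
            )
        if "icer" in cells and res.icer is not None:
            # the printed ICER is a quotient of cells rounded to 2 decimals,
            # so the full-precision recomputation carries both cost and
            # rounding error; audited at the loose relative tolerance
            report.checks.append(
                CellCheck(f"{iv}.icer", res.icer, cells["icer"], PD_COST_REL_TOL, True)
            )
    return report
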