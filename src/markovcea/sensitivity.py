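"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic sensitivity analysis (DSA) re-runs the model with a
single parameter at its low and high bound and reports the ICER spread,
ready for a tornado diagram.  Probabilistic sensitivity analysis (PSA)
jointly samples all uncertain parameters — Beta distributions for
probabilities and utilities, Gamma for costs, method of moments with the
stated range read as mean ± 1.96 SD — re-runs both arms per iteration and
summarises the incremental cost/QALY cloud as a cost-effectiveness
acceptability curve (CEAC).

Parameters are addressed by dotted paths into the model configuration:

- ``annual_discount``
- ``states.<STATE>.utility``
- ``strategies.<ARM>.cycle_costs.<STATE>``
- ``strategies.<ARM>.ae_cost_per_cycle``
- ``strategies.<ARM>.transition.<FROM>.<TO>`` (off-diagonal entry; the
  from-state self-loop absorbs the change to keep the row stochastic)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .economics import CEResult, evaluate
from .model import ModelConfig

__all__ = [
    "DSASpec",
    "TornadoEntry",
    "ParameterDistribution",
    "PSASpec",
    "PSAResult",
    "get_parameter",
    "set_parameter",
    "default_dsa_specs",
    "one_way_dsa",
    "default_psa_ranges",
    "build_psa_distributions",
    "run_psa",
    "ceac",
]


# ---------------------------------------------------------------------------
# parameter paths


def _resolve(config: ModelConfig, path: str):
    """Return (kind, holder, key) for a dotted parameter path."""
    parts = path.split(".")
    try:
        if parts == ["annual_discount"] or parts == ["wtp"]:
            return "config", config, parts[0]
        if len(parts) == 3 and parts[0] == "states" and parts[2] == "utility":
            return "utility", config.get_state(parts[1]), "utility"
        if len(parts) == 4 and parts[0] == "strategies" and parts[2] == "cycle_costs":
            strat = config.get_strategy(parts[1])
            if parts[3] not in strat.cycle_costs:
                raise KeyError(f"strategy {parts[1]!r} has no cost for state {parts[3]!r}")
            return "cost", strat, parts[3]
        if len(parts) == 3 and parts[0] == "strategies" and parts[2] == "ae_cost_per_cycle":
            return "ae_cost", config.get_strategy(parts[1]), "ae_cost_per_cycle"
        if len(parts) == 5 and parts[0] == "strategies" and parts[2] == "transition":
            strat = config.get_strategy(parts[1])
            if strat.transition is None:
                raise KeyError(
                    f"strategy {parts[1]!r} has no explicit transition matrix; "
                    "use ModelConfig.resolved() first"
                )
            return "transition", strat, (parts[3], parts[4])
    except KeyError as exc:
        raise KeyError(f"cannot resolve parameter path {path!r}: {exc}") from exc
    raise KeyError(f"cannot resolve parameter path {path!r}")


def get_parameter(config: ModelConfig, path: str) -> float:
    """Read one scalar model parameter by dotted path."""
    kind, holder, key = _resolve(config, path)
    if kind == "transition":
        return holder.transition.entry(*key)
    if kind == "cost":
        return holder.cycle_costs[key]
    return getattr(holder, key)


def set_parameter(config: ModelConfig, path: str, value: float) -> ModelConfig:
    """Return a deep copy of ``config`` with one scalar replaced.

    Transition entries go through the row-renormalising setter; a value
    that would break row-stochasticity (or a utility outside [0, 1])
    raises with the offending path named.
    """
    cfg = config.model_copy(deep=True)
    kind, holder, key = _resolve(cfg, path)
    try:
        if kind == "transition":
            holder.transition = holder.transition.with_entry(key[0], key[1], value)
        elif kind == "cost":
            if value < 0:
                raise ValueError(f"cost must be non-negative, got {value}")
            holder.cycle_costs[key] = value
        elif kind == "utility":
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"utility must lie in [0, 1], got {value}")
            holder.utility = value
        else:
            setattr(holder, key, value)
            cfg.model_validate(cfg.model_dump())
    except (ValueError, KeyError) as exc:
        raise ValueError(f"invalid value for parameter {path!r}: {exc}") from exc
    return cfg


# ---------------------------------------------------------------------------
# one-way DSA


@dataclass(frozen=True)
class DSASpec:
    """One parameter and the low/high bounds to test it at."""

    parameter_path: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(
                f"{self.parameter_path}: low {self.low} exceeds high {self.high}"
            )


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at both bounds of one parameter, with the spread between them."""

    parameter_path: str
    low: float
    high: float
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]
    baseline_icer: Optional[float]

    @property
    def spread(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return math.inf  # a dominance flip dwarfs any finite spread
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_of(config: ModelConfig) -> Optional[float]:
    return evaluate(config).icer


def one_way_dsa(
    config: ModelConfig, specs: Sequence[DSASpec]
) -> list[TornadoEntry]:
    """Re-run the full model at each parameter's low and high bound.

    All other parameters stay at baseline.  Entries come back sorted by
    descending ICER spread, ready for a tornado diagram.
    """
    if not specs:
        raise ValueError("no DSA specs given")
    cfg = config.resolved()
    base = _icer_of(cfg)
    entries = []
    for spec in specs:
        get_parameter(cfg, spec.parameter_path)  # fail early on bad paths
        lo = _icer_of(set_parameter(cfg, spec.parameter_path, spec.low))
        hi = _icer_of(set_parameter(cfg, spec.parameter_path, spec.high))
        entries.append(
            TornadoEntry(
                parameter_path=spec.parameter_path,
                low=spec.low,
                high=spec.high,
                icer_at_low=lo,
                icer_at_high=hi,
                baseline_icer=base,
            )
        )
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def default_dsa_specs(
    config: ModelConfig,
    fraction: float = 0.2,
    transition_limits: Optional[Mapping[str, tuple[float, float]]] = None,
    discount_range: tuple[float, float] = (0.0, 0.08),
) -> list[DSASpec]:
    """±20% bounds on every cost and utility, published lower/upper limits
    (or ±20%, clipped to [0, 1]) on transition exit probabilities, and an
    absolute 0–8% range on the discount rate."""
    cfg = config.resolved()
    limits = dict(transition_limits or {})
    specs: list[DSASpec] = []

    for state in cfg.states:
        if state.absorbing or state.utility == 0.0:
            continue
        path = f"states.{state.name}.utility"
        specs.append(
            DSASpec(path, state.utility * (1 - fraction), min(state.utility * (1 + fraction), 1.0))
        )
    for strat in cfg.strategies:
        for state_name, cost in strat.cycle_costs.items():
            if cost == 0.0:
                continue
            path = f"strategies.{strat.name}.cycle_costs.{state_name}"
            specs.append(DSASpec(path, cost * (1 - fraction), cost * (1 + fraction)))
        if strat.ae_cost_per_cycle > 0.0:
            path = f"strategies.{strat.name}.ae_cost_per_cycle"
            specs.append(
                DSASpec(
                    path,
                    strat.ae_cost_per_cycle * (1 - fraction),
                    strat.ae_cost_per_cycle * (1 + fraction),
                )
            )
        tm = strat.transition
        for i, frm in enumerate(tm.labels):
            for j, to in enumerate(tm.labels):
                p = tm.probs[i][j]
                if i == j or p == 0.0:
                    continue
                path = f"strategies.{strat.name}.transition.{frm}.{to}"
                lo, hi = limits.get(path, (p * (1 - fraction), min(p * (1 + fraction), 1.0)))
                specs.append(DSASpec(path, lo, hi))
    specs.append(DSASpec("annual_discount", *discount_range))
    return specs


# ---------------------------------------------------------------------------
# PSA


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution for one parameter path.

    ``family`` is "beta", "gamma" or "point"; ``a``/``b`` are the family's
    shape parameters (Beta α/β, Gamma shape/scale, point value/unused).
    """

    parameter_path: str
    family: str
    a: float
    b: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point":
            return np.full(n, self.a)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=n)
        if self.family == "gamma":
            return rng.gamma(shape=self.a, scale=self.b, size=n)
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class PSASpec:
    """Distribution assignments plus iteration count and RNG seed."""

    distributions: tuple[ParameterDistribution, ...]
    n_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")


@dataclass
class PSAResult:
    """Per-iteration incremental outcomes and the acceptability summary."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    wtp: float
    seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.delta_cost)

    @property
    def prob_at_wtp(self) -> float:
        """Fraction of iterations with positive incremental NMB at the
        configured WTP (NMB exactly zero counts as not cost-effective)."""
        return float(np.mean(self.wtp * self.delta_qaly - self.delta_cost > 0.0))


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> dict[float, float]:
    """Probability the intervention is cost-effective at each WTP value."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    nmb = grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    return {float(w): float(p) for w, p in zip(grid, np.mean(nmb > 0.0, axis=1))}


_SD_SCALE = 2.0 * 1.96  # range read as mean ± 1.96 SD


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    if sd <= 0 or mean <= 0.0 or mean >= 1.0:
        raise ValueError("degenerate Beta moments")
    cap = math.sqrt(mean * (1 - mean))
    sd = min(sd, 0.95 * cap)  # keep the method of moments well-posed
    nu = mean * (1 - mean) / sd**2 - 1.0
    return mean * nu, (1 - mean) * nu


def build_psa_distributions(
    config: ModelConfig,
    ranges: Mapping[str, tuple[float, float]],
    n_iterations: int = 1000,
    seed: int = 0,
) -> PSASpec:
    """Assign a sampling distribution to every parameter in ``ranges``.

    Probabilities and utilities get Beta distributions, costs Gamma, each
    with mean equal to the baseline value and SD = (high − low)/3.92.
    Zero-width ranges (and boundary baselines such as a zero cost) become
    point masses, so a fully degenerate spec reproduces the base case.
    """
    cfg = config.resolved()
    dists: list[ParameterDistribution] = []
    for path, (low, high) in ranges.items():
        base = get_parameter(cfg, path)
        if not low <= base <= high:
            raise ValueError(
                f"baseline {base} for {path!r} outside its range ({low}, {high})"
            )
        sd = (high - low) / _SD_SCALE
        is_prob = ".transition." in path or path.endswith(".utility")
        if sd == 0.0:
            dists.append(ParameterDistribution(path, "point", base))
        elif is_prob:
            try:
                a, b = _beta_moments(base, sd)
                dists.append(ParameterDistribution(path, "beta", a, b))
            except ValueError:
                dists.append(ParameterDistribution(path, "point", base))
        else:
            if base <= 0.0:
                dists.append(ParameterDistribution(path, "point", base))
            else:
                shape = base**2 / sd**2
                dists.append(ParameterDistribution(path, "gamma", shape, sd**2 / base))
    return PSASpec(distributions=tuple(dists), n_iterations=n_iterations, seed=seed)


def default_psa_ranges(
    config: ModelConfig,
    fraction: float = 0.2,
    transition_limits: Optional[Mapping[str, tuple[float, float]]] = None,
) -> dict[str, tuple[float, float]]:
    """±20% ranges on costs and utilities, published limits (where given)
    on transition exit probabilities — the same parameter set as the
    default one-way analysis, minus the discount rate."""
    ranges: dict[str, tuple[float, float]] = {}
    for spec in default_dsa_specs(config, fraction, transition_limits):
        if spec.parameter_path == "annual_discount":
            continue
        ranges[spec.parameter_path] = (spec.low, spec.high)
    return ranges


def _apply_iteration(
    cfg: ModelConfig, values: Mapping[str, float]
) -> ModelConfig:
    """Apply one iteration's sampled values, renormalising transition rows.

    Sampled exit probabilities in one row are applied jointly: the
    self-loop takes the residual, and if the exits alone exceed 1 they are
    rescaled to sum to 1 (self-loop 0) to keep the row stochastic.
    """
    out = cfg.model_copy(deep=True)
    rows: dict[tuple[str, str], dict[str, float]] = {}
    for path, value in values.items():
        if ".transition." in path:
            _, strat, _, frm, to = path.split(".")
            rows.setdefault((strat, frm), {})[to] = value
        else:
            kind, holder, key = _resolve(out, path)
            if kind == "cost":
                holder.cycle_costs[key] = float(value)
            elif kind == "utility":
                holder.utility = float(min(max(value, 0.0), 1.0))
            else:
                setattr(holder, key, float(value))
    for (strat_name, frm), exits in rows.items():
        strat = out.get_strategy(strat_name)
        tm = strat.transition
        labels = tm.labels
        i = labels.index(frm)
        row = [0.0] * len(labels)
        for to, p in exits.items():
            row[labels.index(to)] = float(min(max(p, 0.0), 1.0))
        total_exit = sum(row)
        if total_exit > 1.0:
            row = [p / total_exit for p in row]
            total_exit = 1.0
        row[i] = 1.0 - total_exit
        probs = [list(r) for r in tm.probs]
        probs[i] = row
        strat.transition = type(tm)(
            labels=labels, probs=tuple(tuple(r) for r in probs)
        )
    return out


def run_psa(config: ModelConfig, spec: PSASpec) -> PSAResult:
    """Second-order Monte Carlo: sample all parameters jointly per
    iteration (independently across parameters), re-run both arms, and
    record the incremental cost and QALYs.  A single seeded generator
    drives all sampling, so identical seed and spec give identical output.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_iterations
    samples = {d.parameter_path: d.sample(rng, n) for d in spec.distributions}

    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    for it in range(n):
        values = {path: col[it] for path, col in samples.items()}
        res = evaluate(_apply_iteration(cfg, values))
        d_cost[it] = res.incremental_cost
        d_qaly[it] = res.incremental_qaly
    return PSAResult(delta_cost=d_cost, delta_qaly=d_qaly, wtp=cfg.wtp, seed=spec.seed)
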