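"""The gallbladder-cancer parameter fixture and a synthetic-model generator.

``load_gbc_fixture`` returns the complete two-arm configuration for the
mGEMOX-versus-FUFA comparison, together with the published transition
limits (for sensitivity ranges) and the published base-case result cells
(for consistency auditing).  ``generate_synthetic_config`` draws random
valid model configurations of the same structure, so every analysis step
can be property-tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .model import ModelConfig, StateSpec, StrategyParams

__all__ = [
    "FixtureBundle",
    "SyntheticSpec",
    "load_gbc_fixture",
    "generate_synthetic_config",
]

_FIXTURE_RESOURCE = "gbc_mgemox_fufa.yaml"


@dataclass(frozen=True)
class FixtureBundle:
    """Parsed fixture: config plus the published tables and metadata."""

    config: ModelConfig
    table1: dict[str, dict[str, float]]
    table3: dict[str, dict[str, float]]
    metadata: dict

    def transition_limits(self) -> dict[str, tuple[float, float]]:
        """Published lower/upper limits keyed by parameter path."""
        return {k: (v["low"], v["high"]) for k, v in self.table1.items()}


def load_gbc_fixture(path: Optional[str | Path] = None) -> FixtureBundle:
    """Load the gallbladder-cancer fixture (or a user-supplied bundle).

    The default fixture ships with the package; medians, utilities, the
    discount rate and the willingness-to-pay threshold are the published
    values, and the progression-free-state per-cycle costs are calibrated
    against the published per-state totals (see the calibration module).
    """
    if path is None:
        raw = (
            resources.files("markovcea").joinpath("data", _FIXTURE_RESOURCE).read_text()
        )
    else:
        raw = Path(path).read_text()
    try:
        doc = yaml.safe_load(raw)
        config = ModelConfig.model_validate(doc["config"])
        table1 = doc.get("table1", {})
        table3 = doc.get("table3", {})
        metadata = doc.get("metadata", {})
    except (yaml.YAMLError, KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"corrupted fixture file: {exc}") from exc
    return FixtureBundle(config=config, table1=table1, table3=table3, metadata=metadata)


@dataclass(frozen=True)
class SyntheticSpec:
    """Sampling ranges for random valid model configurations.

    Medians are drawn log-uniformly (months), per-cycle costs log-uniformly
    (USD/month) — spanning realistic oncology-model magnitudes — and
    utilities uniformly, with the progressed-state utility forced below the
    progression-free one.  ``median_gap_range`` bounds post-progression
    survival away from zero so the death-from-progression probability is
    always defined.
    """

    seed: int = 0
    n_strategies: int = 2
    median_pfs_range: tuple[float, float] = (1.0, 60.0)
    median_gap_range: tuple[float, float] = (0.1, 24.0)
    cost_range: tuple[float, float] = (10.0, 5000.0)
    pfs_utility_range: tuple[float, float] = (0.5, 0.95)
    pd_utility_range: tuple[float, float] = (0.2, 0.9)
    horizon_options: tuple[int, ...] = (60, 120, 240)
    cycle_length: float = 1.0
    discount_range: tuple[float, float] = (0.0, 0.08)
    wtp_range: tuple[float, float] = (10_000.0, 100_000.0)

    def __post_init__(self) -> None:
        for name in ("median_pfs_range", "median_gap_range", "cost_range",
                     "pfs_utility_range", "pd_utility_range",
                     "discount_range", "wtp_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi and lo >= 0):
                raise ValueError(f"infeasible range {name}: ({lo}, {hi})")
        if self.n_strategies < 1 or not self.horizon_options:
            raise ValueError("need at least one strategy and one horizon option")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return lo if lo == hi else float(rng.uniform(lo, hi))


def generate_synthetic_config(spec: SyntheticSpec) -> ModelConfig:
    """Draw one random, fully valid three-state model configuration.

    Seeded and reproducible: the same spec yields the same config.  Every
    output satisfies the configuration invariants by construction (ordered
    medians, non-negative costs, utilities in [0, 1], stochastic rows).
    Zero-width ranges collapse to their midpoint, giving a deterministic
    config.
    """
    rng = np.random.default_rng(spec.seed)
    u_pfs = _uniform(rng, *spec.pfs_utility_range)
    pd_hi = min(spec.pd_utility_range[1], u_pfs)
    pd_lo = min(spec.pd_utility_range[0], pd_hi)
    u_pd = _uniform(rng, pd_lo, pd_hi)
    states = [
        StateSpec(name="PFS", utility=u_pfs),
        StateSpec(name="PD", utility=u_pd),
        StateSpec(name="DEATH", utility=0.0, absorbing=True),
    ]

    strategies = []
    for k in range(spec.n_strategies):
        median_pfs = _log_uniform(rng, *spec.median_pfs_range)
        median_os = median_pfs + _log_uniform(rng, *spec.median_gap_range)
        strategies.append(
            StrategyParams(
                name=f"arm{k}",
                median_pfs=median_pfs,
                median_os=median_os,
                cycle_costs={
                    "PFS": _log_uniform(rng, *spec.cost_range),
                    "PD": _log_uniform(rng, *spec.cost_range),
                    "DEATH": 0.0,
                },
            )
        )

    return ModelConfig(
        states=states,
        strategies=strategies,
        cycle_length=spec.cycle_length,
        horizon=int(rng.choice(np.array(spec.horizon_options))),
        annual_discount=_uniform(rng, *spec.discount_range),
        wtp=_uniform(rng, *spec.wtp_range),
        intervention=strategies[0].name if len(strategies) > 1 else None,
        comparator=strategies[1].name if len(strategies) > 1 else None,
    )
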