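"""Tabular and JSON report writers for traces, base case, DSA and PSA.

Human-readable tables round money and ratios to 2 decimals and
probabilities/QALY weights to 4; the JSON summaries keep full precision.
"""

from __future__ import annotations

import json
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .economics import CEResult
from .model import MarkovTrace
from .sensitivity import PSAResult, TornadoEntry, ceac

__all__ = [
    "trace_frame",
    "base_case_summary",
    "base_case_table",
    "dsa_frame",
    "psa_frame",
    "ceac_frame",
    "write_json",
    "run_manifest",
]


def trace_frame(trace: MarkovTrace) -> pd.DataFrame:
    """Per-cycle trace: occupancy, discount factor, discounted accrual."""
    return trace.to_frame()


def base_case_summary(result: CEResult) -> dict:
    """Full-precision JSON-ready summary mirroring the published table's
    row structure (per-state and total costs/QALYs, increments, average
    cost-effectiveness ratios, ICER, net monetary benefit)."""
    ratios = result.ce_ratios()
    return {
        "strategies": {
            t.name: {
                "per_state_cost": t.per_state_cost,
                "per_state_qaly": t.per_state_qaly,
                "total_cost": t.total_cost,
                "total_qaly": t.total_qaly,
                "ce_ratio": ratios[t.name],
                "nmb": nmb,
            }
            for t, nmb in (
                (result.intervention, result.nmb_intervention),
                (result.comparator, result.nmb_comparator),
            )
        },
        "incremental_cost": result.incremental_cost,
        "incremental_qaly": result.incremental_qaly,
        "icer": result.icer,
        "dominance": result.dominance,
        "wtp": result.wtp,
        "incremental_nmb": result.incremental_nmb,
        "cost_effective_at_wtp": result.cost_effective,
    }


def base_case_table(result: CEResult) -> pd.DataFrame:
    """Two-column result table, one row per reported quantity."""
    s = base_case_summary(result)
    iv, cp = result.intervention.name, result.comparator.name
    rows = []
    states = list(result.intervention.per_state_cost)
    for st in states:
        rows.append((f"cost_{st}", *(round(s["strategies"][a]["per_state_cost"][st], 2) for a in (iv, cp))))
    rows.append(("total_cost", round(s["strategies"][iv]["total_cost"], 2), round(s["strategies"][cp]["total_cost"], 2)))
    for st in states:
        rows.append((f"qaly_{st}", *(round(s["strategies"][a]["per_state_qaly"][st], 4) for a in (iv, cp))))
    rows.append(("total_qaly", round(s["strategies"][iv]["total_qaly"], 4), round(s["strategies"][cp]["total_qaly"], 4)))
    rows.append(("ce_ratio", round(s["strategies"][iv]["ce_ratio"], 2), round(s["strategies"][cp]["ce_ratio"], 2)))
    rows.append(("incremental_cost", round(s["incremental_cost"], 2), ""))
    rows.append(("incremental_qaly", round(s["incremental_qaly"], 4), ""))
    icer = s["icer"]
    rows.append(("icer", round(icer, 2) if icer is not None else s["dominance"], ""))
    return pd.DataFrame(rows, columns=["quantity", iv, cp])


def dsa_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Tornado-ready table: parameter, bounds, endpoint ICERs, spread."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter_path,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_at_low,
                "icer_high": e.icer_at_high,
                "baseline_icer": e.baseline_icer,
                "spread": e.spread if math.isfinite(e.spread) else np.inf,
            }
            for e in entries
        ]
    )


def psa_frame(psa: PSAResult) -> pd.DataFrame:
    """Per-iteration incremental cost/QALY scatter."""
    return pd.DataFrame(
        {
            "iteration": np.arange(psa.n_iterations),
            "delta_cost": psa.delta_cost,
            "delta_qaly": psa.delta_qaly,
        }
    )


def ceac_frame(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Acceptability curve: probability cost-effective per WTP value."""
    curve = ceac(psa, wtp_grid)
    return pd.DataFrame({"wtp": list(curve), "probability": list(curve.values())})


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def run_manifest(
    subcommand: str,
    config_path: Optional[str],
    config_digest: Optional[str],
    outputs: Sequence[str],
    seed: Optional[int] = None,
) -> dict:
    """Provenance record written next to every CLI output set."""
    return {
        "package": "markovcea",
        "version": __version__,
        "subcommand": subcommand,
        "config_path": config_path,
        "config_sha256": config_digest,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": list(outputs),
    }
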