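"""Back-solving the unpublished progression-free drug cost.

The published cost table gives each arm's discounted progression-free
state total but not the per-cycle drug-acquisition cost behind it.
Because a state's total cost is exactly per-cycle cost × discounted
person-time, the missing input is one division away.  The solved
intervention cost lands near 2105.85 USD/month — the midpoint of the
published one-way range (1684.68, 2527.02) — which corroborates the
reconstruction.
"""

from markovcea import (
    CalibrationProblem,
    calibrate_cycle_cost,
    discounted_person_time,
    load_gbc_fixture,
    run_trace,
    validate_fixture,
)

bundle = load_gbc_fixture()
cfg = bundle.config

for arm in ("mGEMOX", "FUFA"):
    trace = run_trace(cfg, arm)
    pt = discounted_person_time(trace, "PFS")
    target = bundle.table3[arm]["pfs_cost"]
    solved = calibrate_cycle_cost(
        CalibrationProblem(strategy=arm, state="PFS", target_total=target), trace
    )
    comps = cfg.get_strategy(arm).cost_components
    known = sum(v for k, v in comps.items() if "back_calculated" not in k)
    print(f"{arm}:")
    print(f"  discounted person-months in PFS: {pt:.4f}")
    print(f"  published PFS total:             {target:.2f} USD")
    print(f"  solved per-cycle cost:           {solved:.2f} USD/month")
    print(f"  printed components (tests+hosp+AE): {known:.2f} USD/month")
    print(f"  residual drug acquisition:       {solved - known:.2f} USD/month\n")

print("fixture audit against the published result table:")
print(validate_fixture(cfg, bundle.table3).to_text())
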