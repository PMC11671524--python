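"""Random valid model configurations for testing and exploration.

The generator draws a full three-state model (medians, costs, utilities,
horizon, discount rate, willingness-to-pay) from documented ranges, with
every invariant guaranteed by construction.  The same seed always yields
the same model, and any generated model runs through the whole pipeline:
trace, incremental economics, one-way and probabilistic sensitivity.
"""

from markovcea import (
    SyntheticSpec,
    build_psa_distributions,
    default_psa_ranges,
    evaluate,
    generate_synthetic_config,
    run_psa,
)

cfg = generate_synthetic_config(SyntheticSpec(seed=7))

print("generated model:")
for s in cfg.strategies:
    print(
        f"  {s.name}: median PFS {s.median_pfs:.2f} mo, OS {s.median_os:.2f} mo, "
        f"PFS cost {s.cycle_costs['PFS']:.2f}, PD cost {s.cycle_costs['PD']:.2f} USD/mo"
    )
print(
    f"  horizon {cfg.horizon} cycles, discount {cfg.annual_discount:.3f}/yr, "
    f"WTP {cfg.wtp:.0f} USD/QALY"
)

res = evaluate(cfg)
print(f"\nincremental cost {res.incremental_cost:.2f} USD, QALYs {res.incremental_qaly:.4f}")
if res.icer is not None:
    print(f"ICER {res.icer:.2f} USD/QALY")
else:
    print(f"ICER undefined: intervention is {res.dominance}")

psa = run_psa(cfg, build_psa_distributions(cfg, default_psa_ranges(cfg), 200, seed=7))
print(f"P(cost-effective at WTP {psa.wtp:.0f}) = {psa.prob_at_wtp:.3f} (200 draws)")
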