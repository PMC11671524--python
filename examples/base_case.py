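"""Base case: costs, QALYs and the ICER for mGEMOX versus FUFA.

Loads the shipped gallbladder-cancer fixture, runs the 120-cycle Markov
cohort trace for both treatment arms and prints the incremental
economics.  The ICER well above the 37,697 USD/QALY willingness-to-pay
threshold is the analysis' headline: the intervention buys extra QALYs,
but at a price per QALY the Chinese healthcare system is assumed
unwilling to pay.
"""

from markovcea import evaluate, load_gbc_fixture, run_trace

bundle = load_gbc_fixture()
cfg = bundle.config

for arm in ("mGEMOX", "FUFA"):
    tr = run_trace(cfg, arm)
    print(f"{arm}:")
    for state in ("PFS", "PD"):
        print(
            f"  {state}: cost {tr.per_state_cost[state]:9.2f} USD, "
            f"QALYs {tr.per_state_qaly[state]:.4f}"
        )
    print(f"  total: cost {tr.discounted_cost:9.2f} USD, QALYs {tr.discounted_qaly:.4f}")

res = evaluate(cfg)
print(f"\nincremental cost:  {res.incremental_cost:9.2f} USD")
print(f"incremental QALYs: {res.incremental_qaly:9.4f}")
print(f"ICER:              {res.icer:9.2f} USD/QALY")
print(f"WTP threshold:     {cfg.wtp:9.2f} USD/QALY")
print(f"cost-effective at WTP: {res.cost_effective}")
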