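# markovcea

A Markov cohort cost-effectiveness engine for comparing chemotherapy
regimens in unresectable gallbladder cancer, built around the published
Chinese-payer comparison of **modified gemcitabine + oxaliplatin
(mGEMOX)** against **fluorouracil + folinic acid (FUFA)** — and usable as
a general config-driven three-state decision model for anyone doing
health-economic evaluation in Python.

## The model

Patients occupy one of three mutually exclusive health states —
progression-free survival (**PFS**), progressive disease (**PD**) and
**death** (absorbing) — and move between them in monthly cycles over a
10-year horizon. Per-cycle transition probabilities come from median
survival under a constant-hazard assumption,

> p = 1 − exp(−cycle · ln 2 / median) = 1 − 0.5^(cycle/median),

applied to median PFS (progression risk), median OS (death from PFS) and
post-progression survival OS − PFS (death from PD). PD cannot return to
PFS.

Each cycle accrues discounted costs (per-state USD/month) and QALYs
(state utility × 1/12 year), with half-cycle correction — membership for
cycle *t* is the average of the occupancies at cycle boundaries *t−1*
and *t* — and 5 %/year discounting in whole-year steps. Two arms are
compared by the incremental cost-effectiveness ratio
**ICER = ΔC/ΔE** against a willingness-to-pay (WTP) threshold of
$37,697/QALY (3× China's 2022 GDP per capita); uncertainty is handled by
one-way (tornado) sensitivity analysis and a 1,000-iteration
probabilistic sensitivity analysis (PSA) summarised as a
cost-effectiveness acceptability curve (CEAC).

The engine also *calibrates* unpublished inputs: the published tables
give each arm's discounted PFS-state cost total but not the per-cycle
drug-acquisition cost behind it, which the calibration module back-solves
exactly (total = per-cycle cost × discounted person-time).

## Worked example

```python
from markovcea import evaluate, load_gbc_fixture

bundle = load_gbc_fixture()
res = evaluate(bundle.config)
print(res.intervention.total_cost, res.intervention.total_qaly)
print(res.incremental_cost, res.incremental_qaly, res.icer)
```

Running `python examples/base_case.py` prints:

```
mGEMOX:
  PFS: cost  12790.39 USD, QALYs 0.3920
  PD: cost   2126.27 USD, QALYs 0.0562
  total: cost  14916.66 USD, QALYs 0.4482
FUFA:
  PFS: cost   1121.48 USD, QALYs 0.1683
  PD: cost   2191.70 USD, QALYs 0.0637
  total: cost   3313.18 USD, QALYs 0.2320

incremental cost:   11603.48 USD
incremental QALYs:    0.2162
ICER:               53669.09 USD/QALY
WTP threshold:      37697.00 USD/QALY
cost-effective at WTP: False
```

mGEMOX gains 0.22 QALYs (0.45 vs 0.23 at two decimals) at about $11,600
extra cost; at roughly $53,700 per QALY gained it is **not**
cost-effective at the $37,697/QALY threshold. The PSA
(`examples/psa_ceac.py`) finds an essentially 0 % probability of
cost-effectiveness at that threshold, with the acceptability curve
crossing 50 % only near the base-case ICER; the tornado
(`examples/tornado.py`) is dominated by the mGEMOX PFS-state cost and
the PFS utility.

Other examples: `calibrate_costs.py` (back-solving the unpublished drug
cost and auditing the fixture against the published result table) and
`synthetic_models.py` (random valid models through the whole pipeline).

A thin CLI wraps the same library calls:

```sh
markovcea base-case --out-dir out/        # traces + result table + JSON
markovcea dsa --out-dir out/              # tornado-ready CSV
markovcea psa -n 1000 --seed 0 --out-dir out/   # scatter + CEAC CSVs
markovcea calibrate --strategy mGEMOX --target-total 12790.39
markovcea synth --seed 5 --out config.yaml
markovcea validate --out-dir out/
```

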