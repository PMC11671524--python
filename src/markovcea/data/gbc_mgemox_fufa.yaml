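# Unresectable gallbladder cancer: modified gemcitabine + oxaliplatin (mGEMOX)
# versus fluorouracil + folinic acid (FUFA), Chinese healthcare payer view.
#
# Per-cycle PFS-state costs are calibrated: the published table prints the
# discounted PFS-state totals but not the drug-acquisition cost per cycle,
# so the per-cycle total is back-solved from the printed total under this
# fixture's trace conventions (rounded transition table, half-cycle
# correction, annual-step 5% discounting). The printed components (tests,
# hospitalisation, adverse events) are broken out below; the residual is
# labelled drug acquisition (back-calculated).
name: gbc_mgemox_fufa
config:
  states:
    - {name: PFS, utility: 0.77, absorbing: false}
    - {name: PD, utility: 0.64, absorbing: false}
    - {name: DEATH, utility: 0.0, absorbing: true}
  cycle_length: 1.0          # months
  horizon: 120               # 10 years of monthly cycles
  annual_discount: 0.05
  wtp: 37697.00              # 3x China's 2022 GDP per capita, USD/QALY
  half_cycle_correction: true
  discounting: annual
  use_rounded_table1: true   # published transition table is printed at 2 dp
  initial_state: PFS
  intervention: mGEMOX
  comparator: FUFA
  strategies:
    - name: mGEMOX
      median_pfs: 8.5        # months
      median_os: 9.5
      ae_cost_per_cycle: 1.26
      cycle_costs:
        PFS: 2092.1531076605  # calibrated total 2093.4131 minus the 1.26 AE cost
        PD: 2017.94
        DEATH: 0.0
      cost_components:
        tests: 90.03
        hospitalization: 140.76
        adverse_events: 1.26
        drug_acquisition_back_calculated: 1861.3631076605
    - name: FUFA
      median_pfs: 3.5
      median_os: 4.6
      ae_cost_per_cycle: 0.0
      cycle_costs:
        PFS: 427.5258711398   # calibrated (no separate AE cost in this arm)
        PD: 1834.49
        DEATH: 0.0
      cost_components:
        tests: 164.37
        hospitalization: 164.22
        drug_acquisition_back_calculated: 98.9358711398

# Published per-cycle transition probabilities with lower/upper limits,
# used for the sensitivity-analysis ranges.
table1:
  strategies.mGEMOX.transition.PFS.PD: {baseline: 0.08, low: 0.06, high: 0.09}
  strategies.mGEMOX.transition.PFS.DEATH: {baseline: 0.07, low: 0.06, high: 0.08}
  strategies.mGEMOX.transition.PD.DEATH: {baseline: 0.50, low: 0.40, high: 0.60}
  strategies.FUFA.transition.PFS.PD: {baseline: 0.18, low: 0.14, high: 0.22}
  strategies.FUFA.transition.PFS.DEATH: {baseline: 0.14, low: 0.11, high: 0.17}
  strategies.FUFA.transition.PD.DEATH: {baseline: 0.47, low: 0.37, high: 0.56}

# Published base-case results, audited by calibration.validate_fixture.
table3:
  mGEMOX:
    pfs_cost: 12790.39
    pd_cost: 2111.92
    total_cost: 14902.31
    incremental_cost: 11608.43
    pfs_qaly: 0.39
    pd_qaly: 0.06
    total_qaly: 0.45
    incremental_qaly: 0.22
    ce_ratio: 33116.24
    icer: 52765.59
  FUFA:
    pfs_cost: 1121.48
    pd_cost: 2172.40
    total_cost: 3293.88
    pfs_qaly: 0.17
    pd_qaly: 0.06
    total_qaly: 0.23
    ce_ratio: 14321.22

metadata:
  perspective: Chinese societal / payer
  currency: USD
  exchange_rate_note: "costs converted at 1 USD = 6.82 CNY (Jan 2023); metadata only, no conversion performed"
  wtp_note: "three times China's 2022 GDP per capita, 37697.00 USD/QALY"
  ae_probabilities_pct:
    mGEMOX: {vomiting: 7.69, myelosuppression: 38.46, neurotoxicity: 11.54, transaminitis: 15.38, neutropenic_fever: 7.69}
    FUFA: {vomiting: 7.14, myelosuppression: 7.14, neurotoxicity: 0.0, transaminitis: 0.0, neutropenic_fever: 0.0}
  dsa_published_endpoints:
    strategies.mGEMOX.cycle_costs.PFS:
      range: [1684.68, 2527.02]
      icer_endpoints: [42068.81, 65850.30]
    states.PFS.utility:
      range: [0.62, 1.00]
      icer_endpoints: [68112.01, 41417.29]
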