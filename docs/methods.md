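# Methods

## Model structure and assumptions

The engine implements a discrete-time Markov cohort model. Health states
are mutually exclusive and collectively exhaustive; the shipped
gallbladder-cancer fixture uses three — progression-free survival (PFS,
utility 0.77), progressive disease (PD, utility 0.64) and death
(absorbing, utility 0) — with the whole cohort starting in PFS. The
cycle is one month and the horizon 120 cycles (10 years), long enough
that under the fixture's transition probabilities over 99 % of the
cohort has died by the end, so the truncation error is negligible.

Transition probabilities derive from median survival under an
exponential (constant-hazard) assumption: `p = 1 − 0.5^(cycle/median)`.
Progression risk uses median PFS, death-from-PFS uses median OS, and
death-from-PD uses post-progression survival (median OS − median PFS:
1.0 month for mGEMOX, 1.1 for FUFA). That last derivation is this
package's reconstruction — it reproduces the published PD-row
probabilities (0.50 and 0.47) exactly at two decimals, which is strong
evidence it is how those cells were produced. Self-loops are residuals;
PD cannot return to PFS. Explicit matrices may be supplied instead of
medians, and the fixture sets `use_rounded_table1: true` so the engine
uses the two-decimal published probabilities, since the published
results are evidently computed from them.

The model deliberately mirrors the source analysis' simplifications and
therefore shares its limitations: no background (other-cause) mortality,
no tunnel states, and per-state costs that are flat per month — in
particular the chemotherapy acquisition cost is not capped at the actual
treatment duration (6 three-week cycles for mGEMOX, 30 weeks for FUFA)
but accrues for as long as a patient stays progression-free. All
computation is in USD; the stated CNY conversion is metadata only.

## Accrual conventions

Two conventions are configurable because the source text does not state
them; the defaults were chosen as the unique pair that reproduces every
published QALY cell at two decimals.

- **Half-cycle correction** (default on): membership for cycle *t* is
  `(occ[t−1] + occ[t])/2`, approximating mid-cycle transitions. There is
  no separate cycle-0 reward. Cycle-start counting gives 0.43
  PFS QALYs for mGEMOX and cycle-end 0.36 against the published 0.39,
  which brackets the half-cycle value — the published analysis must have
  used a mid-cycle convention.
- **Discounting** (default `annual`): the 5 %/year rate is applied in
  whole-year steps, `(1.05)^(−⌊t/12⌋)`, the convention of the standard
  decision-tree packages (the first model year is undiscounted). The
  alternative `monthly` setting compounds continuously in fractional
  years, `(1.05)^(−t/12)`. Under `annual` + half-cycle correction +
  rounded probabilities the trace gives total QALYs 0.4482 (mGEMOX) and
  0.2320 (FUFA) — 0.45/0.23 at two decimals, matching the published
  totals and per-state splits — whereas `monthly` gives 0.4403, which
  rounds to 0.44. Costs and QALYs are discounted identically.

## Cost calibration

The published result table prints each arm's discounted PFS-state cost
total, but the per-cycle cost behind it is only partially itemised
(tests, hospitalisation, adverse events — no drug-acquisition figure).
A state's total cost is exactly linear in its per-cycle cost, with slope
equal to the discounted half-cycle-corrected person-time in that state,
so the missing input is recovered by one division. The fixture stores
the calibrated values — 2093.41 USD/month for mGEMOX (including the
1.26 USD/month adverse-event cost) and 427.53 for FUFA — with the
printed components broken out and the residual labelled
`drug_acquisition_back_calculated`. The mGEMOX value lands 0.6 % from
2105.85, the midpoint of the published one-way range (1684.68,
2527.02), corroborating the reconstruction.

PD-state per-cycle costs use the printed values (2017.94 / 1834.49
USD/month) directly. Recomputing the PD totals from them misses the
printed cells by 0.7–0.9 % — a residual inconsistency in the source
inputs that `validate_fixture` reports rather than absorbs (tolerances:
QALY cells ±0.005 absolute; calibrated-cost cells and grand totals ±1 %
relative; PD-cost, ratio and ICER cells ±3 %).

A consequence: the engine's full-precision base-case ICER is
53,669 USD/QALY, while the published 52,765.59 equals 11,608.43/0.22 —
a quotient of result cells rounded to two decimals. Both facts are
surfaced (the arithmetic identity in the economics layer, the
full-precision value in the fixture audit); nothing is tuned to split
the difference.

## Sensitivity analysis

**One-way (tornado).** Each parameter is set to its low and high bound
with everything else at baseline and the model re-run. Defaults: ±20 %
for costs and utilities (utilities clipped at 1), the published
lower/upper limits for transition exit probabilities, 0–8 % absolute for
the discount rate. Transition entries are varied with the self-loop
taking the residual. Because incremental QALYs do not depend on costs,
the ICER is affine in any single per-cycle cost — verified against a
five-point brute-force grid. The published endpoint ICERs for the
mGEMOX PFS cost (42,068.81 / 65,850.30) are not symmetric about the
published base ICER even though affinity forces symmetry, so they are
mutually inconsistent as printed; this engine reproduces the model
faithfully (its endpoints over the same cost range are 42,118 / 65,923)
and asserts the structural properties, not the printed endpoints.

**Probabilistic.** Second-order Monte Carlo, default 1,000 iterations.
Distribution families are a standard health-economics choice (the
source states none): Beta for probabilities and utilities, Gamma for
costs, method of moments with mean at baseline and SD = (high −
low)/3.92 (range read as mean ± 1.96 SD; the SD is capped below the
Beta feasibility bound where needed). Parameters are sampled
independently; within a transition row the exit probabilities are
sampled and the self-loop takes the residual, with exits rescaled in
the rare draw where they exceed 1. Zero-width ranges become point
masses, so a degenerate specification reproduces the base case exactly.
A single seeded `numpy` generator drives all sampling; identical seed
and specification give bit-identical results. Ties at zero incremental
net monetary benefit count as not cost-effective. At the 37,697
USD/QALY threshold the acceptance probability is ≈ 1.8 % (0.0181 at
10,000 iterations), consistent with the published "0 %" reading of the
acceptability curve at Monte Carlo resolution.

## Synthetic models

The generator draws fully valid three-state configurations for property
testing: medians log-uniform on 1–60 months with a log-uniform 0.1–24
month post-progression gap (keeping death-from-PD defined), per-cycle
costs log-uniform on 10–5,000 USD/month (spanning realistic oncology
magnitudes), PFS utility uniform on 0.5–0.95 with PD utility forced
below it, horizons of 5/10/20 years, discount 0–8 %, WTP
10,000–100,000 USD/QALY. Synthetic models exercise structure — ordered
medians, stochastic rows, conservation, monotone death occupancy,
calibration round-trips — not clinical realism: they have no treatment
duration caps, no correlation between costs and effectiveness, and
exponential survival by construction, so passing tests say nothing
about hazard shapes real trials might show.

## Numerical choices

Row sums are enforced to 1e-9 on input matrices and reproduced to
1e-12 by construction; occupancy conservation holds to 1e-10 over 120
cycles. Calibration is an exact linear inversion (no iteration);
round-trips recover generating costs to 1e-9 relative. The ICER is
reported only when |ΔQALY| > 1e-12, otherwise a dominance label
(`dominant` / `dominated` / `undefined`) — the dominance taxonomy is
standard practice, included for generality beyond the two-arm fixture.
Human-readable outputs round money to 2 and probabilities/QALYs to 4
decimals; JSON keeps full precision.
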