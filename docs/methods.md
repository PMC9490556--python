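# Methods

## Model structure

A deterministic cohort Markov model with three mutually exclusive states —
progression-free survival (PFS), progressed disease (PD), death — simulates
patients with resected stage IB–IIIA NSCLC after platinum-based adjuvant
chemotherapy. The whole cohort starts in PFS. Cycles are 21 days
(0.68994 months, 0.05749 years); the horizon is 10 years. 120 months /
0.68994 months per cycle = 173.93, which we round to **174 transitions**
(the trace has 175 rows and ends at 120.05 months); using 173 instead changes
totals by under 0.1%.

Transition probabilities are rebuilt every cycle from the parametric survivor
curves at elapsed time *t*:

* stay in PFS: `S_pfs(t) / S_pfs(t − μ)`, capped so the row sums to one;
* PFS → death: the per-cycle background-mortality probability;
* PFS → PD: the remainder of the PFS row;
* the whole-cohort survival ratio is `S_os(t) / S_os(t − μ)`; PD → PD is
  back-calculated as
  `[(n_PFS + n_PD)·p_SS − n_PFS·p_PFS,PFS − n_PFS·p_PFS,PD] / n_PD`
  (clamped to [0, 1]; clamping cycles are recorded on the trace), and
  PD → death takes the remainder. When `n_PD` is numerically zero the PD row
  falls back to the whole-cohort ratio instead of dividing by zero.

This construction ties total cohort survival to the OS curve exactly
(first-cycle transitions are evaluated at t = μ so `S(t − μ) = S(0) = 1`).

## Survival families and parameterization

Six accelerated-failure-time families are supported with Stata-`streg`-style
forms (time in months): exponential `S = exp(−λt)`; Weibull (PH form)
`S = exp(−λt^p)`; Gompertz `S = exp(−λ/a·(e^{at}−1))` with any real shape
(negative shape gives a defective law whose median may be infinite);
log-normal `S = 1 − Φ((ln t − μ)/σ)`; log-logistic `S = 1/(1+(λt)^{1/γ})`;
two-parameter gamma in shape/rate form. The source publication prints
parameter symbols (λ, P, σ, μ, γ) but never the formulas; these forms are the
ones under which the printed values give clinically plausible curves (e.g.
exponential OS λ = 0.00516/month ⇒ median ≈ 134 months), and that inference is
the single most consequential reading decision in the reimplementation.

The printed parameter table repeats two rows verbatim (the BSC all-randomised
Weibull OS equals the atezolizumab ITT Weibull OS; the BSC all-randomised and
BSC ITT lognormal PFS rows are identical) — possibly a transcription
duplication in the source. We reproduce them exactly as printed and emit a
one-time warning when the defaults are built.

Fitting is plain right-censored maximum likelihood (no covariates):
Nelder–Mead on log-transformed positive parameters, three fixed data-driven
starts plus a polishing restart, convergence tolerance 1e-8/1e-9 on the
log-likelihood; the exponential MLE (events / total follow-up time) is closed
form. AIC = 2k − 2·logL selects among families; ties break toward fewer
parameters, then a fixed family order. Note that three families nest the
exponential, so on truly exponential data AIC's +2 penalty is beaten by
chance in roughly 15% of cases per nesting rival — the true family wins a
clear majority, not 100%, of replicates.

## Pseudo-IPD reconstruction

Digitized curve coordinates plus a numbers-at-risk table are converted to
patient records by the standard iterative algorithm: within each at-risk
interval a censoring count is guessed, censor times are spread evenly, event
counts at each digitized step are back-solved from the survival ratios against
the running product-limit estimate, and the guess is adjusted until the
implied number at risk matches the published one at the next boundary. With no
risk-table row at time zero the initial n is taken from the earliest row. In
the final interval no censoring is assumed unless a total event count is
supplied (then censoring is adjusted to match it); everyone still at risk at
the last digitized time is administratively censored there. Events + censored
always equal the initial number at risk.

## Economics

All costs in 2022 USD (the source converts at 1 USD = 6.3 RMB; the exchange
rate is metadata only). Per cycle: drug cost (atezolizumab $4,218.61/cycle,
≤16 cycles) is charged to patients progression-free at the start of the
cycle; BSC cost ($299.47/cycle) to the comparator arm's PFS occupancy over the
same 16-cycle window by default; routine follow-up ($76.05) to everyone alive;
subsequent-line therapy ($736.35) to PD occupancy; terminal care ($2,331.70)
once per new death within the horizon. Severe adverse events (neutropenia
0.01 — no published unit cost, modelled at $0 and configurable; ALT 0.02 and
AST 0.01 at $75.67; pyrexia 0.01 at $845.61) are charged once in the treated
arm's first cycle, as the source states — even though the transaminase cost is
printed "per cycle"; a switch restores per-cycle charging. QALYs weight
occupancy by u_PFS = 0.827 and u_PD = 0.321 (death 0), minus a first-cycle
pyrexia disutility (0.420 × incidence). Costs and effects are discounted at
5%/year, applied per cycle as `(1.05)^(−t_years)`.

The pyrexia incidence is used in the published tornado but never tabulated;
default 0.01, configurable.

**Patient-assistance programme.** The published description ("pay for the
first two cycles and then receive three cycles free") is ambiguous. The
default schedule is paid cycles 1–8 / free 9–16, because the published
with-PAP drug spend sits ≈7.7 discounted cycle-costs below the no-PAP spend,
which matches eight free cycles; the literal repeating pay-2/free-3 pattern is
available as `PAP_PAID_PAY2_FREE3`. Price-negotiation scenarios scale the drug
unit cost to 30–70% of list.

## Modelling conventions (defaults and option space)

The source leaves four conventions unstated. Defaults, with the alternatives
kept as first-class options:

| convention | default | alternative |
|---|---|---|
| background mortality (0.00718/year, China crude death rate, configurable) | `embedded`: the OS curve is the complete account of deaths | `additional`: independent competing death multiplying cohort survival by (1−q_cycle)^k |
| discount timing | cycle start | cycle end |
| half-cycle correction | off (the source never mentions one) | on |
| BSC charging window | 16 cycles | every PFS cycle |

`convention_sweep` evaluates all 16 combinations. Under the defaults the
PD-L1 per-arm discounted LY/QALY land within ~6% of the published table
(6.07/4.03 vs 5.72/3.81 treated; 5.34/3.51 vs 5.11/3.36 comparator) and the
treated arm's total cost within 1%; the combination {additional mortality,
cycle-end discounting, no half-cycle correction, BSC charged every cycle}
brings all four LY/QALY figures within 2.7% and both arms' costs within 3%.
The comparator arm's total cost is the one output genuinely sensitive to the
BSC-window choice (≈$35.4k for 16 cycles vs ≈$47k charged throughout, matching
the published $47.1k).

## Sensitivity analysis

One-way analysis swings each tabulated parameter to ±25% of baseline (or its
printed range; discount rate 0–8%) with everything else at baseline and ranks
ICER spreads. The PSA draws costs from lognormal distributions (the
transaminase cost from a triangular) and utilities/AE incidences from betas,
10,000 draws by default. Parameterization is method of moments: the printed
(low, high) range is read as a central 95% interval, sd = (high − low)/3.92,
with the baseline as the mean; the survival parameters are held fixed, as in
the printed table. Survival inputs being fixed, both cohort traces are
computed once and re-costed per draw — each draw is a full re-run of
everything its parameters can touch. The CEAC reports, on a $0–350k grid
($1k steps), the fraction of draws with positive incremental net monetary
benefit; the 50% crossing is linearly interpolated. All randomness flows from
one root `numpy` SeedSequence.

## Synthetic data

`simulate_ipd` draws event times by inverse CDF from a known law and censors
administratively at 45 months (the follow-up era implied by the trial
curves); arm sizes default to 450. `digitize` emulates reading a published
figure: ideal mode keeps every step coordinate and tabulates exact at-risk
counts at 6-month marks; jitter mode rounds survival to 0.001 and time to
0.05 months. What the generator deliberately does not emulate: dependent
censoring, covariate structure, PD-L1 assay variability, or digitizer bias
that is correlated over time — so passing round-trip tests demonstrate the
pipeline's internal consistency, not robustness to every failure mode of real
figure extraction.

Problem sizes used in the shipped validation: reconstruction round trips at
200–425 patients per arm over 20 seeds; family-recovery checks at n = 1,000
over 20 seeds per family; PSA checks at 10,000 draws.

## Known limitations

* The parameterization conventions are inferred from parameter magnitudes
  (see above); if the source used different forms the survival inputs would
  change meaning.
* Two published PSA summaries are internally inconsistent with the
  publication's own base case and are not reproducible by this (or, we
  argue, any) faithful reimplementation: a ~94.9% probability of
  cost-effectiveness under the PAP at $27,354/QALY despite the published
  with-PAP ICER of $36,627.60/QALY (which implies negative mean incremental
  net benefit at that threshold), and a 50% CEAC crossing of ~$79,859/QALY
  despite a published base-case ICER of $108,825.37/QALY (a CEAC centred on
  the published incrementals must cross near the ICER itself). This model's
  corresponding outputs — ≈0% and a crossing near its own base-case ICER —
  are the internally consistent counterparts.
* Microsimulation, tunnel states, age-dependent background mortality,
  covariate-adjusted AFT models, cure fractions and EVPI are out of scope.
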