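"""Probabilistic sensitivity analysis and the acceptability curve (PD-L1).

Draws every uncertain cost/utility/AE parameter from its published
distribution 2,000 times (10,000 in the full analysis), re-costs the fixed
cohort traces per draw, and summarises the incremental outcomes as a
cost-effectiveness acceptability curve: the probability that atezolizumab has
positive incremental net monetary benefit at each willingness-to-pay level.
"""

import numpy as np

from lungcea import AnalysisConfig, ceac, run_group_psa, wtp_at_probability, wtp_grid

WTP = 27_354.0
config = AnalysisConfig()

samples = run_group_psa(config, "pdl1", "base", n=2_000, seed=42)
dq = samples["delta_qaly"].to_numpy()
dc = samples["delta_cost"].to_numpy()
print(f"draws: {len(samples)}  mean dC ${dc.mean():,.0f}  mean dQ {dq.mean():.3f}")
print(f"P(cost-effective at ${WTP:,.0f}/QALY) = {(WTP * dq - dc > 0).mean():.1%}")

curve = ceac(samples, wtp_grid(config))
for w in (25_000, 50_000, 100_000, 150_000, 200_000):
    p = curve.loc[curve.wtp == w, "probability"].iloc[0]
    print(f"  WTP ${w:>7,}: P = {p:.2f}")
print(f"50% crossing: ${wtp_at_probability(curve, 0.5):,.0f}/QALY "
      "(sits near the deterministic ICER)")
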