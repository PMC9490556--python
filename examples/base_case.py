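"""Deterministic base case: total costs, LYs, QALYs and ICERs per population.

Runs the three-state Markov cohort model (3-week cycles, 10-year horizon, 5%
annual discounting) from the shipped default inputs and prints a results table
per analysis population, plus the incremental comparison against best
supportive care.  A positive ICER far above the $27,354/QALY threshold means
adjuvant atezolizumab is not cost-effective at list price.
"""

from lungcea import AnalysisConfig, GROUP_LABELS, run_group

config = AnalysisConfig()

print(f"{'population':<24}{'arm':<14}{'cost ($)':>12}{'LY':>7}{'QALY':>7}")
for group, label in GROUP_LABELS.items():
    res_a, res_b, cmp_ = run_group(config, group)
    for res in (res_a, res_b):
        print(f"{group:<24}{res.arm:<14}{res.cost:>12,.2f}{res.ly:>7.2f}{res.qaly:>7.2f}")
    print(f"  -> dC = ${cmp_.delta_cost:,.2f}, dQ = {cmp_.delta_qaly:.3f} QALYs, "
          f"ICER = ${cmp_.icer:,.2f}/QALY ({cmp_.classification})")
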