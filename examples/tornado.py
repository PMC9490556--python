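"""One-way sensitivity analysis (tornado) for the PD-L1 population.

Each tabulated parameter is swung to its low/high bound (+/-25% of baseline,
or the published range) with everything else at baseline, and the ICER is
recomputed.  Rows are ranked by spread; the drug price and the
progression-free utility should dominate.
"""

from lungcea import AnalysisConfig, run_tornado

tor = run_tornado(AnalysisConfig(), "pdl1")
base = tor["base_icer"].iloc[0]
print(f"base-case ICER: ${base:,.0f}/QALY\n")
print(f"{'parameter':<22}{'ICER @ low':>14}{'ICER @ high':>14}{'spread':>12}")
for _, row in tor.head(8).iterrows():
    print(f"{row.parameter:<22}{row.low_icer:>14,.0f}{row.high_icer:>14,.0f}"
          f"{row.spread:>12,.0f}")
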