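"""Structural-assumption sensitivity: how modelling conventions move LY/QALY.

The source publication leaves several conventions unstated (background
mortality handling, discount timing, half-cycle correction, how long
supportive care is charged).  This sweep evaluates every combination in the
documented option space for the PD-L1 population and prints the per-arm
discounted LY/QALY, so the spread attributable to conventions - roughly 5%
here - is visible next to the defaults.
"""

from lungcea import AnalysisConfig, convention_sweep

sweep = convention_sweep(AnalysisConfig(), "pdl1")
atezo = sweep[sweep.arm == "atezolizumab"]
print(f"{'mortality':<12}{'discount':<10}{'HCC':<7}{'BSC window':<12}"
      f"{'LY':>7}{'QALY':>7}{'cost ($)':>12}")
for _, r in atezo.iterrows():
    print(f"{r.mortality_mode:<12}{r.discount_timing:<10}{str(r.half_cycle_correction):<7}"
          f"{r.bsc_cost_window:<12}{r.ly:>7.3f}{r.qaly:>7.3f}{r.total_cost:>12,.0f}")
spread = 100 * (atezo.ly.max() - atezo.ly.min()) / atezo.ly.min()
print(f"\natezolizumab-arm LY spread across conventions: {spread:.1f}%")
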