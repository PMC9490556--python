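"""Evaluate the published parametric survival laws used to extrapolate the trial.

Prints, for each arm and endpoint of the PD-L1 population, the fitted family,
its parameters, the median survival time and the 10-year survivor fraction.
The OS medians exceed the trial's follow-up - that extrapolation beyond
observed data is exactly why the parametric families matter.
"""

from lungcea import default_group_survival, median_survival, survival_at

models = default_group_survival()["pdl1"]
rows = [
    ("atezolizumab", "PFS", models.atezolizumab_pfs),
    ("atezolizumab", "OS", models.atezolizumab_os),
    ("BSC", "PFS", models.bsc_pfs),
    ("BSC", "OS", models.bsc_os),
]

print(f"{'arm':<14}{'endpoint':<10}{'family':<13}{'median (mo)':>12}{'S(120 mo)':>11}")
for arm, endpoint, model in rows:
    med = median_survival(model)
    print(f"{arm:<14}{endpoint:<10}{model.family:<13}{med:>12.1f}"
          f"{survival_at(model, 120.0):>11.3f}")
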