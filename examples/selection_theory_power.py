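"""Apparent odds ratio and power gain from risk-score prioritisation.

For an undiscovered 1%-frequency risk allele with a true odds ratio of
2 in a disease of 1% prevalence, computes the allele frequency among
"super cases" and screened "super controls" selected on residual risk,
the inflated (apparent) odds ratio this induces, and the power of a
genome-wide-significance trend test for prioritised versus random
designs drawn from 10,000-case / 10,000-control pools.
"""

import numpy as np

from prioriseq import (
    DiseaseDesign,
    SelectionDesign,
    TestVariant,
    apparent_or,
    power_curve,
    qt_power_curve,
    selected_case_freq,
    selected_control_freq,
)

v = TestVariant(f_v=0.01, odds_ratio=2.0)

print("q (fraction kept)   f_case   f_control   apparent OR (true OR = 2)")
for V in (0.05, 0.25, 0.5):
    d = DiseaseDesign(K=0.01, V=V)
    for q in (0.1, 0.5, 1.0):
        fc = selected_case_freq(v, d, q)
        fx = selected_control_freq(v, d, q, screened=True)
        print(f"V={V:4.2f} q={q:4.2f}      {fc:.4f}   {fx:.4f}      "
              f"{apparent_or(fc, fx):.3f}")

print("\nSharper selection (small q) and better predictors (large V) inflate")
print("the apparent odds ratio, which is what drives the power gain.\n")

d = DiseaseDesign(K=0.01, V=0.25)
df = power_curve(
    v, d, SelectionDesign(controls_screened=True, alpha_sig=5e-8),
    pool_cases=10_000, pool_controls=10_000,
    N_grid=[1000, 2500, 5000, 10_000],
)
print(df[["N", "power_random", "power_prioritised"]].to_string(index=False))

qt = qt_power_curve(beta_v=0.2, f_v=0.01, V=0.05, pool=100_000,
                    N_grid=[5000, 20_000])
print("\nQuantitative trait (beta = 0.2 SD, V = 0.05): comparing residual")
print("extremes versus raw-trait extremes of a 100,000-person cohort:")
print(qt[["N", "power_random", "power_prioritised"]].to_string(index=False))
print("\nEven a predictor explaining 5% of variance adds measurable power.")
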