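"""Fit an LT50 dose-response curve to simulated heat-shock trials.

Generates survival outcomes at six shock temperatures (34-44 deg C) for
host caterpillars and adult parasitoids, fits the binomial-logistic
dose-response to each, and contrasts their median lethal temperatures.
"""

import aspentherm as at

host = at.simulate_heat_shock(
    at.HeatShockDesign(species="host", true_lt50=42.1, true_slope=-0.86,
                       n_per_temperature=200, seed=1)
)
parasitoid = at.simulate_heat_shock(
    at.HeatShockDesign(species="parasitoid", true_lt50=37.4, true_slope=-0.25,
                       n_per_temperature=200, seed=2)
)

fit_host = at.fit_logistic_survival(host)
fit_para = at.fit_logistic_survival(parasitoid)
diff, se, z = at.compare_lt50(fit_host, fit_para)

print(f"host       LT50 = {fit_host.lt50:6.2f} +/- {fit_host.lt50_se:.2f} C "
      f"(slope {fit_host.slope:+.3f} logit/C)")
print(f"parasitoid LT50 = {fit_para.lt50:6.2f} +/- {fit_para.lt50_se:.2f} C "
      f"(slope {fit_para.slope:+.3f} logit/C)")
print(f"difference      = {diff:.2f} +/- {se:.2f} C (z = {z:.1f})")
print()
print("The LT50 is the temperature at which half the individuals die after")
print("an acute 1 h heat shock; the ~4.7 C gap means adult parasitoids are")
print("markedly less heat-tolerant than the leaf-mining caterpillars.")
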