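"""Group-comparison statistics and the dose-to-concentration calculator."""

import numpy as np

import erythrokit as ek

# per-donor slow-cell percentages for three groups (synthetic donors)
rng = np.random.default_rng(42)
data = {
    "Control": rng.normal(0.45, 0.20, 10).clip(0),
    "PLAT": rng.normal(4.7, 1.88, 10).clip(0),
    "TAX": rng.normal(8.9, 3.29, 10).clip(0),
}
res = ek.compare_groups(data)
print(f"omnibus: {res.omnibus_test} statistic={res.omnibus_statistic:.1f} p={res.omnibus_p:.2e}")
print(f"post hoc: {res.posthoc_test}")
for comp in res.comparisons:
    print(f"  {comp.group:>9s} vs {comp.versus}: p_adj={comp.p_adjusted:.2e} {comp.tier}")

print()
for drug, dose in (("paclitaxel", 175.0), ("carboplatin", 400.0)):
    conc = ek.dose_to_concentration(ek.DoseSpec(dose_per_bsa=dose))
    print(
        f"{drug} {dose:.0f} mg/m²: blood {conc.blood_conc_ug_per_ml:.1f} µg/mL, "
        f"5e8 cells/mL suspension {conc.suspension_conc_ug_per_ml:.2f} µg/mL"
    )
hct = ek.suspension_hematocrit_percent(5e8, 84.6)
print(f"suspension hematocrit at 5e8 cells/mL and 84.6 fL: {hct:.2f}%")
print()
print("Stars follow the usual figure-legend convention (*, **, ***, **** at")
print("p <= 0.05 / 0.01 / 0.001 / 0.0001); the dose calculator converts a")
print("body-surface-area dose into the concentration a washed-cell suspension sees.")
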