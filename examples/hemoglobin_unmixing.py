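"""Spectrophotometric hemoglobin quantification.

Free hemoglobin released into the incubation medium is measured against a
whole-blood lysate at 540 nm (700 nm turbidity-corrected); the oxidation
state of the lysate is resolved into oxyHb / metHb / hemichrome fractions by
nonnegative least squares on the extinction matrix.
"""

import erythrokit as ek
from erythrokit.synth.spectra import simulate_absorbance

# supernatant of a treated sample: a small amount of released oxyHb
supernatant = simulate_absorbance(
    (1.0, 0.0, 0.0), total_hb=0.05, noise_sd=0.002, seed=1, dilution_factor=20.0
)
# whole-blood lysate reference with mild oxidative damage
lysate = simulate_absorbance(
    (0.90, 0.06, 0.04), total_hb=0.5, noise_sd=0.002, seed=2,
    dilution_factor=200.0, role="whole_lysate",
)

free = ek.free_hb_percent(supernatant, lysate)
species = ek.hb_species_fractions(lysate)

print(f"free hemoglobin: {free:.1f}% of the whole-blood lysate signal")
print("lysate species fractions:")
for name, fraction in species.fractions.items():
    print(f"  {name:<11s} {100 * fraction:5.1f}%")
print(f"unmixing residual: {species.residual:.2e}")
print()
print("Free Hb tracks membrane rupture (hemolysis); rising metHb and hemichrome")
print("fractions mark oxidative conversion of hemoglobin inside intact cells.")
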