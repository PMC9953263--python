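# erythrokit

Measurement analyses for quantifying damage to red blood cells (RBCs), as
inflicted for example by cytostatic chemotherapy drugs in vitro, together
with a synthetic-data generator that emulates every raw measurement so the
whole pipeline runs and is tested without any instrument data.

## Who this is for

Groups characterising RBC injury combine four bench assays whose raw outputs
need nontrivial reduction before they become comparable numbers:

1. **Laser-diffraction osmotic fragility test (OFT).** Scattered light
   intensity (SLI) at forward angles (0–12°) is recorded while the buffer
   osmolality is stepped from 300 down to 100 mOsmol. Swelling of intact
   cells raises low-angle SLI; lysis lowers SLI at every angle. The derived
   statistics are **H50** (osmolality at 50% lysis), the heterogeneity width
   **W = |H10 − H90|**, the hydrodynamic volume curve **MCV_osm** anchored to
   the hematology MCV at 300 mOsmol, and the **asphericity index**
   AI = 100 · 2√2 · SD(detrended isotonic SLI) / mean SLI, which falls
   sharply when discocytes spherize.
2. **Microfluidic transit velocimetry.** Cells are tracked through
   capillary-sized microchannels; per-cell velocities are normalised to the
   bulk flow (wide-channel mean) and the **slow-cell fraction** below the
   0.175 a.u. cutoff, the optional fast fraction, experiment-averaged
   probability densities, and the **channel occlusion rate** are computed.
3. **Spectrophotometry.** **Free hemoglobin** released into the medium is the
   turbidity-corrected (A540 − A700) ratio of supernatant to whole-blood
   lysate; oxyHb / metHb(Fe³⁺) / hemichrome fractions are unmixed from
   560/577/630 nm by nonnegative least squares on an extinction matrix.
4. **Hematology and flow cytometry.** MCV, RDW% (CV of volume) and **RDW-SD**
   (width of the volume histogram at 20% of peak height), normalised mean
   fluorescence intensity (MFI) with negative-control subtraction,
   quantile-gated Annexin-positive fractions, and the microparticle gate.

A group-comparison layer (D'Agostino–Pearson normality, then either one-way
ANOVA + Tukey HSD or Kruskal–Wallis + Dunn) and a dose-to-concentration
calculator (dose · S / V, with S = 1.81 m² body surface and V = 4.5 L blood)
round out the workflow.

The physics inside the generator is deliberately minimal but closed-form:
cells swell along the two-parameter van't Hoff law
V(osm) = v_s + (v₃₀₀ − v_s) · 300/osm, lyse instantly at a per-cell
threshold, and scatter in proportion to V^(2/3) with an angle-dependent
volume sensitivity, so every analysis result can be checked against the
generating parameters.

## Worked example

`examples/osmotic_fragility.py` simulates one control and one
paclitaxel-like recording (5000 cells, 1% SLI noise) and analyses them:

```
Control:
  H50 = 142.5 mOsmol   (osmolality at 50% lysis)
  W   = 23.2 mOsmol   (10%-90% lysis span, population heterogeneity)
  MCV_osm at 300/200 mOsmol = 90.0 / 92.1 fL
  asphericity index = 117%
TAX:
  H50 = 135.6 mOsmol   (osmolality at 50% lysis)
  W   = 24.1 mOsmol   (10%-90% lysis span, population heterogeneity)
  MCV_osm at 300/200 mOsmol = 84.6 / 91.5 fL
  asphericity index = 39%
```

The treated population was generated with a lysis threshold 6.4 mOsmol below
control, a swelling-prone nonsolvent volume (84.6 fL isotonic → 91.6 fL at
200 mOsmol) and a three-fold smaller orientation-oscillation amplitude — and
the analysis reads those numbers back off the simulated light-scattering
traces alone. The other scripts in `examples/` do the same for the
microfluidic, spectrophotometric, cytometric and statistical stages.

A thin CLI mirrors the stages
(`erythrokit simulate|oft|micro|spectro|hemocyto|compare|dose|run`); the
`run` subcommand executes a YAML-configured pipeline end to end.

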