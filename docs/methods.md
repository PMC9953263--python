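# Methods

This note documents the models behind `erythrokit`'s synthetic generators
and analyses, the parameters that matter, the numerical conventions, and the
limits of what the synthetic tests demonstrate.

## Osmotic fragility model

**Swelling.** Each cell is a two-parameter van't Hoff osmometer:
V(osm) = v_s + (v₃₀₀ − v_s) · (300 / osm), with isotonic volume v₃₀₀ (fL)
and osmotically inactive (nonsolvent) volume v_s. The taxane presets are
calibrated from two volumes: v₃₀₀ = 84.6 fL and V(200) = 91.6 fL give
v_s = 70.6 fL (`solve_nonsolvent_volume`). Lysis is instantaneous: a cell
stops scattering at every plateau whose osmolality is at or below its
per-cell threshold; thresholds are Gaussian per group (control mean
142 mOsmol, SD 8; the taxane groups are shifted down by 6.4 mOsmol). The
control mean is a configurable default — the assay only constrains shifts,
not the absolute scale.

**Scattering.** An intact cell of volume V contributes
v₃₀₀^(2/3) · (V/v₃₀₀)^((2/3)·g(θ)) to the SLI at detector angle θ, where the
volume-sensitivity profile g(θ) is 1 up to 4°, falls linearly to 0 at 8°,
and stays 0 to 12°. This encodes the instrument phenomenology — swelling
raises only the low-angle channels while lysis lowers every channel — and is
the package's instrument convention, shared by generator and analysis. Two
channels with *different* g are what makes lysis and swelling separable:
with per-plateau SLI ratios r_a (swelling channel, default 2.5°, g_a = 1)
and r_h (hemolysis channel, default 6°, g_h = 0.5) relative to the
300 mOsmol reference,

    intact fraction   L = r_h^(g_a/(g_a−g_h)) · r_a^(−g_h/(g_a−g_h))
    mean swelling     f = (r_a / r_h)^(1/(g_a−g_h))

and MCV_osm = MCV₃₀₀ · f^(3/2) (area → volume). Choosing two angles with
equal g is rejected as an error. The mapping from SLI to volume is a
documented convention validated against the generator, not a claim about
any particular instrument's internals.

**Orientation oscillations.** Cell tumbling is modelled as a per-sample
orientation factor 1 + (1 − q)·u with axis ratio q ∈ (0, 1] and u uniform on
[−1, 1] shared by the whole sample, so a discoid population (q ≈ 0.3)
produces strong SLI oscillations and spheres none; the peak-to-peak relative
amplitude is 2(1 − q). Within each plateau u is drawn in balanced antithetic
pairs (u and −u, shuffled), a variance-reduction choice that makes the
plateau-mean orientation factor exactly neutral, so plateau means reflect
only swelling and lysis while the oscillation statistics for the
asphericity index are unaffected. The asphericity index
AI = 100 · 2√2 · SD(linearly detrended isotonic trace) / mean equals
peak-to-peak over mean for a sinusoid; for the uniform orientation model its
absolute scale is model-specific, so AI is interpreted through ratios
(the treated-to-control fold change), which are scale-free.

**Schedule and estimation.** The default schedule steps 300 → 100 mOsmol in
10 mOsmol plateaus of 4 s at 100 samples/s (≥ 200 isotonic samples for AI).
The hemolysis curve is made monotone by pool-adjacent-violators (isotonic)
regression before thresholds are located by linear interpolation between
plateaus; H50/H10/H90 interpolation bias at 10 mOsmol spacing is ≈ 0.3
mOsmol. W is reported as the absolute span |H10 − H90| since it is a width.
For a zero-variance population W degenerates to a fraction of the plateau
spacing (the resolution floor). Noise is additive Gaussian per sample;
`noise_rel` scales it to a fraction of the isotonic mean SLI per angle.
MCV_osm is reported only while the estimated intact fraction is ≥ 5% — with
almost everything lysed the swelling channel carries no volume information —
and the 300 mOsmol point is pinned to the supplied reference MCV.

## Microfluidic transit model

Normalized velocities (1 a.u. = bulk flow) are drawn from a labelled
mixture: a main Gaussian near 1 (SD 0.30 for the control preset, 0.15 for
treated groups), a slow tail Normal(0.10, 0.03) truncated to (0, 0.175), and
an optional fast tail Normal(1.6, 0.15) truncated above 1.2. Slow-tail
weights follow the treated-group phenotypes (TAX 8.9%, PLAT 4.7%, TAX_PLAT
7.7%, RUBI 8.0%, PHOS 9.8%, RUBI_PHOS 8.9%); the fast-tail weight for the
taxane groups (1%) and the per-transit arrest probabilities (0.001–0.005,
chosen so a few-hundred-cell experiment occludes a realistic minority of a
16-channel chip) are package choices, as no counts are available for them.
A channel is occluded when any assigned cell arrests (Bernoulli per
transit), so the occlusion rate grows with channel load.

The tracker thresholds dark cells (Otsu by default) on a bright background,
gates connected components by area, and links detections frame-to-frame by
nearest neighbour within a displacement gate (ties: smallest displacement,
then lowest track id). Frames are 0-based with pixel centres at integer
coordinates. Per-track velocity is a Theil–Sen slope of x versus time
(robust to a single mis-detection), dropped below 3 frames. The rendered
stacks place cells fully inside the channel so centroids are unclipped;
defaults are 0.5 µm/pixel, 400 fps, 8-bit grayscale, anti-aliased ellipses.
Occlusion detection from trajectories flags tracks stationary within 2 px
for ≥ 100 consecutive frames.

Per-experiment velocity densities are histograms (default bin 0.025 a.u.)
whose grid always covers the data, so each integrates to exactly 1; the
group-level PDF is their pointwise mean ± SE. The slow fraction counts
velocities strictly below the cutoff (default 0.175 a.u.). The cutoff can
also be calibrated per control sample as the 0.45% empirical quantile — the
inverse of the cutoff's construction — and a fast cutoff defaults to the
mirrored 99.75th percentile when requested.

## Spectrophotometry

Free hemoglobin is 100 · [(A540 − A700) · dilution]_supernatant /
[(A540 − A700) · dilution]_lysate, clamped at 0; the 700 nm read, where
hemoglobin does not absorb, removes flat turbidity (the generator adds a
constant 0.1 OD offset at all wavelengths so this correction is exercised).
Species unmixing subtracts A700, then solves ε·c = A at 560/577/630 nm by
nonnegative least squares (NNLS rather than the exact 3×3 solve, since noise
can push the exact solution negative; both agree whenever the exact solution
is nonnegative). Matrices with condition number above 10⁶ and signal-free
spectra are rejected. The shipped extinction table (mM⁻¹ cm⁻¹ per heme, for
oxyHb / metHb / hemichrome at 540/560/577/630/700 nm) contains
literature-style defaults; it is configuration, and any matrix with the same
layout can be substituted.

## Hematology and cytometry

RDW-SD is read off a 1 fL histogram smoothed with a Gaussian kernel of one
bin width — the 20%-of-peak width is ill-defined on raw noisy histograms —
with linear interpolation of both flanks; multiple crossings use the widest
span with a warning, and a zero-variance sample returns exactly 0. For a
Gaussian volume distribution the width converges to 2√(2 ln 5)·σ ≈ 3.588 σ
(the one-bin smoothing inflates this by ≈ 0.5% at σ = 10 fL, well inside the
tolerance used in tests). MFI is the arithmetic mean of channel intensities
(matching the name), normalised as 100·(treated − negative)/(control −
negative); the construction is invariant to any affine gain applied to all
three tables. Positive-cell gating places the threshold at the 99.5th
percentile of an unstained control by default — a standard, explicit choice
where no rule is universal — so an unstained sample gated against itself
reads ≈ 0.5% by construction. The microparticle gate is an FSC upper bound
(or interval), calibrated externally (e.g. on 3 µm beads).

## Statistics and dose arithmetic

Normality is tested per group with D'Agostino–Pearson; one failing group —
or any group smaller than 8 values, below which the test is undefined —
switches the whole dataset to the nonparametric branch, matching the
one-decision-per-dataset convention. Parametric: one-way ANOVA with Tukey
HSD. Nonparametric: Kruskal–Wallis with Dunn's rank z-tests (tie-corrected,
Bonferroni-adjusted over the comparisons performed). Significance tiers
*, **, ***, **** at p ≤ 0.05, 0.01, 0.001, 0.0001. A fully constant dataset
short-circuits to "no differences" since no test statistic is defined.

The dose calculator reports blood concentration = dose · S / V (µg/mL, with
defaults S = 1.81 m², V = 4.5 L) and its rescaling by the suspension-to-
whole-blood cell-concentration ratio (5×10⁸ / 5×10⁹ per mL by default). It
deliberately asserts nothing beyond this arithmetic: published "final"
suspension concentrations for specific drugs do not follow from any single
documented scaling, so both conventions are reported as what they are. The
companion hematocrit check is 100 · cells/mL · MCV(fL) · 10⁻¹².

## Problem sizes and determinism

Default test/acceptance scales are desk-scale choices that keep estimator
noise well under the stated tolerances: 5000 cells per OFT recording (the
cuvette holds millions; H50 estimator bias ≈ 0.25 mOsmol and seed-to-seed SD
≈ 0.1 mOsmol at 1% SLI noise over 10 seeds), 20,000 velocities per transit
experiment, 20,000 cytometry events, 50,000 volumes for the RDW asymptotics.
Every generator takes an explicit seed and is bit-reproducible given (spec,
seed); the pipeline derives per-stage seeds from one root seed via
`numpy.random.SeedSequence`, and JSON outputs are written with sorted keys
so fixed-seed runs are byte-identical.

## What the synthetic tests do and do not show

Passing tests demonstrate that each analysis recovers the generating
parameters of the stated model at realistic noise — an internal-consistency
and correctness guarantee, not an instrument validation. Real recordings
contain drift, stirring transients, non-instantaneous lysis, ghost
scattering, and an SLI–volume relation set by diffraction physics rather
than the g(θ) convention; real velocity data contain focus loss and
cell–cell interactions the renderer omits (rigid ellipses, no deformation
inside channels, additive Gaussian camera noise only). Absolute asphericity
indices and occlusion rates are model-scale numbers; fold changes and
fractions are the transferable quantities. Heterogeneity effects beyond a
shared lysis SD (e.g. treatment-dependent widening of W) are not encoded in
the presets.
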