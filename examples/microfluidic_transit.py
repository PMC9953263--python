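"""Microfluidic transit velocimetry: tracking, slow-cell fractions, occlusions.

Renders a small microchannel image stack with programmed cells, recovers
their velocities with the tracker, then quantifies the slow-cell
subpopulation of a treated velocity mixture against the 0.175 a.u. cutoff.
"""

import numpy as np

import erythrokit as ek
from erythrokit.synth.micro import ProgrammedCell

# --- image-based tracking on a rendered stack -------------------------------
cells = [
    ProgrammedCell(i, entry_frame=25 * i, velocity_um_s=800.0 + 100.0 * i, y_px=6.0 + 6 * (i % 3))
    for i in range(4)
]
stack, truth = ek.render_microchannel_frames(cells, fps=400.0, pixel_size_um=0.5)
trajectories = ek.track_cells(stack)
velocities = ek.transit_velocities(trajectories, fps=400.0, pixel_size_um=0.5)
print(f"rendered {truth.cell_id.nunique()} cells, tracked {len(velocities)}")
print("recovered velocities (µm/s):", np.sort(velocities).round(1))

# --- subpopulation statistics on synthetic experiments ----------------------
datasets = []
for seed in range(5):
    # a few hundred transits per 16-channel chip, as in a bench experiment
    spec = ek.preset_population("TAX", n_cells=400, seed=seed)
    datasets.append(ek.simulate_velocity_dataset(spec, seed=seed))
res = ek.analyze_velocity_datasets(datasets)
print(f"\nTAX slow-cell fraction (v < {res.cutoff_slow} a.u.): {res.slow_fraction_pct:.1f}%")
print(f"per-experiment: {[round(x, 1) for x in res.per_experiment_slow_pct]}")
print(f"occluded channels: {res.occlusion_rate_pct:.0f}% ± {res.occlusion_se_pct:.0f}%")

control = np.random.default_rng(0).normal(1.0, 0.30, 20_000).clip(0)
cutoff = ek.calibrate_cutoff(control, tail_mass=0.0045)
print(f"\ncutoff calibrated from a control sample (0.45% tail): {cutoff:.3f} a.u.")
print("Slow cells transit microcapillary-sized channels at a fraction of the bulk")
print("flow speed; their share and the occlusion rate quantify microcirculatory risk.")
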