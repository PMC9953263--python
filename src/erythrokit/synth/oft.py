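"""Simulated laser-diffraction osmotic fragility recordings.

The assay lowers the buffer osmolality stepwise from 300 to 100 mOsmol while
scattered light intensity (SLI) is sampled continuously at a set of forward
angles.  Each intact cell contributes a projected-area term that follows the
van't Hoff swelling law, attenuated per angle by the shared volume-sensitivity
profile (:mod:`erythrokit.optics`); a cell lyses instantaneously when the
osmolality reaches its per-cell threshold and then stops scattering.  Cell
tumbling in the stirred cuvette is modelled as a per-sample orientation
factor 1 + (1 - q) * u with u uniform on [-1, 1] shared by the whole sample,
so a population of discocytes (q well below 1) produces the characteristic
SLI oscillations while spheres (q = 1) produce none.  Orientation values are
drawn in antithetic pairs within each plateau so the plateau-average
orientation factor is exactly neutral and plateau means reflect only swelling
and lysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..optics import ISOTONIC_OSM, angular_volume_sensitivity, vant_hoff_volume
from .population import CellPopulation

DEFAULT_ANGLES = (2.5, 6.0, 12.0)


def default_schedule(
    start: float = 300.0, stop: float = 100.0, step: float = 10.0, duration_s: float = 4.0
) -> list[tuple[float, float]]:
    """Stepwise osmolality schedule as (duration_s, osmolality) plateaus."""
    osms = np.arange(start, stop - 1e-9, -abs(step))
    return [(duration_s, float(o)) for o in osms]


@dataclass
class OFTRecording:
    """Per-angle SLI time series over an osmolality schedule."""

    schedule: list[tuple[float, float]]
    angles: tuple[float, ...]
    time_s: np.ndarray
    osmolality: np.ndarray  # per-sample plateau osmolality
    sli: np.ndarray  # (n_samples, n_angles), arbitrary units, >= 0
    sampling_rate: float
    lysed_truth: dict[float, float] | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def plateau_osms(self) -> np.ndarray:
        return np.array([osm for _, osm in self.schedule], dtype=float)

    def plateau_slices(self) -> list[tuple[float, slice]]:
        """(osmolality, sample slice) per plateau, in schedule order."""
        out = []
        start = 0
        for duration, osm in self.schedule:
            n = int(np.sum(self.osmolality == osm))
            # durations are stored for provenance; slicing uses the sample count
            out.append((osm, slice(start, start + n)))
            start += n
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time_s, "osmolality_mosmol": self.osmolality}
        for j, a in enumerate(self.angles):
            data[f"sli_{a:g}deg"] = self.sli[:, j]
        return pd.DataFrame(data)


def _plateau_samples(duration_s: float, sampling_rate: float) -> int:
    n = int(round(duration_s * sampling_rate))
    n = max(n, 2)
    return n + (n % 2)  # even, so antithetic orientation pairs balance exactly


def simulate_oft_recording(
    cells: CellPopulation,
    schedule: list[tuple[float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    angles: tuple[float, ...] = DEFAULT_ANGLES,
    sampling_rate: float = 100.0,
    noise_rel: float | None = None,
) -> OFTRecording:
    """Simulate one osmotic fragility recording of ``cells``.

    ``noise_sd`` is the SD of additive Gaussian noise in SLI units; pass
    ``noise_rel`` instead to scale the noise per angle to a fraction of that
    angle's isotonic mean SLI.  A cell is lysed at every plateau whose
    osmolality is at or below its ``lysis_osm``.
    """
    if len(cells) == 0:
        raise ConfigurationError("cannot simulate a recording of an empty population")
    schedule = list(schedule) if schedule is not None else default_schedule()
    osms = np.array([o for _, o in schedule], dtype=float)
    if osms[0] != ISOTONIC_OSM:
        raise ConfigurationError(
            f"schedule must start at the {ISOTONIC_OSM:g} mOsmol isotonic reference"
        )
    if np.any(np.diff(osms) >= 0):
        raise ConfigurationError("schedule osmolalities must be strictly decreasing")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    if noise_rel is not None and noise_sd:
        raise ConfigurationError("give either noise_sd or noise_rel, not both")

    rng = np.random.default_rng(seed)
    angles = tuple(float(a) for a in angles)
    g = np.array([angular_volume_sensitivity(a) for a in angles])
    area300 = cells.v300 ** (2.0 / 3.0)
    one_minus_q = 1.0 - cells.axis_ratio

    # per-angle noise SD, resolved after the isotonic sums are known
    if noise_rel is not None:
        intact0 = cells.lysis_osm < osms[0]
        t0 = np.array([np.sum(area300[intact0]) for _ in angles])
        noise_per_angle = noise_rel * t0
    else:
        noise_per_angle = np.full(len(angles), noise_sd)

    chunks_t, chunks_o, chunks_s = [], [], []
    lysed_truth: dict[float, float] = {}
    t_offset = 0.0
    for duration, osm in schedule:
        n_s = _plateau_samples(duration, sampling_rate)
        intact = cells.lysis_osm < osm
        lysed_truth[osm] = float(np.mean(cells.lysis_osm >= osm))
        vol = vant_hoff_volume(cells.v300[intact], cells.vs[intact], osm)
        swell = (vol / cells.v300[intact]) ** (2.0 / 3.0)
        contrib = area300[intact][:, None] * swell[:, None] ** g[None, :]
        total = contrib.sum(axis=0)  # (n_angles,)
        osc = (contrib * one_minus_q[intact][:, None]).sum(axis=0)

        half = rng.uniform(-1.0, 1.0, size=n_s // 2)
        u = np.concatenate([half, -half])
        rng.shuffle(u)

        sli = total[None, :] + u[:, None] * osc[None, :]
        if np.any(noise_per_angle > 0):
            sli = sli + rng.normal(0.0, 1.0, size=sli.shape) * noise_per_angle[None, :]
        np.maximum(sli, 0.0, out=sli)

        chunks_s.append(sli)
        chunks_o.append(np.full(n_s, osm))
        chunks_t.append(t_offset + np.arange(n_s) / sampling_rate)
        t_offset += n_s / sampling_rate

    return OFTRecording(
        schedule=schedule,
        angles=angles,
        time_s=np.concatenate(chunks_t),
        osmolality=np.concatenate(chunks_o),
        sli=np.vstack(chunks_s),
        sampling_rate=sampling_rate,
        lysed_truth=lysed_truth,
        seed=seed,
        meta={"group": cells.group_label, "n_cells": len(cells)},
    )
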