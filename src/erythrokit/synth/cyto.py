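"""Synthetic hematology histograms and flow-cytometry event tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from .population import CellPopulation


@dataclass
class VolumeHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"volume_fl": self.centers, "count": self.counts})


def simulate_volume_histogram(
    cells: CellPopulation | np.ndarray,
    bin_width: float = 1.0,
    measurement_sd: float = 0.0,
    seed: int | None = None,
) -> VolumeHistogram:
    """Histogram of isotonic cell volumes, as a hematology counter would bin them."""
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    volumes = cells.v300 if isinstance(cells, CellPopulation) else np.asarray(cells, float)
    if volumes.size == 0:
        raise ConfigurationError("no cells to histogram")
    if measurement_sd:
        volumes = volumes + np.random.default_rng(seed).normal(0, measurement_sd, volumes.size)
    lo = np.floor(volumes.min() / bin_width) * bin_width
    hi = np.ceil(volumes.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(volumes, bins=edges)
    return VolumeHistogram(bin_edges=edges, counts=counts)


@dataclass(frozen=True)
class CytometrySpec:
    """Log-normal FSC/SSC/FITC event model for one stained or unstained sample.

    Medians are in arbitrary detector units; ``sigma`` values are the SDs of
    the underlying log-intensities.  A ``positive_fraction`` subpopulation is
    brighter in FITC by ``positive_brightness``-fold (e.g. Annexin-positive
    cells); a ``microparticle_fraction`` of events is scaled down in FSC
    (vesicles below the 3 µm bead gate).
    """

    label: str = "sample"
    n_events: int = 20000
    stained: bool = True
    fsc_median: float = 1.0e5
    fsc_sigma: float = 0.15
    ssc_median: float = 2.0e4
    ssc_sigma: float = 0.25
    fitc_median: float = 1.0e3
    fitc_sigma: float = 0.35
    unstained_fitc_median: float = 20.0
    positive_fraction: float = 0.0
    positive_brightness: float = 10.0
    microparticle_fraction: float = 0.0
    microparticle_fsc_scale: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 1:
            raise ConfigurationError("n_events must be positive")
        for name in ("positive_fraction", "microparticle_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


def simulate_cytometry_events(spec: CytometrySpec) -> pd.DataFrame:
    """Event table with columns fsc, ssc, fitc; metadata in ``DataFrame.attrs``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    fsc = rng.lognormal(np.log(spec.fsc_median), spec.fsc_sigma, n)
    ssc = rng.lognormal(np.log(spec.ssc_median), spec.ssc_sigma, n)
    fitc_median = spec.fitc_median if spec.stained else spec.unstained_fitc_median
    fitc = rng.lognormal(np.log(fitc_median), spec.fitc_sigma, n)
    if spec.stained and spec.positive_fraction:
        pos = rng.random(n) < spec.positive_fraction
        fitc[pos] *= spec.positive_brightness
    if spec.microparticle_fraction:
        mp = rng.random(n) < spec.microparticle_fraction
        fsc[mp] *= spec.microparticle_fsc_scale
    events = pd.DataFrame({"fsc": fsc, "ssc": ssc, "fitc": fitc})
    events.attrs["label"] = spec.label
    events.attrs["stain"] = "stained" if spec.stained else "unstained-negative-control"
    return events
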