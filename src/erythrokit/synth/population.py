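"""Synthetic red-blood-cell populations.

Every downstream assay in the toolkit (osmotic fragility, microfluidic
transit, spectrophotometry, cytometry) consumes cells drawn from a
:class:`PopulationSpec`.  A spec declares, per physical trait, a (possibly
truncated) Gaussian; the transit velocity is a labelled mixture with a main
component near 1 a.u. plus optional slow and fast tails.  Presets encode the
phenotypes of the chemotherapy treatment groups: the taxane groups carry a
lowered lysis threshold, a swelling-prone nonsolvent fraction, a spherized
shape, and slow/fast velocity tails; the platinum/anthracycline/alkylator
groups mostly differ in the weight of the slow tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import ConfigurationError
from ..optics import solve_nonsolvent_volume

GROUP_LABELS = ("Control", "TAX", "PLAT", "TAX_PLAT", "RUBI", "PHOS", "RUBI_PHOS")


@dataclass(frozen=True)
class GaussianSpec:
    """A Gaussian trait distribution, optionally truncated to (lower, upper)."""

    mean: float
    sd: float = 0.0
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ConfigurationError(f"negative SD {self.sd} in trait distribution")
        if self.lower is not None and self.upper is not None and self.lower >= self.upper:
            raise ConfigurationError("truncation bounds must satisfy lower < upper")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0.0:
            out = np.full(n, self.mean, dtype=float)
            if self.lower is not None:
                out = np.maximum(out, self.lower)
            if self.upper is not None:
                out = np.minimum(out, self.upper)
            return out
        if self.lower is None and self.upper is None:
            return rng.normal(self.mean, self.sd, size=n)
        a = -np.inf if self.lower is None else (self.lower - self.mean) / self.sd
        b = np.inf if self.upper is None else (self.upper - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


@dataclass(frozen=True)
class MixtureComponent:
    """One labelled component of the transit-velocity mixture."""

    label: str
    weight: float
    dist: GaussianSpec


# velocity tails shared by all treated groups: the slow tail sits wholly
# below the 0.175 a.u. counting cutoff, the fast tail well above the main peak
SLOW_TAIL = GaussianSpec(0.10, 0.03, lower=0.0, upper=0.175)
FAST_TAIL = GaussianSpec(1.60, 0.15, lower=1.2)


def velocity_mixture(
    slow_weight: float = 0.0,
    fast_weight: float = 0.0,
    main: GaussianSpec = GaussianSpec(1.0, 0.30, lower=0.0),
    slow: GaussianSpec = SLOW_TAIL,
    fast: GaussianSpec = FAST_TAIL,
) -> tuple[MixtureComponent, ...]:
    """Build a main/slow/fast velocity mixture with the given tail weights."""
    comps = [MixtureComponent("main", 1.0 - slow_weight - fast_weight, main)]
    if slow_weight:
        comps.append(MixtureComponent("slow", slow_weight, slow))
    if fast_weight:
        comps.append(MixtureComponent("fast", fast_weight, fast))
    return tuple(comps)


@dataclass(frozen=True)
class PopulationSpec:
    """Generating distributions for one treatment group."""

    group_label: str
    n_cells: int
    seed: int = 0
    v300: GaussianSpec = GaussianSpec(90.0, 5.0, lower=40.0)
    #: nonsolvent volume as a fraction of the isotonic volume
    vs_fraction: GaussianSpec = GaussianSpec(0.95, 0.0, lower=0.05, upper=0.999)
    lysis_osm: GaussianSpec = GaussianSpec(142.0, 8.0, lower=1.0, upper=299.0)
    axis_ratio: GaussianSpec = GaussianSpec(0.30, 0.05, lower=0.02, upper=1.0)
    velocity: tuple[MixtureComponent, ...] = field(
        default_factory=lambda: velocity_mixture()
    )
    adhesion_propensity: float = 0.0
    esterase_activity: GaussianSpec = GaussianSpec(1.0, 0.05, lower=0.0, upper=1.0)
    ps_exposed_fraction: float = 0.01

    def __post_init__(self):
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be positive")
        weights = np.array([c.weight for c in self.velocity], dtype=float)
        if np.any(weights < 0):
            raise ConfigurationError("velocity mixture weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"velocity mixture weights sum to {weights.sum()!r}, expected 1"
            )
        if not 0.0 <= self.adhesion_propensity <= 1.0:
            raise ConfigurationError("adhesion_propensity must lie in [0, 1]")
        if not 0.0 <= self.ps_exposed_fraction <= 1.0:
            raise ConfigurationError("ps_exposed_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CellState:
    """Physical parameters of a single cell."""

    v300: float
    vs: float
    lysis_osm: float
    axis_ratio: float
    velocity_factor: float
    adhesion_propensity: float
    esterase_activity: float
    ps_exposed: bool


@dataclass
class CellPopulation:
    """Column-oriented container for a sampled population."""

    group_label: str
    v300: np.ndarray
    vs: np.ndarray
    lysis_osm: np.ndarray
    axis_ratio: np.ndarray
    velocity_factor: np.ndarray
    adhesion_propensity: np.ndarray
    esterase_activity: np.ndarray
    ps_exposed: np.ndarray
    velocity_component: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.v300)

    def cell(self, i: int) -> CellState:
        return CellState(
            v300=float(self.v300[i]),
            vs=float(self.vs[i]),
            lysis_osm=float(self.lysis_osm[i]),
            axis_ratio=float(self.axis_ratio[i]),
            velocity_factor=float(self.velocity_factor[i]),
            adhesion_propensity=float(self.adhesion_propensity[i]),
            esterase_activity=float(self.esterase_activity[i]),
            ps_exposed=bool(self.ps_exposed[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v300_fl": self.v300,
                "vs_fl": self.vs,
                "lysis_osm_mosmol": self.lysis_osm,
                "axis_ratio": self.axis_ratio,
                "velocity_au": self.velocity_factor,
                "adhesion_propensity": self.adhesion_propensity,
                "esterase_activity": self.esterase_activity,
                "ps_exposed": self.ps_exposed.astype(int),
                "velocity_component": self.velocity_component,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_label: str = "", seed=None):
        return cls(
            group_label=group_label,
            v300=frame["v300_fl"].to_numpy(float),
            vs=frame["vs_fl"].to_numpy(float),
            lysis_osm=frame["lysis_osm_mosmol"].to_numpy(float),
            axis_ratio=frame["axis_ratio"].to_numpy(float),
            velocity_factor=frame["velocity_au"].to_numpy(float),
            adhesion_propensity=frame["adhesion_propensity"].to_numpy(float),
            esterase_activity=frame["esterase_activity"].to_numpy(float),
            ps_exposed=frame["ps_exposed"].to_numpy(bool),
            velocity_component=frame["velocity_component"].to_numpy(str),
            seed=seed,
        )


def sample_population(spec: PopulationSpec, seed: int | None = None) -> CellPopulation:
    """Draw exactly ``spec.n_cells`` cells from the declared distributions.

    Bit-reproducible for a fixed (spec, seed); ``seed`` defaults to
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_cells
    v300 = spec.v300.sample(rng, n)
    vs = spec.vs_fraction.sample(rng, n) * v300
    lysis = spec.lysis_osm.sample(rng, n)
    q = spec.axis_ratio.sample(rng, n)

    weights = np.array([c.weight for c in spec.velocity])
    comp_idx = rng.choice(len(weights), size=n, p=weights / weights.sum())
    velocity = np.empty(n)
    labels = np.empty(n, dtype=object)
    for k, comp in enumerate(spec.velocity):
        mask = comp_idx == k
        velocity[mask] = comp.dist.sample(rng, int(mask.sum()))
        labels[mask] = comp.label
    velocity = np.maximum(velocity, 0.0)

    return CellPopulation(
        group_label=spec.group_label,
        v300=v300,
        vs=vs,
        lysis_osm=lysis,
        axis_ratio=q,
        velocity_factor=velocity,
        adhesion_propensity=np.full(n, spec.adhesion_propensity),
        esterase_activity=spec.esterase_activity.sample(rng, n),
        ps_exposed=rng.random(n) < spec.ps_exposed_fraction,
        velocity_component=labels.astype(str),
        seed=spec.seed if seed is None else seed,
    )


# van't Hoff calibration of the swelling-prone taxane phenotype: isotonic
# volume 84.6 fL swelling to 91.6 fL at 200 mOsmol gives vs = 70.6 fL
_TAX_V300 = 84.6
_TAX_VS_FRACTION = solve_nonsolvent_volume(_TAX_V300, 200.0, 91.6) / _TAX_V300

# spherized shape whose orientation-oscillation amplitude is one third of the
# control amplitude: 1 - q = (1 - 0.30) / 3
_TAX_AXIS_RATIO = 1.0 - (1.0 - 0.30) / 3.0

_TREATED_MAIN = GaussianSpec(1.0, 0.15, lower=0.0)

_GROUP_PRESETS: dict[str, dict] = {
    "Control": dict(),
    "TAX": dict(
        v300=GaussianSpec(_TAX_V300, 2.9, lower=40.0),
        vs_fraction=GaussianSpec(_TAX_VS_FRACTION, 0.0, lower=0.05, upper=0.999),
        lysis_osm=GaussianSpec(142.0 - 6.4, 8.0, lower=1.0, upper=299.0),
        axis_ratio=GaussianSpec(_TAX_AXIS_RATIO, 0.05, lower=0.02, upper=1.0),
        velocity=velocity_mixture(slow_weight=0.089, fast_weight=0.01, main=_TREATED_MAIN),
        adhesion_propensity=0.005,
        esterase_activity=GaussianSpec(0.75, 0.08, lower=0.0, upper=1.0),
        ps_exposed_fraction=0.06,
    ),
    "PLAT": dict(
        velocity=velocity_mixture(slow_weight=0.047, main=_TREATED_MAIN),
        adhesion_propensity=0.001,
        esterase_activity=GaussianSpec(0.85, 0.08, lower=0.0, upper=1.0),
        ps_exposed_fraction=0.03,
    ),
    "TAX_PLAT": dict(
        v300=GaussianSpec(_TAX_V300, 2.9, lower=40.0),
        vs_fraction=GaussianSpec(_TAX_VS_FRACTION, 0.0, lower=0.05, upper=0.999),
        lysis_osm=GaussianSpec(142.0 - 6.4, 8.0, lower=1.0, upper=299.0),
        axis_ratio=GaussianSpec(_TAX_AXIS_RATIO, 0.05, lower=0.02, upper=1.0),
        velocity=velocity_mixture(slow_weight=0.077, fast_weight=0.01, main=_TREATED_MAIN),
        adhesion_propensity=0.005,
        esterase_activity=GaussianSpec(0.70, 0.08, lower=0.0, upper=1.0),
        ps_exposed_fraction=0.05,
    ),
    "RUBI": dict(
        velocity=velocity_mixture(slow_weight=0.080, main=_TREATED_MAIN),
        adhesion_propensity=0.001,
        esterase_activity=GaussianSpec(0.95, 0.06, lower=0.0, upper=1.0),
        ps_exposed_fraction=0.04,
    ),
    "PHOS": dict(
        velocity=velocity_mixture(slow_weight=0.098, main=_TREATED_MAIN),
        adhesion_propensity=0.002,
        esterase_activity=GaussianSpec(0.85, 0.08, lower=0.0, upper=1.0),
        ps_exposed_fraction=0.03,
    ),
    "RUBI_PHOS": dict(
        lysis_osm=GaussianSpec(144.0, 8.0, lower=1.0, upper=299.0),
        velocity=velocity_mixture(slow_weight=0.089, main=_TREATED_MAIN),
        adhesion_propensity=0.003,
        esterase_activity=GaussianSpec(0.80, 0.08, lower=0.0, upper=1.0),
        ps_exposed_fraction=0.04,
    ),
}


def preset_population(group: str, n_cells: int = 5000, seed: int = 0, **overrides) -> PopulationSpec:
    """Spec for one of the treatment groups, with optional field overrides."""
    if group not in _GROUP_PRESETS:
        raise ConfigurationError(
            f"unknown group {group!r}; expected one of {GROUP_LABELS}"
        )
    spec = PopulationSpec(group_label=group, n_cells=n_cells, seed=seed, **_GROUP_PRESETS[group])
    if overrides:
        spec = replace(spec, **overrides)
    return spec
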