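"""Spectrophotometric hemoglobin quantification.

Two measurements are supported.  *Free hemoglobin* compares the
turbidity-corrected optical density at 540 nm of an incubation-medium
supernatant against a whole-blood lysate taken as 100%.  *Species unmixing*
resolves oxyhemoglobin, methemoglobin (Fe(III)) and hemichrome from the
optical densities at 560/577/630 nm via nonnegative least squares on a
molar-extinction matrix; the 700 nm read, where hemoglobin does not absorb,
is subtracted as a flat turbidity baseline.

The shipped extinction coefficients are literature-style defaults for
millimolar heme concentrations and a 1 cm path; they are configuration, not
measured constants, and any matrix with the same layout may be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import AnalysisError, ConfigurationError

WAVELENGTHS_NM = (540.0, 560.0, 577.0, 630.0, 700.0)
SPECIES = ("oxyhb", "methb", "hemichrome")

#: default molar extinction coefficients (mM^-1 cm^-1 per heme)
DEFAULT_EXTINCTION = pd.DataFrame(
    {
        "oxyhb": [14.1, 8.8, 15.4, 0.15, 0.0],
        "methb": [6.6, 4.2, 4.1, 3.9, 0.0],
        "hemichrome": [9.2, 8.1, 7.0, 1.2, 0.0],
    },
    index=pd.Index(WAVELENGTHS_NM, name="wavelength_nm"),
)

_UNMIX_WAVELENGTHS = (560.0, 577.0, 630.0)
_MAX_CONDITION = 1e6


@dataclass
class AbsorbanceSpectrum:
    """Optical densities at named wavelengths, with the applied dilution."""

    od: dict[float, float]
    dilution_factor: float = 1.0
    role: str = "supernatant"  # or "whole_lysate"

    def __post_init__(self):
        self.od = {float(w): float(v) for w, v in self.od.items()}
        if any(v < 0 for v in self.od.values()):
            raise ConfigurationError("optical densities must be nonnegative")
        if self.dilution_factor < 1:
            raise ConfigurationError("dilution_factor must be >= 1")

    def require(self, *wavelengths: float) -> None:
        missing = [w for w in wavelengths if w not in self.od]
        if missing:
            raise AnalysisError(f"spectrum lacks required wavelength(s) {missing} nm")

    def to_frame(self) -> pd.DataFrame:
        ws = sorted(self.od)
        return pd.DataFrame({"wavelength_nm": ws, "od": [self.od[w] for w in ws]})


@dataclass
class HbSpeciesResult:
    fractions: dict[str, float]
    residual: float
    concentrations: dict[str, float] = field(default_factory=dict)


def free_hb_percent(supernatant: AbsorbanceSpectrum, lysate: AbsorbanceSpectrum) -> float:
    """Free hemoglobin as a percentage of the whole-blood lysate signal.

    Uses the turbidity-corrected 540 nm optical density scaled by each
    spectrum's dilution factor; the lysate is the 100% reference.
    """
    for spec in (supernatant, lysate):
        spec.require(540.0, 700.0)
    sup = (supernatant.od[540.0] - supernatant.od[700.0]) * supernatant.dilution_factor
    lys = (lysate.od[540.0] - lysate.od[700.0]) * lysate.dilution_factor
    if lys <= 0:
        raise AnalysisError("lysate has no corrected 540 nm signal to reference against")
    return max(0.0, 100.0 * sup / lys)


def hb_species_fractions(
    spectrum: AbsorbanceSpectrum,
    extinction: pd.DataFrame | None = None,
    wavelengths: tuple[float, ...] = _UNMIX_WAVELENGTHS,
) -> HbSpeciesResult:
    """Species fractions by nonnegative least squares on a 700 nm-corrected spectrum."""
    ext = DEFAULT_EXTINCTION if extinction is None else extinction
    spectrum.require(*wavelengths, 700.0)
    try:
        a = ext.loc[list(wavelengths)].to_numpy(float)
    except KeyError as exc:
        raise ConfigurationError(f"extinction matrix lacks wavelength row: {exc}") from exc
    if np.linalg.cond(a) > _MAX_CONDITION:
        raise ConfigurationError("extinction matrix is ill-conditioned (cond > 1e6)")
    b = np.array([spectrum.od[w] - spectrum.od[700.0] for w in wavelengths])
    if np.linalg.norm(b) <= 1e-12:
        raise AnalysisError("corrected spectrum is all zero; no hemoglobin signal")
    conc, residual = nnls(a, b)
    total = conc.sum()
    if total <= 0:
        raise AnalysisError("unmixing yielded no positive species concentration")
    species = list(ext.columns)
    return HbSpeciesResult(
        fractions={s: float(c / total) for s, c in zip(species, conc)},
        residual=float(residual),
        concentrations={s: float(c) for s, c in zip(species, conc)},
    )
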