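"""Osmotic fragility analysis of laser-diffraction recordings.

From one :class:`~erythrokit.synth.oft.OFTRecording` this module derives

* the hemolysis curve (percent of cells lysed per osmolality plateau),
* the resistance summary H50 / H10 / H90 and the heterogeneity width
  W = |H10 - H90|,
* the hydrodynamic volume curve MCV_osm anchored to a reference MCV at
  300 mOsmol, and
* the asphericity index (AI), the normalised amplitude of the SLI
  oscillations at the isotonic plateau.

Lysis and swelling both move the raw SLI, so the hemolysis estimate divides
out a swelling factor obtained by comparing two channels with different
volume sensitivities (see :mod:`erythrokit.optics`): with per-plateau SLI
ratios r_a (swelling channel, exponent g_a) and r_h (hemolysis channel,
exponent g_h), the intact fraction is  L = r_h**(g_a/(g_a-g_h)) *
r_a**(-g_h/(g_a-g_h))  and the mean per-cell swelling factor is
f = (r_a/r_h)**(1/(g_a-g_h)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.signal import detrend

from .errors import AnalysisError
from .optics import ISOTONIC_OSM, angular_volume_sensitivity
from .synth.oft import OFTRecording

log = logging.getLogger(__name__)

_MIN_SENSITIVITY_GAP = 0.05
_RATIO_FLOOR = 1e-6


@dataclass(frozen=True)
class ResistanceSummary:
    h50: float
    h10: float
    h90: float
    w: float


@dataclass
class OsmoticResistanceResult:
    hemolysis_curve: pd.DataFrame
    h50: float
    h10: float
    h90: float
    w: float
    mcv_osm_curve: pd.DataFrame | None
    asphericity_index: float | None


def _angle_index(rec: OFTRecording, angle: float, what: str) -> int:
    for i, a in enumerate(rec.angles):
        if abs(a - angle) < 1e-9:
            return i
    raise AnalysisError(f"{what} angle {angle:g} deg not present in recording {rec.angles}")


def _plateau_means(rec: OFTRecording) -> tuple[np.ndarray, np.ndarray]:
    slices = rec.plateau_slices()
    osms = np.array([osm for osm, _ in slices])
    means = np.vstack([rec.sli[sl].mean(axis=0) for _, sl in slices])
    return osms, means


def _channel_ratios(rec, hemolysis_angle, swelling_angle):
    if not 1.0 <= hemolysis_angle <= 12.0:
        raise AnalysisError("hemolysis angle must lie in the 1-12 degree detector range")
    osms, means = _plateau_means(rec)
    if osms[0] != ISOTONIC_OSM:
        raise AnalysisError(f"recording lacks the {ISOTONIC_OSM:g} mOsmol reference plateau")
    ia = _angle_index(rec, swelling_angle, "swelling")
    ih = _angle_index(rec, hemolysis_angle, "hemolysis")
    ga = angular_volume_sensitivity(swelling_angle)
    gh = angular_volume_sensitivity(hemolysis_angle)
    if ga - gh < _MIN_SENSITIVITY_GAP:
        raise AnalysisError(
            "swelling and hemolysis channels need distinct volume sensitivities; "
            f"got g={ga:.2f} at {swelling_angle:g} deg and g={gh:.2f} at {hemolysis_angle:g} deg"
        )
    ref_a, ref_h = means[0, ia], means[0, ih]
    if ref_a <= 0 or ref_h <= 0:
        raise AnalysisError("zero SLI at the 300 mOsmol reference plateau")
    return osms, means[:, ia] / ref_a, means[:, ih] / ref_h, ga, gh


def _intact_and_swelling(ra, rh, ga, gh):
    """Per-plateau intact fraction L and mean swelling factor f."""
    gap = ga - gh
    valid = (ra > _RATIO_FLOOR) & (rh > _RATIO_FLOOR)
    L = np.zeros_like(ra)
    f = np.ones_like(ra)
    L[valid] = rh[valid] ** (ga / gap) * ra[valid] ** (-gh / gap)
    f[valid] = (ra[valid] / rh[valid]) ** (1.0 / gap)
    return np.clip(L, 0.0, None), f, valid


def lysed_fraction_curve(
    rec: OFTRecording,
    hemolysis_angle: float = 6.0,
    swelling_angle: float = 2.5,
    regularize: bool = True,
) -> pd.DataFrame:
    """Percent of cells lysed at each plateau, swelling-corrected.

    With ``regularize`` the curve is made monotone (nondecreasing with
    falling osmolality) by pool-adjacent-violators smoothing, which removes
    local inversions caused by noise.
    """
    osms, ra, rh, ga, gh = _channel_ratios(rec, hemolysis_angle, swelling_angle)
    L, _, _ = _intact_and_swelling(ra, rh, ga, gh)
    lysed = 100.0 * np.clip(1.0 - L, 0.0, 1.0)
    if regularize and len(lysed) > 1:
        lysed = isotonic_regression(lysed, increasing=True).x
        lysed = np.clip(lysed, 0.0, 100.0)
    return pd.DataFrame({"osmolality_mosmol": osms, "lysed_pct": lysed})


def _as_curve_arrays(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, pd.DataFrame):
        return curve["osmolality_mosmol"].to_numpy(float), curve["lysed_pct"].to_numpy(float)
    arr = np.asarray(curve, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1]
    raise AnalysisError("hemolysis curve must be a DataFrame or a sequence of (osm, pct) pairs")


def _threshold_osm(osm: np.ndarray, lysed: np.ndarray, level: float, name: str) -> float:
    if lysed[0] > level:
        raise AnalysisError(f"curve is already above {name} at its first plateau")
    above = np.nonzero(lysed >= level)[0]
    if len(above) == 0:
        raise AnalysisError(f"curve never reaches {name} ({level:g}% lysis)")
    i = above[0]
    if lysed[i] == level or i == 0:
        return float(osm[i])
    y0, y1 = lysed[i - 1], lysed[i]
    return float(osm[i - 1] + (osm[i] - osm[i - 1]) * (level - y0) / (y1 - y0))


def resistance_summary(curve) -> ResistanceSummary:
    """H50 / H10 / H90 by linear interpolation, plus the width W = |H10 - H90|."""
    osm, lysed = _as_curve_arrays(curve)
    order = np.argsort(-osm)  # decreasing osmolality
    osm, lysed = osm[order], lysed[order]
    h50 = _threshold_osm(osm, lysed, 50.0, "H50")
    h10 = _threshold_osm(osm, lysed, 10.0, "H10")
    h90 = _threshold_osm(osm, lysed, 90.0, "H90")
    return ResistanceSummary(h50=h50, h10=h10, h90=h90, w=abs(h10 - h90))


def mcv_osm_curve(
    rec: OFTRecording,
    mcv_300: float,
    hemolysis_angle: float = 6.0,
    swelling_angle: float = 2.5,
    min_intact: float = 0.05,
) -> pd.DataFrame:
    """Hydrodynamic volume per plateau, anchored to ``mcv_300`` at 300 mOsmol.

    The per-intact-cell swelling factor f (an area ratio) converts to a
    volume ratio as f**(3/2).  Plateaus whose estimated intact fraction falls
    below ``min_intact`` are dropped: with almost every cell lysed the
    swelling channel carries no volume information.
    """
    if mcv_300 <= 0:
        raise AnalysisError("reference MCV must be positive")
    osms, ra, rh, ga, gh = _channel_ratios(rec, hemolysis_angle, swelling_angle)
    L, f, valid = _intact_and_swelling(ra, rh, ga, gh)
    keep = valid & (L >= min_intact)
    vol = mcv_300 * f[keep] ** 1.5
    out = pd.DataFrame({"osmolality_mosmol": osms[keep], "mcv_osm_fl": vol})
    if len(out):
        out.iloc[0, out.columns.get_loc("mcv_osm_fl")] = mcv_300  # exact anchor
    return out


def asphericity_index(rec: OFTRecording, angle: float = 2.5, min_samples: int = 200) -> float:
    """AI (%) = 100 * 2*sqrt(2) * SD(detrended isotonic SLI) / mean SLI.

    For a sinusoidal oscillation this equals peak-to-peak amplitude over the
    mean; it is zero for a constant trace (spherical cells).
    """
    ia = _angle_index(rec, angle, "asphericity")
    for osm, sl in rec.plateau_slices():
        if osm == ISOTONIC_OSM:
            trace = rec.sli[sl, ia]
            break
    else:
        raise AnalysisError(f"recording lacks the {ISOTONIC_OSM:g} mOsmol plateau")
    if len(trace) < min_samples:
        raise AnalysisError(
            f"isotonic plateau has {len(trace)} samples; at least {min_samples} required"
        )
    mean = float(trace.mean())
    if mean <= 0:
        raise AnalysisError("zero mean SLI at the isotonic plateau")
    amp = 2.0 * np.sqrt(2.0) * float(np.std(detrend(trace)))
    return 100.0 * amp / mean


def analyze_recording(
    rec: OFTRecording,
    mcv_300: float | None = None,
    hemolysis_angle: float = 6.0,
    swelling_angle: float = 2.5,
) -> OsmoticResistanceResult:
    """Full osmotic-resistance readout of one recording."""
    curve = lysed_fraction_curve(rec, hemolysis_angle, swelling_angle)
    summary = resistance_summary(curve)
    mcv = None
    if mcv_300 is not None:
        mcv = mcv_osm_curve(rec, mcv_300, hemolysis_angle, swelling_angle)
    try:
        ai = asphericity_index(rec, angle=swelling_angle)
    except AnalysisError:
        log.warning("asphericity index unavailable for this recording")
        ai = None
    return OsmoticResistanceResult(
        hemolysis_curve=curve,
        h50=summary.h50,
        h10=summary.h10,
        h90=summary.h90,
        w=summary.w,
        mcv_osm_curve=mcv,
        asphericity_index=ai,
    )
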