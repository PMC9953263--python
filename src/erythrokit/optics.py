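"""Shared small-angle light-scattering conventions.

The laser-diffraction osmotic fragility assay records scattered light
intensity (SLI) at forward angles up to 12 degrees.  Swelling of intact
cells raises the intensity at low angles (roughly 1-6 degrees) while lysis
removes scatterers and lowers the intensity at every angle.  The toolkit
encodes this as a per-angle *volume sensitivity exponent* g(theta): the
contribution of an intact cell of volume V at angle theta is

    V300**(2/3) * (V / V300)**((2/3) * g(theta))

so g = 1 gives the full projected-area dependence and g = 0 gives a purely
count-proportional channel.  Both the generator and the analysis use the
same profile; two channels with different g are what makes lysis and
swelling separable.
"""

from __future__ import annotations

import numpy as np

#: isotonic reference osmolality of the assay buffer (mOsmol/kg)
ISOTONIC_OSM = 300.0

#: angle below which the volume sensitivity is full (degrees)
_FULL_ANGLE = 4.0
#: angle at and above which the volume sensitivity vanishes (degrees)
_ZERO_ANGLE = 8.0


def angular_volume_sensitivity(angle_deg: float | np.ndarray) -> float | np.ndarray:
    """Volume-sensitivity exponent g(theta) of the SLI channel at ``angle_deg``.

    Equals 1 for angles up to 4 degrees, falls linearly to 0 at 8 degrees and
    stays 0 out to the edge of the detector ring (12 degrees).
    """
    a = np.asarray(angle_deg, dtype=float)
    g = np.clip((_ZERO_ANGLE - a) / (_ZERO_ANGLE - _FULL_ANGLE), 0.0, 1.0)
    if np.isscalar(angle_deg):
        return float(g)
    return g


def vant_hoff_volume(v300, vs, osmolality):
    """Hydrodynamic cell volume under the two-parameter van't Hoff law.

    V(osm) = vs + (v300 - vs) * (300 / osm), with ``vs`` the osmotically
    inactive (nonsolvent) volume and ``v300`` the isotonic volume, both in fL.
    """
    return np.asarray(vs) + (np.asarray(v300) - np.asarray(vs)) * (
        ISOTONIC_OSM / np.asarray(osmolality, dtype=float)
    )


def solve_nonsolvent_volume(v_iso: float, osmolality: float, v_at_osm: float) -> float:
    """Nonsolvent volume implied by an isotonic volume and one swollen volume.

    Inverts the van't Hoff law given V(300) = ``v_iso`` and
    V(``osmolality``) = ``v_at_osm``.
    """
    r = ISOTONIC_OSM / float(osmolality)
    if r == 1.0:
        raise ValueError("swollen volume must be given at a non-isotonic osmolality")
    return (v_at_osm - r * v_iso) / (1.0 - r)
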