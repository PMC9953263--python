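"""Synthetic absorbance spectra of hemoglobin-species mixtures."""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from ..spectro import DEFAULT_EXTINCTION, AbsorbanceSpectrum


def simulate_absorbance(
    species_fractions,
    total_hb: float = 0.1,
    extinction=None,
    pathlength_cm: float = 1.0,
    turbidity_offset: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dilution_factor: float = 1.0,
    role: str = "supernatant",
) -> AbsorbanceSpectrum:
    """Linear Beer-Lambert mixture spectrum plus flat turbidity and noise.

    OD(lambda) = pathlength * total_hb * sum_s fraction_s * eps(lambda, s)
                 + turbidity_offset + noise,
    with ``total_hb`` the heme concentration in the cuvette (mM) and the
    extinction matrix in mM^-1 cm^-1 (defaults to the shipped table, all
    wavelengths including the hemoglobin-free 700 nm row).
    """
    ext = DEFAULT_EXTINCTION if extinction is None else extinction
    if isinstance(species_fractions, dict):
        fr = np.array([species_fractions.get(s, 0.0) for s in ext.columns], dtype=float)
    else:
        fr = np.asarray(species_fractions, dtype=float)
    if fr.shape != (len(ext.columns),):
        raise ConfigurationError(
            f"expected {len(ext.columns)} species fractions {tuple(ext.columns)}"
        )
    if np.any(fr < 0):
        raise ConfigurationError("species fractions must be nonnegative")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"species fractions sum to {fr.sum()!r}, expected 1")
    if total_hb < 0 or pathlength_cm <= 0:
        raise ConfigurationError("total_hb must be >= 0 and pathlength positive")

    od = pathlength_cm * total_hb * (ext.to_numpy(float) @ fr) + turbidity_offset
    if noise_sd:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    return AbsorbanceSpectrum(
        od={float(w): float(v) for w, v in zip(ext.index, od)},
        dilution_factor=dilution_factor,
        role=role,
    )
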