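"""Analytic x-ray tube spectrum model.

The polychromatic model is a Kramers bremsstrahlung continuum for a tungsten
anode, hardened by aluminum-equivalent inherent filtration, plus the
tungsten K characteristic lines when the tube voltage exceeds the K-edge.
Defaults follow the modeled scanner: 120 kVp with 10 mm Al-equivalent
filtration.  A monoenergetic mode (default 60 keV, a typical effective
energy for this beam) is provided for fast deterministic tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import ENERGY_MIN_KEV, material_mu

# tungsten K lines [keV] and relative intensities
_W_LINES = ((57.98, 0.25), (59.32, 0.45), (67.2, 0.22), (69.1, 0.08))
_W_K_EDGE = 69.5
_LINE_FRACTION = 0.08  # fraction of unfiltered continuum fluence in K lines


@dataclass(frozen=True)
class EnergySpectrum:
    """Discrete photon-fluence spectrum on keV bin centers."""

    energies: np.ndarray          # keV, strictly increasing
    weights: np.ndarray           # relative fluence, sums to 1
    kvp: float
    filtration_al_mm: float

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)
        if e.size != w.size or e.size == 0:
            raise ValueError("energies and weights must be non-empty, same length")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if e[-1] > self.kvp + 1e-9:
            raise ValueError("max energy exceeds tube voltage")

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))

    @property
    def is_monoenergetic(self) -> bool:
        return self.energies.size == 1


def build_spectrum(kvp: float = 120.0, filtration_al_mm: float = 10.0,
                   mode: str = "polychromatic", energy_kev: float = 60.0,
                   bin_width_kev: float = 2.0) -> EnergySpectrum:
    """Build a normalized tube spectrum.

    ``mode='monoenergetic'`` returns a single bin at ``energy_kev``;
    ``filtration_al_mm`` must be non-negative and ``kvp`` within [40, 150].
    """
    if not (40.0 <= kvp <= 150.0):
        raise ValueError("tube voltage must be within [40, 150] kVp")
    if filtration_al_mm < 0:
        raise ValueError("filtration cannot be negative")
    if mode == "monoenergetic":
        return EnergySpectrum(energies=np.array([float(energy_kev)]),
                              weights=np.array([1.0]),
                              kvp=kvp, filtration_al_mm=filtration_al_mm)
    if mode != "polychromatic":
        raise ValueError("mode must be 'polychromatic' or 'monoenergetic'")

    lo = ENERGY_MIN_KEV + bin_width_kev / 2.0
    energies = np.arange(lo, kvp, bin_width_kev)
    # Kramers photon fluence ~ (kvp - E) / E
    fluence = np.clip(kvp - energies, 0.0, None) / energies
    # characteristic K lines folded into the nearest continuum bin
    if kvp > _W_K_EDGE:
        line_total = _LINE_FRACTION * fluence.sum()
        for e_line, frac in _W_LINES:
            idx = int(np.argmin(np.abs(energies - e_line)))
            fluence[idx] += line_total * frac
    if filtration_al_mm > 0:
        _, _, _, mu_al = material_mu("aluminum", energies)
        fluence = fluence * np.exp(-mu_al * filtration_al_mm / 10.0)
    keep = fluence > fluence.max() * 1e-9
    energies, fluence = energies[keep], fluence[keep]
    return EnergySpectrum(energies=energies, weights=fluence / fluence.sum(),
                          kvp=kvp, filtration_al_mm=filtration_al_mm)
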