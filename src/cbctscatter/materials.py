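"""X-ray attenuation data for the phantom and detector materials.

Linear attenuation coefficients are split into photoelectric, Compton
(incoherent) and Rayleigh (coherent) components on a 2-keV energy grid
covering 10-150 keV.  The tables are generated from a compact physics
parameterization rather than shipped as external data files:

* Compton: exact free-electron Klein-Nishina total cross-section per
  electron times the electron density of the mixture.
* Rayleigh: per-atom cross-section proportional to ``Z**2.5 / E**2``.
* Photoelectric: per-atom cross-section proportional to ``Z**4.5 / E**3``.

The two power-law constants are anchored so that the water table reproduces
the standard tabulated values at 60 keV (total mass attenuation
0.2059 cm^2/g, of which 0.0065 cm^2/g is coherent).  Between 30 and
120 keV -- the range that matters for a 120 kVp beam -- the resulting water
curve agrees with standard compilations to a few percent.  Electron binding
(incoherent scatter functions), K-edges of heavy elements and anomalous
dispersion are not modeled; see docs/methods.md for the consequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# classical electron radius [cm] and derived Thomson cross-section [cm^2]
R_E_CM = 2.8179403262e-13
SIGMA_THOMSON = 8.0 * np.pi / 3.0 * R_E_CM**2
AVOGADRO = 6.02214076e23
ELECTRON_REST_KEV = 510.99895

# energy grid of the packaged tables [keV]
ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 150.0
ENERGY_STEP_KEV = 2.0
ENERGY_GRID = np.arange(ENERGY_MIN_KEV, ENERGY_MAX_KEV + 0.5 * ENERGY_STEP_KEV,
                        ENERGY_STEP_KEV)

# (Z, A) for the elements appearing in the material compositions
_ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "Al": (13, 26.982),
    "P": (15, 30.974), "S": (16, 32.06), "Cl": (17, 35.45),
    "Ar": (18, 39.948), "K": (19, 39.098), "Ca": (20, 40.078),
    "I": (53, 126.904), "Cs": (55, 132.905),
}

# anchor values for water at 60 keV [cm^2/g], standard tabulation
_WATER_TOTAL_60 = 0.2059
_WATER_COHERENT_60 = 0.0065

_PE_Z_EXP = 4.5
_PE_E_EXP = 3.0
_COH_Z_EXP = 2.5
_COH_E_EXP = 2.0

# The Z^4.5 law calibrated on light (tissue) elements overestimates the
# photoelectric cross-section of the heavy scintillator elements, whose
# effective Z-exponent is lower above the K edge.  Per-element factors anchor
# Cs and I to their standard above-K-edge cross-sections (~4 cm^2/g at
# 60 keV for CsI), giving a realistic flat-panel quantum efficiency.
_PE_CORRECTION = {"I": 0.31, "Cs": 0.32}


def klein_nishina_total(energy_kev: float | np.ndarray) -> float | np.ndarray:
    """Total Klein-Nishina cross-section per free electron [cm^2]."""
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    if np.any(k <= 0):
        raise ValueError("photon energy must be positive")
    t = 1.0 + 2.0 * k
    sigma = 2.0 * np.pi * R_E_CM**2 * (
        (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - np.log(t) / k)
        + np.log(t) / (2.0 * k)
        - (1.0 + 3.0 * k) / t**2
    )
    return sigma if sigma.shape else float(sigma)


# mass fractions; normalized on use.  Tissue mixes follow ICRU-style recipes,
# densities follow the tissue-equivalent electron-density plug set.
_COMPOSITIONS: dict[str, tuple[float, dict[str, float]]] = {
    "water": (1.000, {"H": 0.1119, "O": 0.8881}),
    "air": (0.001205, {"N": 0.755, "O": 0.232, "Ar": 0.013}),
    "muscle": (1.060, {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.710,
                       "Na": 0.001, "P": 0.002, "S": 0.003, "Cl": 0.001,
                       "K": 0.004}),
    "adipose": (0.950, {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278,
                        "Na": 0.001, "S": 0.001, "Cl": 0.001}),
    "liver": (1.070, {"H": 0.102, "C": 0.139, "N": 0.030, "O": 0.716,
                      "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002,
                      "K": 0.003}),
    "breast": (0.990, {"H": 0.106, "C": 0.332, "N": 0.030, "O": 0.527,
                       "Na": 0.001, "P": 0.001, "S": 0.002, "Cl": 0.001}),
    "lung_inhale": (0.200, {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749,
                            "Na": 0.002, "P": 0.002, "S": 0.003, "Cl": 0.003,
                            "K": 0.002}),
    "lung_exhale": (0.500, {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749,
                            "Na": 0.002, "P": 0.002, "S": 0.003, "Cl": 0.003,
                            "K": 0.002}),
    "trabecular_bone": (1.160, {"H": 0.085, "C": 0.404, "N": 0.058,
                                "O": 0.367, "Na": 0.001, "Mg": 0.001,
                                "P": 0.034, "S": 0.002, "Cl": 0.002,
                                "K": 0.001, "Ca": 0.045}),
    "dense_bone_800": (1.530, {"H": 0.056, "C": 0.235, "N": 0.050,
                               "O": 0.437, "Mg": 0.001, "P": 0.072,
                               "S": 0.003, "Ca": 0.146}),
    "dense_bone_1250": (1.820, {"H": 0.049, "C": 0.187, "N": 0.042,
                                "O": 0.438, "P": 0.091, "S": 0.003,
                                "Ca": 0.190}),
    "dense_bone_1750": (2.100, {"H": 0.041, "C": 0.150, "N": 0.033,
                                "O": 0.434, "P": 0.106, "S": 0.002,
                                "Ca": 0.234}),
    "aluminum": (2.699, {"Al": 1.0}),
    # CsI flat-panel scintillator
    "detector_scintillator": (4.510, {"Cs": 0.511, "I": 0.489}),
}


def _per_gram_sums(composition: dict[str, float]) -> tuple[float, float, float]:
    """Return (electrons/g / N_A, sum w Z^4.5/A, sum w Z^2.5/A)."""
    total = sum(composition.values())
    s_e = s_pe = s_coh = 0.0
    for sym, w in composition.items():
        z, a = _ELEMENTS[sym]
        f = (w / total) / a
        s_e += f * z
        s_pe += f * z**_PE_Z_EXP * _PE_CORRECTION.get(sym, 1.0)
        s_coh += f * z**_COH_Z_EXP
    return s_e, s_pe, s_coh


def _calibrate_constants() -> tuple[float, float]:
    """Anchor the photoelectric/coherent constants on water at 60 keV."""
    s_e, s_pe, s_coh = _per_gram_sums(_COMPOSITIONS["water"][1])
    incoh_60 = AVOGADRO * s_e * klein_nishina_total(60.0)
    c_coh = _WATER_COHERENT_60 / (AVOGADRO * s_coh)          # at 60 keV
    pe_60 = _WATER_TOTAL_60 - incoh_60 - _WATER_COHERENT_60
    if pe_60 <= 0:
        raise RuntimeError("water anchor inconsistent with Klein-Nishina")
    c_pe = pe_60 / (AVOGADRO * s_pe)                          # at 60 keV
    return c_pe, c_coh


_C_PE_60, _C_COH_60 = _calibrate_constants()


@dataclass(frozen=True)
class Material:
    """A homogeneous mixture with packaged attenuation tables.

    ``mu_table`` holds the linear attenuation components (photoelectric,
    Compton, Rayleigh) in 1/cm on :data:`ENERGY_GRID`.
    """

    name: str
    density: float  # g/cm^3
    composition: dict[str, float] = field(repr=False)
    mu_table: np.ndarray = field(repr=False)  # (n_energies, 3)

    @property
    def electron_density(self) -> float:
        """Electrons per cm^3."""
        s_e, _, _ = _per_gram_sums(self.composition)
        return self.density * AVOGADRO * s_e

    def mu_total(self, energy_kev: float | np.ndarray) -> float | np.ndarray:
        out = material_mu(self, np.atleast_1d(np.asarray(energy_kev, float)))
        total = out[3]
        return total if np.ndim(energy_kev) else float(total[0])


def _build_table(density: float, composition: dict[str, float]) -> np.ndarray:
    s_e, s_pe, s_coh = _per_gram_sums(composition)
    e = ENERGY_GRID
    incoh = density * AVOGADRO * s_e * klein_nishina_total(e)
    pe = density * AVOGADRO * s_pe * _C_PE_60 * (60.0 / e) ** _PE_E_EXP
    coh = density * AVOGADRO * s_coh * _C_COH_60 * (60.0 / e) ** _COH_E_EXP
    return np.column_stack([pe, incoh, coh])


def _build_registry() -> dict[str, Material]:
    reg = {}
    for name, (density, comp) in _COMPOSITIONS.items():
        total = sum(comp.values())
        comp = {k: v / total for k, v in comp.items()}
        reg[name] = Material(name=name, density=density, composition=comp,
                             mu_table=_build_table(density, comp))
    return reg


MATERIALS: dict[str, Material] = _build_registry()
MATERIAL_NAMES = tuple(MATERIALS)


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {', '.join(MATERIAL_NAMES)}"
        ) from None


def material_mu(material: Material | str, energy_kev):
    """Attenuation components (pe, compton, rayleigh, total) in 1/cm.

    Values are interpolated log-log between the 2-keV table bins.  Energies
    outside [10, 150] keV raise ``ValueError``.
    """
    mat = get_material(material) if isinstance(material, str) else material
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
        raise ValueError(
            f"energy outside table range [{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV"
        )
    loge = np.log(ENERGY_GRID)
    comps = []
    for j in range(3):
        logmu = np.log(mat.mu_table[:, j])
        comps.append(np.exp(np.interp(np.log(e), loge, logmu)))
    pe, compton, rayleigh = comps
    total = pe + compton + rayleigh
    if np.ndim(energy_kev) == 0:
        return float(pe[0]), float(compton[0]), float(rayleigh[0]), float(total[0])
    return pe, compton, rayleigh, total


def mu_table_fine(material_names: list[str], energies_kev: np.ndarray) -> np.ndarray:
    """Dense (n_materials, n_energies, 3) component table for transport kernels."""
    out = np.empty((len(material_names), energies_kev.size, 3))
    for i, name in enumerate(material_names):
        pe, co, ra, _ = material_mu(name, energies_kev)
        out[i, :, 0] = pe
        out[i, :, 1] = co
        out[i, :, 2] = ra
    return out
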