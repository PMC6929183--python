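"""Physical constants and unit conversions (CODATA-2014).

All downstream modules import from here so that closed-form oracles and the
numerical engines agree to machine precision regardless of which CODATA
release a user's other software assumes.

Working units across the package:

* geometry        : angstrom (Å)
* masses          : unified atomic mass units (amu)
* Cartesian Hessians : hartree / bohr**2 (the convention of QM program output)
* wavenumbers     : cm**-1
* molar energies  : kcal / mol
* temperature     : kelvin
"""

from __future__ import annotations

import math

# --- CODATA-2014 base constants (SI) ---
PLANCK_J_S = 6.626070040e-34        # h
HBAR_J_S = 1.054571800e-34          # h / 2π
BOLTZMANN_J_K = 1.38064852e-23      # k_B
AVOGADRO = 6.022140857e23           # N_A
SPEED_OF_LIGHT_CM_S = 2.99792458e10  # c, cm/s (exact)
AMU_KG = 1.660539040e-27
HARTREE_J = 4.359744650e-18
BOHR_M = 0.52917721067e-10
CAL_J = 4.184                        # thermochemical calorie (exact)

# --- derived conversions ---
BOHR_ANGSTROM = BOHR_M * 1e10

#: second radiation constant hc/k_B in cm·K; u = C2 * (wavenumber / T)
C2_CM_K = PLANCK_J_S * SPEED_OF_LIGHT_CM_S / BOLTZMANN_J_K  # 1.438777...

#: Boltzmann constant in kcal mol^-1 K^-1 (0.0019872036)
KB_KCAL_MOL_K = BOLTZMANN_J_K * AVOGADRO / (CAL_J * 1000.0)

#: sqrt(hartree/(bohr^2 amu)) expressed as an angular frequency, divided by
#: 2πc, gives wavenumbers: ν̃ [cm^-1] = HESSIAN_EIG_TO_CM * sqrt(λ) with λ the
#: mass-weighted Hessian eigenvalue in hartree/(bohr^2 amu).  ≈ 5140.49.
HESSIAN_EIG_TO_CM = math.sqrt(HARTREE_J / (AMU_KG * BOHR_M**2)) / (
    2.0 * math.pi * SPEED_OF_LIGHT_CM_S
)

#: 1 hartree/bohr^2 in N/m (≈ 1556.89); divide a spectroscopic force constant
#: in N/m by this to obtain atomic units.
HARTREE_PER_BOHR2_IN_N_M = HARTREE_J / BOHR_M**2

#: ħ^2 / (amu · kcal/mol) in Å^2 — the thermal-wavelength combination used by
#: the path-integral samplers: λ^2 = HBAR2_AMU_KCALMOL_A2 / (m · k_B T).
HBAR2_AMU_KCALMOL_A2 = (
    HBAR_J_S**2 / (AMU_KG * (CAL_J * 1000.0 / AVOGADRO))
) * 1e20

# default isotope masses (amu), most abundant / heavy substitution partners
ISOTOPE_MASSES = {
    "H": (1.00782503, 2.01410178),    # 1H / 2H
    "C": (12.0, 13.00335484),         # 12C / 13C
    "O": (15.99491462, 17.99915961),  # 16O / 18O
    "Cl": (34.96885268, 36.96590259),  # 35Cl / 37Cl
}


def force_constant_nm_to_au(k_n_per_m: float) -> float:
    """Convert a bond force constant from N/m to hartree/bohr^2."""
    return k_n_per_m / HARTREE_PER_BOHR2_IN_N_M
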