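"""Unit conventions and physical constants.

Internal conventions: lengths in Å, times in ps, energies in kcal/mol.
Number densities cross a nm boundary at reporting time (particles/nm³),
so the Å↔nm conversions are centralized here.
"""

import numpy as np

# lengths
A_PER_NM = 10.0
NM_PER_A = 0.1
A3_PER_NM3 = 1.0e3

# energies
KJ_PER_KCAL = 4.184

# Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

# 1 Å³ per molecule expressed in cm³/mol
A3_TO_CM3_PER_MOL = N_AVOGADRO * 1.0e-24

# Coulomb constant in kcal·Å/(mol·e²): 1/(4πε0) with AMBER-style units
COULOMB_KCAL_A_E2 = 332.0637

# diffusion: 1 Å²/ps = 1e-16 cm² / 1e-12 s = 1e-4 cm²/s = 10 × 1e-5 cm²/s
A2_PER_PS_TO_1E5_CM2_S = 10.0

# water geometry used by the rigid 3-site synthetic water
WATER_OH_BOND_A = 0.9572
WATER_HOH_ANGLE_DEG = 104.52


def per_A3_to_per_nm3(rho: float | np.ndarray) -> float | np.ndarray:
    """Convert a number density from 1/Å³ to 1/nm³."""
    return rho * A3_PER_NM3


def A3_to_cm3_per_mol(G: float | np.ndarray) -> float | np.ndarray:
    """Convert a per-molecule volume (Å³) to a molar volume (cm³/mol)."""
    return G * A3_TO_CM3_PER_MOL


def sigma_from_rmin(rmin: float) -> float:
    """LJ σ from the potential-minimum distance: σ = Rmin · 2^(−1/6)."""
    return rmin / 2.0 ** (1.0 / 6.0)


def rmin_from_sigma(sigma: float) -> float:
    """Inverse of :func:`sigma_from_rmin`."""
    return sigma * 2.0 ** (1.0 / 6.0)
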