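"""Pitzer ion-interaction model for 1:1 electrolytes.

Gives the experimental reference quantities against which simulated
Kirkwood-Buff activity derivatives are compared: the mean molal activity
coefficient γ±^(b), the molal activity derivative

    a′^(b) = 1 + ∂ln γ±^(b)/∂ln b,

and its conversion to the molar scale through the log-slope of the salt
number density with respect to molality,

    a′ = a′^(b) · ∂ln b/∂ln ρ_s.

For a 1:1 salt at molality m (ionic strength I = m):

    ln γ± = f^γ(I) + B^γ(I)·m + (3/2)·C^φ·m²
    f^γ   = −A_φ [ √I/(1 + b√I) + (2/b)·ln(1 + b√I) ]
    B^γ   = 2β⁰ + (2β¹/(α²I)) [ 1 − e^(−α√I) (1 + α√I − α²I/2) ]

with the conventional α = 2.0 and b = 1.2 (kg/mol)^½.  The molal
derivative is differentiated analytically; a finite-difference cross-check
lives in the test suite.

For a 1:1 electrolyte the salt-unit and cosolvent (indistinguishable-ion)
descriptions carry identical activity *coefficients and derivatives*;
only the activity itself differs by the factor a_s = 0.5·a_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator


@dataclass(frozen=True)
class PitzerParameters:
    """Ion-interaction constants for a 1:1 electrolyte at fixed temperature.

    beta0, beta1 : kg/mol   virial-style interaction coefficients
    Cphi         : kg²/mol² third-order coefficient
    Aphi         : Debye-Hückel limiting slope (0.392 at 298 K for water)
    alpha, b     : (kg/mol)^½ conventional model constants
    """

    beta0: float
    beta1: float
    Cphi: float
    Aphi: float
    alpha: float = 2.0
    b: float = 1.2

    def __post_init__(self):
        if self.alpha <= 0 or self.b <= 0:
            raise ValueError("alpha and b must be positive")


#: Potassium acetate at 298 K (Pitzer-Mayorga compilation for KC2H3O2).
POTASSIUM_ACETATE = PitzerParameters(beta0=0.1587, beta1=0.3251, Cphi=-0.00660, Aphi=0.392)

PRESETS = {"KOAc": POTASSIUM_ACETATE, "KCH3COO": POTASSIUM_ACETATE}

#: molar mass of potassium acetate, kg/mol
M_KOAC_KG_MOL = 0.0981423


def pitzer_ln_gamma(b_s, p: PitzerParameters):
    """ln of the mean molal activity coefficient γ±^(b) at molality ``b_s``."""
    m = np.asarray(b_s, dtype=float)
    if np.any(m <= 0):
        raise ValueError("molality must be positive")
    s = np.sqrt(m)  # √I for a 1:1 salt
    f_gamma = -p.Aphi * (s / (1 + p.b * s) + (2.0 / p.b) * np.log1p(p.b * s))
    x = p.alpha * s
    h = 1.0 - np.exp(-x) * (1.0 + x - 0.5 * x * x)
    B_gamma = 2.0 * p.beta0 + (2.0 * p.beta1 / (p.alpha ** 2 * m)) * h
    out = f_gamma + B_gamma * m + 1.5 * p.Cphi * m * m
    return out if out.ndim else float(out)


def _dlngamma_db(b_s, p: PitzerParameters):
    """Analytic ∂ln γ±^(b)/∂b for the 1:1 Pitzer expression."""
    m = np.asarray(b_s, dtype=float)
    s = np.sqrt(m)
    dfds = -p.Aphi * (1.0 / (1 + p.b * s) ** 2 + 2.0 / (1 + p.b * s))
    df_dm = dfds / (2.0 * s)
    # B^γ·m = 2β0·m + (2β1/α²)·h(α√m)
    x = p.alpha * s
    h_prime = np.exp(-x) * (2.0 * x - 0.5 * x * x)
    dBm_dm = 2.0 * p.beta0 + (2.0 * p.beta1 / p.alpha ** 2) * h_prime * p.alpha / (2.0 * s)
    return df_dm + dBm_dm + 3.0 * p.Cphi * m


def molal_activity_derivative(b_s, p: PitzerParameters):
    """Molal salt activity derivative a′^(b) = 1 + ∂ln γ±^(b)/∂ln b."""
    m = np.asarray(b_s, dtype=float)
    if np.any(m <= 0):
        raise ValueError("molality must be positive")
    out = 1.0 + m * _dlngamma_db(m, p)
    return out if out.ndim else float(out)


@dataclass
class DensityCurve:
    """Solution mass density vs. molality, with the salt molar mass.

    ``b`` in mol/kg, ``density`` in g/cm³ (solution mass density),
    ``molar_mass`` in kg/mol.  The derived salt *number* density is
    proportional to the molarity  c(b) = b·d(b)/(1 + b·M); proportionality
    constants cancel in every log-derivative.
    """

    b: np.ndarray
    density: np.ndarray
    molar_mass: float
    rho_w: float = 0.99705  # g/cm³, water at 298 K

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.b) <= 0):
            raise ValueError("molality grid must be strictly increasing")
        if np.any(self.density <= 0):
            raise ValueError("densities must be positive")
        self._interp = PchipInterpolator(self.b, self.density)
        if np.any(np.diff(self.molarity(self.b)) <= 0):
            raise ValueError("salt number density must increase with molality")

    @staticmethod
    def from_csv(path, molar_mass: float) -> "DensityCurve":
        df = pd.read_csv(path)
        return DensityCurve(df["b_molkg"].to_numpy(), df["density_gcm3"].to_numpy(), molar_mass)

    def mass_density(self, b_s):
        b = np.asarray(b_s, dtype=float)
        if np.any(b < self.b[0]) or np.any(b > self.b[-1]):
            raise ValueError("molality outside the density table range (no extrapolation)")
        return self._interp(b)

    def molarity(self, b_s):
        """Salt molarity in mol/L (∝ number density)."""
        b = np.asarray(b_s, dtype=float)
        # c = b·d/(1 + b·M): d in g/cm³ ≡ kg/L, M in kg/mol
        return b * self._interp(b) / (1.0 + b * self.molar_mass)

    def dlnb_dlnrho(self, b_s, rel_step: float = 1e-4) -> float:
        """∂ln b/∂ln ρ_s by central differences on the interpolated curve."""
        b = float(b_s)
        if not (self.b[0] <= b <= self.b[-1]):
            raise ValueError("molality outside the density table range")
        h = rel_step
        lo, hi = b * np.exp(-h), b * np.exp(h)
        lo = max(lo, self.b[0])
        hi = min(hi, self.b[-1])
        dlnrho = np.log(self.molarity(hi)) - np.log(self.molarity(lo))
        dlnb = np.log(hi) - np.log(lo)
        return float(dlnb / dlnrho)


def molal_to_molar_derivative(a_prime_molal: float, b_s: float,
                              density_curve: DensityCurve) -> float:
    """Convert a′^(b) to the molar-scale derivative a′ = a′^(b)·∂ln b/∂ln ρ_s."""
    return float(a_prime_molal) * density_curve.dlnb_dlnrho(b_s)


def molar_gamma(b_s: float, gamma_molal: float, density_curve: DensityCurve) -> float:
    """Mean molar activity coefficient γ± = (b·ρ_w/ρ_s)·γ±^(b).

    ρ_w in kg/L and ρ_s as molarity in mol/L makes the prefactor
    dimensionless per mole of salt.
    """
    rho_s = float(density_curve.molarity(b_s))
    return float(b_s) * density_curve.rho_w / rho_s * float(gamma_molal)


def salt_to_cosolvent(a_prime_salt):
    """Salt-unit → cosolvent derivative: the identity for 1:1 electrolytes."""
    return a_prime_salt


def cosolvent_to_salt_activity(a_c):
    """Activity values (not derivatives) convert as a_s = 0.5·a_c."""
    return 0.5 * a_c


def reference_table(b_values, p: PitzerParameters,
                    density_curve: DensityCurve | None = None) -> pd.DataFrame:
    """Experimental-reference table: γ±^(b), a′^(b) and (optionally) a′ molar."""
    rows = []
    for b in np.atleast_1d(np.asarray(b_values, dtype=float)):
        gamma = float(np.exp(pitzer_ln_gamma(b, p)))
        apb = float(molal_activity_derivative(b, p))
        row = {"b_s": b, "gamma_molal": gamma, "a_prime_molal": apb}
        if density_curve is not None:
            row["a_prime_molar"] = molal_to_molar_derivative(apb, b, density_curve)
            row["gamma_molar"] = molar_gamma(b, gamma, density_curve)
        rows.append(row)
    return pd.DataFrame(rows)


def synthetic_koac_density_curve() -> DensityCurve:
    """Synthetic stand-in for a literature potassium-acetate density table.

    Constructed so that the salt number density follows ρ_s ∝ b^(1/1.034)
    over b ∈ [0.1, 3] mol/kg, i.e. a constant molal→molar log-slope of
    1.034 — the behaviour implied by published molal/molar derivative
    pairs for this salt.  It is *synthetic*: the absolute densities are
    anchored at a plausible 1.025 g/cm³ for b = 0.5 but are not
    measurements.
    """
    slope = 1.0 / 1.034
    b = np.linspace(0.1, 3.0, 60)
    M = M_KOAC_KG_MOL
    K = 1.025 / (0.5 ** (slope - 1.0) * (1.0 + 0.5 * M))
    density = K * b ** (slope - 1.0) * (1.0 + b * M)
    return DensityCurve(b, density, M)
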