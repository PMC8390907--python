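"""Radial distribution functions and finite-size-corrected Kirkwood-Buff integrals.

Kirkwood-Buff (KB) theory links pair correlations to thermodynamic
derivatives.  For a closed (canonical) box the KB integral is estimated
with a finite-size kernel and a multiplicative tail factor,

    G_ij(R) = ∫₀^{2R} [ f_ij·g_ij(r) − 1 ] · 4πr² · (1 − 3x/2 + x³/2) dr,

with x = r/(2R) and, by default, R equal to a quarter of the box edge.
The factor f_ij rescales the RDF so that its tail averages to one; in a
closed system the raw tail deviates from 1 by O(1/N).

Electroneutrality forces the electrolyte to be treated as a binary mixture
of water and a *cosolvent* of indistinguishable ions.  The molar cosolvent
activity derivative follows from

    a′_c = 1 / (1 + ρ_c·(G_cc − G_cw)),
    G_cc = (2G₊₋ + G₊₊ + G₋₋)/4,   G_cw = G₊w + G₋w,

where ρ_c is the number density of ions (counting both signs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import SpeciesRoster, SyntheticTrajectory
from .units import A3_to_cm3_per_mol

DEFAULT_BIN_WIDTH_A = 0.05
#: finer default for parameterization-grade RDFs (peak fitting)
FINE_BIN_WIDTH_A = 0.02
#: fraction of [0, 2R] used to estimate the tail factor
DEFAULT_TAIL_WINDOW = 0.2


@dataclass
class RadialDistributionFunction:
    """Binned pair correlation g(r) for a labeled species pair in a closed box."""

    pair: tuple[str, str]
    r: np.ndarray          # bin centers, Å
    g: np.ndarray          # g^NVT(r)
    bin_width: float
    r_max: float
    n_frames: int

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        widths = np.diff(self.r)
        if widths.size and not np.allclose(widths, self.bin_width, rtol=1e-6):
            raise ValueError("bins must be uniform")


@dataclass(frozen=True)
class KBIntegralResult:
    pair: tuple[str, str]
    G_A3: float
    G_cm3mol: float
    R: float
    f: float


@dataclass
class CosolventState:
    """Cosolvent-level summary: ion number density and KB combinations."""

    rho_c: float           # 1/Å³
    G_cc: float            # Å³
    G_cw: float            # Å³
    a_prime_c: float | None = None


def minimum_image_distances(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    """All pairwise minimum-image distances between point sets a and b (Å)."""
    delta = a[:, None, :] - b[None, :, :]
    delta -= L * np.round(delta / L)
    return np.sqrt((delta ** 2).sum(axis=-1))


def compute_rdf_indices(traj: SyntheticTrajectory, idx_a: np.ndarray, idx_b: np.ndarray,
                        bin_width: float = DEFAULT_BIN_WIDTH_A,
                        r_max: float | None = None, same: bool = False,
                        pair: tuple[str, str] = ("A", "B")) -> RadialDistributionFunction:
    """RDF between two explicit atom index sets (see :func:`compute_rdf`)."""
    L = traj.box.edge_length
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-9:
        raise ValueError("r_max must not exceed half the box edge")
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    n_a, n_b = len(idx_a), len(idx_b)
    n_pairs = n_a * (n_a - 1) / 2.0 if same else n_a * n_b
    if n_pairs == 0:
        raise ValueError("empty species selection for the RDF pair")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)
    iu = np.triu_indices(n_a, k=1) if same else None
    for frame in traj.coords:
        d = minimum_image_distances(frame[idx_a], frame[idx_b], L)
        if same:
            d = d[iu]
        counts += np.histogram(d.ravel(), bins=edges)[0]
    counts /= traj.n_frames
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_pairs / traj.box.volume * shell_vol
    g = counts / ideal
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RadialDistributionFunction(pair, centers, g, bin_width,
                                      float(edges[-1]), traj.n_frames)


def compute_rdf(traj: SyntheticTrajectory, species_a: str, species_b: str,
                bin_width: float = DEFAULT_BIN_WIDTH_A,
                r_max: float | None = None) -> RadialDistributionFunction:
    """Shell-histogram RDF estimator with closed-system normalization.

    Uses minimum-image distances and the distinct-pair convention (self
    pairs excluded for identical species).  The ideal-gas normalization
    uses the closed-box density N/V, so for an uncorrelated solution the
    estimator averages to 1 on every bin with r below L/2.
    """
    idx_a = traj.select(species_a)
    idx_b = traj.select(species_b)
    return compute_rdf_indices(traj, idx_a, idx_b, bin_width, r_max,
                               same=(species_a == species_b),
                               pair=(species_a, species_b))


def tail_correction(rdf: RadialDistributionFunction,
                    window: float = DEFAULT_TAIL_WINDOW,
                    R: float | None = None) -> float:
    """Tail factor f = 1/mean(g) over the final ``window`` fraction of [0, 2R]."""
    if not 0 < window <= 1:
        raise ValueError("window must be a fraction in (0, 1]")
    two_R = 2.0 * R if R is not None else rdf.r_max
    mask = (rdf.r >= (1.0 - window) * two_R) & (rdf.r <= two_R)
    if not mask.any():
        raise ValueError("empty tail window")
    tail_mean = float(rdf.g[mask].mean())
    if tail_mean <= 0:
        raise ValueError("tail of g(r) is non-positive; cannot normalize")
    return 1.0 / tail_mean


def kb_integral(rdf: RadialDistributionFunction, R: float, f: float = 1.0) -> KBIntegralResult:
    """Finite-size-corrected KB integral by trapezoidal quadrature.

    Integrates [f·g(r) − 1]·4πr²·(1 − 3x/2 + x³/2) on the bin-center grid
    over [0, 2R], x = r/(2R).  The kernel weight is 1 at r = 0 and 0 at
    r = 2R.
    """
    two_R = 2.0 * R
    if rdf.r[-1] + rdf.bin_width / 2 < two_R - 1e-9:
        raise ValueError("rdf does not extend to 2R")
    mask = rdf.r <= two_R + 1e-12
    r = rdf.r[mask]
    g = rdf.g[mask]
    x = r / two_R
    kernel = 4.0 * np.pi * r ** 2 * (1.0 - 1.5 * x + 0.5 * x ** 3)
    integrand = (f * g - 1.0) * kernel
    # close the grid at the endpoints where the kernel vanishes/is exact
    r_full = np.concatenate([[0.0], r, [two_R]])
    y_full = np.concatenate([[(f * g[0] - 1.0) * 0.0], integrand, [0.0]])
    G = float(np.trapezoid(y_full, r_full))
    return KBIntegralResult(rdf.pair, G, float(A3_to_cm3_per_mol(G)), R, f)


def cosolvent_kb(G_pp: float, G_mm: float, G_pm: float,
                 G_pw: float, G_mw: float) -> tuple[float, float]:
    """Indistinguishable-ion combinations: G_cc = (2G₊₋+G₊₊+G₋₋)/4, G_cw = G₊w+G₋w."""
    G_cc = (2.0 * G_pm + G_pp + G_mm) / 4.0
    G_cw = G_pw + G_mw
    return G_cc, G_cw


def activity_derivative_from_kb(rho_c: float, G_cc: float, G_cw: float) -> float:
    """Molar cosolvent activity derivative a′_c = 1/(1 + ρ_c(G_cc − G_cw))."""
    denom = 1.0 + rho_c * (G_cc - G_cw)
    if denom <= 0:
        raise ValueError("non-positive KB denominator: thermodynamically invalid input")
    return 1.0 / denom


def replica_activity_derivative(traj: SyntheticTrajectory, cation: str, anion: str,
                                water: str | None, bin_width: float = DEFAULT_BIN_WIDTH_A,
                                R: float | None = None,
                                tail_window: float = DEFAULT_TAIL_WINDOW) -> CosolventState:
    """Full single-replica chain: RDFs → tail factors → KB integrals → a′_c."""
    L = traj.box.edge_length
    if R is None:
        R = L / 4.0
    pairs = {"pp": (cation, cation), "mm": (anion, anion), "pm": (cation, anion)}
    if water is not None:
        pairs["pw"] = (cation, water)
        pairs["mw"] = (anion, water)
    G = {}
    for key, (a, b) in pairs.items():
        rdf = compute_rdf(traj, a, b, bin_width=bin_width, r_max=2.0 * R)
        f = tail_correction(rdf, window=tail_window, R=R)
        G[key] = kb_integral(rdf, R, f).G_A3
    G_cc, G_cw = cosolvent_kb(G["pp"], G["mm"], G["pm"],
                              G.get("pw", 0.0), G.get("mw", 0.0))
    n_ions = len(traj.select(cation)) + len(traj.select(anion))
    rho_c = n_ions / traj.box.volume
    return CosolventState(rho_c, G_cc, G_cw,
                          activity_derivative_from_kb(rho_c, G_cc, G_cw))


def activity_pipeline(replicas: list[SyntheticTrajectory], roster: SpeciesRoster,
                      bin_width: float = DEFAULT_BIN_WIDTH_A,
                      R: float | None = None,
                      tail_window: float = DEFAULT_TAIL_WINDOW) -> dict:
    """Mean ± SEM of a′_c over independent replica trajectories.

    Mirrors the replica bookkeeping of multi-run production simulations:
    each replica is analyzed independently (RDFs for +−, ++, −−, +w, −w,
    tail factors, KB integrals at R = box/4), then the derivative is
    averaged with its standard error of the mean.
    """
    if len(replicas) < 2:
        raise ValueError("at least 2 replicas required for a SEM")
    cations = roster.labels_with_role("cation")
    anions = roster.labels_with_role("anion")
    waters = roster.labels_with_role("water")
    if len(cations) != 1 or len(anions) != 1:
        raise ValueError("pipeline expects one cation and one anion species")
    water = waters[0] if waters else None
    values = [replica_activity_derivative(t, cations[0], anions[0], water,
                                          bin_width=bin_width, R=R,
                                          tail_window=tail_window).a_prime_c
              for t in replicas]
    values = np.asarray(values, dtype=float)
    sem = float(values.std(ddof=1) / np.sqrt(len(values)))
    return {"a_prime_c": float(values.mean()), "sem": sem,
            "replica_values": values.tolist(), "n_replicas": len(values)}
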