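"""Lennard-Jones pair-parameter optimization for cation⋯carboxylate contacts.

A single unlike-pair parameter, R_min for the K⁺⋯carboxylate-oxygen LJ
potential, is scanned via a multiplicative scaling factor applied to its
Lorentz-Berthelot value.  Candidates are scored on two experimental
anchors: (i) the electrolyte activity derivative must stay within a
relative band (default ±7%) of its reference value at every concentration,
and (ii) among surviving candidates the winner minimizes the mean unsigned
relative deviation between the simulated first-peak position of per-site
cation-oxygen RDFs and the corresponding crystal-structure distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .kirkwood_buff import RadialDistributionFunction
from .synthetic import ContactSiteTable
from .units import COULOMB_KCAL_A_E2, KJ_PER_KCAL, rmin_from_sigma, sigma_from_rmin


@dataclass(frozen=True)
class LJPairParameters:
    """12-6 pair parameters (plus charges, for full pair-energy evaluation).

    Rmin_ij in Å is the potential-minimum distance; eps_ij in kcal/mol the
    well depth; q_i, q_j in elementary charges.
    """

    Rmin_ij: float
    eps_ij: float
    q_i: float = 0.0
    q_j: float = 0.0

    def __post_init__(self):
        if self.Rmin_ij <= 0:
            raise ValueError("Rmin must be positive")
        if self.eps_ij < 0:
            raise ValueError("eps must be non-negative")


@dataclass(frozen=True)
class PeakFit:
    """Gaussian fit of an RDF first peak; ``r_sim`` is the fitted mean (Å)."""

    r_sim: float
    sd: float
    amplitude: float
    window: tuple[float, float]
    baseline: float = 0.0
    method: str = "gaussian"


@dataclass
class ScanCandidate:
    """One scaling-factor candidate with its measured observables.

    ``a_prime`` maps concentration label → (value, sem); ``r_sim`` maps
    site_id → fitted peak position (Å).
    """

    f: float
    Rmin: float
    a_prime: dict = field(default_factory=dict)
    r_sim: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.f <= 0:
            raise ValueError("scaling factor must be positive")


def lorentz_berthelot(Rmin_ii: float, Rmin_jj: float,
                      eps_ii: float, eps_jj: float) -> LJPairParameters:
    """Combination rules: arithmetic mean of Rmin, geometric mean of eps."""
    if Rmin_ii <= 0 or Rmin_jj <= 0 or eps_ii < 0 or eps_jj < 0:
        raise ValueError("invalid self-interaction parameters")
    return LJPairParameters((Rmin_ii + Rmin_jj) / 2.0, float(np.sqrt(eps_ii * eps_jj)))


def apply_scaling(f: float, Rmin_LB: float) -> float:
    """Scaled pair distance Rmin = f · Rmin_LB."""
    if f <= 0:
        raise ValueError("scaling factor must be positive")
    return f * Rmin_LB


def lj_potential(r, pair: LJPairParameters, include_coulomb: bool = False):
    """12-6 pair energy ε[(Rmin/r)¹² − 2(Rmin/r)⁶] (+ Coulomb), kcal/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    s = (pair.Rmin_ij / r) ** 6
    v = pair.eps_ij * (s * s - 2.0 * s)
    if include_coulomb:
        v = v + COULOMB_KCAL_A_E2 * pair.q_i * pair.q_j / r
    return v if v.ndim else float(v)


def _gaussian_baseline(r, amp, mu, sd, c):
    return amp * np.exp(-0.5 * ((r - mu) / sd) ** 2) + c


def fit_first_peak(rdf: RadialDistributionFunction) -> PeakFit:
    """Position of the first RDF peak from a Gaussian + baseline fit.

    The fit window runs from the left flank where g first exceeds half the
    peak value to the first local minimum after the peak; fitting a curve
    rather than taking the maximal bin makes the position robust to bin
    noise.  Degenerate peaks (fewer than 5 informative bins, e.g. a
    zero-noise delta spike) fall back to the intensity-weighted centroid
    of the window.
    """
    g, r = rdf.g, rdf.r
    if len(g) < 3:
        raise ValueError("rdf too short for peak detection")
    # smooth only for window detection; the fit uses raw bins
    kernel_w = max(1, min(5, len(g) // 10) | 1)
    smooth = np.convolve(g, np.ones(kernel_w) / kernel_w, mode="same")
    i_peak = int(np.argmax(smooth))
    peak_val = smooth[i_peak]
    tail_level = float(np.median(smooth[len(smooth) // 2:]))
    if i_peak in (0, len(g) - 1) or peak_val <= 1.05 * max(tail_level, 1e-12):
        raise ValueError("no peak detected in the RDF")
    half = peak_val / 2.0
    left = i_peak
    while left > 0 and smooth[left - 1] >= half:
        left -= 1
    right = i_peak
    while right < len(g) - 1 and smooth[right + 1] <= smooth[right]:
        right += 1
    window = (float(r[left]), float(r[right]))
    rw, gw = r[left:right + 1], g[left:right + 1]
    informative = int((gw > 0).sum())
    if informative >= 5:
        p0 = [float(g[i_peak]), float(r[i_peak]),
              max(rdf.bin_width, (rw[-1] - rw[0]) / 4.0), float(gw.min())]
        try:
            popt, _ = curve_fit(_gaussian_baseline, rw, gw, p0=p0, maxfev=10000)
            amp, mu, sd, c = popt
            sd = abs(float(sd))
            if window[0] <= mu <= window[1] and sd > 0:
                return PeakFit(float(mu), sd, float(amp), window, float(c), "gaussian")
        except RuntimeError:
            pass
    weights = np.clip(gw - gw.min(), 0.0, None)
    if weights.sum() <= 0:
        raise ValueError("peak fit failed: no intensity in window")
    mu = float(np.average(rw, weights=weights))
    return PeakFit(mu, float(rdf.bin_width), float(gw.max()), window,
                   float(gw.min()), "centroid")


def site_deviation(r_sim: float, r_cryst: float) -> float:
    """Unsigned relative deviation |r_sim − r_cryst| / r_cryst."""
    if r_cryst <= 0:
        raise ValueError("r_cryst must be positive")
    return abs(r_sim - r_cryst) / r_cryst


def select_optimal(candidates: list[ScanCandidate], reference: dict,
                   sites: ContactSiteTable, band: float = 0.07) -> ScanCandidate:
    """Pick the scaling factor satisfying the activity band with the best
    crystal-distance agreement.

    A candidate survives if |a′ − a′_ref|/a′_ref ≤ band at *every*
    concentration present in ``reference``; among survivors the winner has
    minimal mean unsigned site deviation, ties broken toward smaller f.
    The band comparison is a strict ≤ on unrounded values.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    survivors = []
    for cand in candidates:
        ok = True
        for conc, a_ref in reference.items():
            if conc not in cand.a_prime:
                raise ValueError(f"candidate f={cand.f} lacks a′ at concentration {conc!r}")
            value = cand.a_prime[conc][0]
            if abs(value - a_ref) / a_ref > band:
                ok = False
                break
        if ok:
            survivors.append(cand)
    if not survivors:
        raise ValueError("no candidate within the activity-derivative band")
    r_cryst = {s.site_id: s.r_cryst for s in sites.sites}

    def mean_dev(c: ScanCandidate) -> float:
        devs = [site_deviation(c.r_sim[sid], rc) for sid, rc in r_cryst.items()]
        return float(np.mean(devs))

    return min(survivors, key=lambda c: (mean_dev(c), c.f))


def site_peak_positions(traj, sites: ContactSiteTable, cation_species: str = "K",
                        bin_width: float = 0.001, r_max: float = 5.0) -> dict:
    """Fitted first-peak position of each site's carboxylate-O⋯cation RDF.

    Each contact site is matched to its protein atom by residue number and
    oxygen name; the RDF against the cation population is peak-fitted and
    the fitted mean returned per site_id.
    """
    from .kirkwood_buff import compute_rdf_indices

    cat_idx = traj.select(cation_species)
    out = {}
    for site in sites.sites:
        mask = ((traj.species == "protein") & (traj.resnums == site.resnum)
                & (traj.names == site.oxygen_name))
        o_idx = np.flatnonzero(mask)
        if o_idx.size == 0:
            raise ValueError(f"contact site {site.site_id}: atom not found")
        rdf = compute_rdf_indices(traj, o_idx, cat_idx, bin_width=bin_width,
                                  r_max=r_max, pair=(site.oxygen_name, cation_species))
        out[site.site_id] = fit_first_peak(rdf).r_sim
    return out


def load_candidates(manifest_csv, site_fits_csv=None) -> list[ScanCandidate]:
    """Read candidates from CSV.

    ``manifest_csv`` columns: f, concentration, a_prime, sem.
    ``site_fits_csv`` columns: f, site_id, r_sim.
    """
    import pandas as pd

    mani = pd.read_csv(manifest_csv)
    cands: dict[float, ScanCandidate] = {}
    for row in mani.itertuples():
        f = float(row.f)
        cand = cands.setdefault(f, ScanCandidate(f=f, Rmin=getattr(row, "Rmin", f)))
        cand.a_prime[str(row.concentration)] = (float(row.a_prime), float(row.sem))
    if site_fits_csv is not None:
        fits = pd.read_csv(site_fits_csv)
        for row in fits.itertuples():
            cands[float(row.f)].r_sim[int(row.site_id)] = float(row.r_sim)
    return [cands[f] for f in sorted(cands)]


DIALECTS = ("rmin-eps", "sigma-eps-kj")


def export_pair_override(Rmin: float, eps: float, path, dialect: str = "rmin-eps",
                         pair: tuple[str, str] = ("K+", "O2")) -> None:
    """Write a pair-specific nonbonded override file.

    ``rmin-eps``: Rmin in Å, eps in kcal/mol (AMBER-style NBFIX table).
    ``sigma-eps-kj``: σ = Rmin·2^(−1/6) in Å, eps in kJ/mol.
    """
    if Rmin <= 0 or eps < 0:
        raise ValueError("parameters must be positive")
    if dialect == "rmin-eps":
        payload = {"dialect": dialect, "atom_i": pair[0], "atom_j": pair[1],
                   "Rmin_A": Rmin, "eps_kcalmol": eps}
    elif dialect == "sigma-eps-kj":
        payload = {"dialect": dialect, "atom_i": pair[0], "atom_j": pair[1],
                   "sigma_A": sigma_from_rmin(Rmin), "eps_kJmol": eps * KJ_PER_KCAL}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def parse_pair_override(path) -> tuple[float, float]:
    """Round-trip reader for :func:`export_pair_override` → (Rmin Å, eps kcal/mol)."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload["dialect"] == "rmin-eps":
        return payload["Rmin_A"], payload["eps_kcalmol"]
    if payload["dialect"] == "sigma-eps-kj":
        return rmin_from_sigma(payload["sigma_A"]), payload["eps_kJmol"] / KJ_PER_KCAL
    raise ValueError(f"unknown dialect {payload['dialect']!r}")
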