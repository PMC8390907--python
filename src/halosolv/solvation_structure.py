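"""Protein solvation-shell structure: proximal densities, SASA(r), hydrogen bonds.

The proximal (perpendicular) number density resolves solvent concentration
by distance to the *surface* of the protein rather than to its center:

    ρ_X(r) = n̄_X(r) / (dr · SASA̅(r)),

where n̄_X(r) is the time-averaged count of species X in the shell
[r, r+dr) of distance to the nearest non-hydrogen protein atom, and
SASA(r) is the area of the isosurface whose points lie exactly r from the
nearest heavy atom — the exposed area of the union of spheres of radius r
centered on the heavy atoms.  This normalization cancels the protein's
shape, so a structureless solvent gives a flat profile at its bulk
density.

Strong water→protein hydrogen bonds use a geometric criterion: donor
oxygen to acceptor (N/O) distance below 3 Å and an O_w–H⋯A angle at the
hydrogen above 135°, maximized over the two water hydrogens.  Their
surface density is σ_HB = n̄_HB / SASA̅ evaluated at the first maximum of
the hydration layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import SyntheticTrajectory
from .units import per_A3_to_per_nm3

DEFAULT_DR_A = 0.05
DEFAULT_SHELL_CUTOFF_A = 4.5
DEFAULT_SASA_POINTS = 960

ACIDIC = {"ASP", "GLU"}
BASIC = {"LYS", "ARG"}
POLAR = {"SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS"}
APOLAR = {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "TRP", "GLY", "PRO"}


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric strong-hydrogen-bond criterion (strict inequalities).

    ``angle_at`` selects where the angle is measured: ``"hydrogen"`` uses
    the O_w–H⋯A angle at H (> min_angle); ``"oxygen"`` uses the angle
    between the O–H bond vector and the O⋯A vector (< 180° − min_angle).
    """

    max_distance: float = 3.0       # Å, O_w ⋯ acceptor
    min_angle: float = 135.0        # degrees
    acceptor_elements: tuple[str, ...] = ("N", "O")
    angle_at: str = "hydrogen"

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_angle <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")
        if self.angle_at not in ("hydrogen", "oxygen"):
            raise ValueError("angle_at must be 'hydrogen' or 'oxygen'")


@dataclass
class ProximalDensityProfile:
    """Shell-resolved species density around a protein."""

    species: str
    edges: np.ndarray        # shell edges, Å; shells are [r, r+dr)
    counts: np.ndarray       # mean shell counts n̄_X(r)
    sasa: np.ndarray         # mean SASA at shell midpoints, Å²
    rho_per_nm3: np.ndarray  # ρ_X(r), particles/nm³
    dr: float = DEFAULT_DR_A

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    def first_peak_height(self) -> float:
        return float(self.rho_per_nm3.max())

    def first_peak_position(self) -> float:
        return float(self.r_mid[int(np.argmax(self.rho_per_nm3))])


@dataclass
class SurfaceCompositionMetrics:
    n_acidic: int
    n_basic: int
    n_polar: int
    n_apolar: int
    net_charge: float              # e
    mean_sasa: float               # Å²
    acidic_density: float          # residues/Å²
    charge_density: float          # e/Å²


def proximal_distance(points: np.ndarray, protein_heavy: np.ndarray,
                      box_length: float | None = None) -> np.ndarray:
    """Distance from each point to the nearest non-hydrogen protein atom.

    Minimum-image convention when ``box_length`` is given.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    protein_heavy = np.atleast_2d(np.asarray(protein_heavy, dtype=float))
    if protein_heavy.shape[0] == 0:
        raise ValueError("empty protein selection")
    delta = points[:, None, :] - protein_heavy[None, :, :]
    if box_length is not None:
        delta -= box_length * np.round(delta / box_length)
    d = np.sqrt((delta ** 2).sum(axis=-1))
    return d.min(axis=1)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform spiral point set on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(1.0 - z * z)
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def sasa_at_distance(protein_heavy: np.ndarray, r: float,
                     n_sphere_points: int = DEFAULT_SASA_POINTS) -> float:
    """Area (Å²) of the isosurface at distance ``r`` from the nearest heavy atom.

    Equals the exposed area of the union of radius-r spheres centered on
    the heavy atoms, estimated by deterministic sphere-point sampling:
    per atom, the fraction of spiral points farther than r from every
    other atom, times 4πr².
    """
    if r <= 0:
        raise ValueError("r must be positive")
    atoms = np.atleast_2d(np.asarray(protein_heavy, dtype=float))
    unit = _fibonacci_sphere(n_sphere_points)
    area = 0.0
    for k, center in enumerate(atoms):
        pts = center + r * unit
        others = np.delete(atoms, k, axis=0)
        if len(others):
            d2 = ((pts[:, None, :] - others[None, :, :]) ** 2).sum(axis=-1)
            exposed = (d2.min(axis=1) > r * r - 1e-9).mean()
        else:
            exposed = 1.0
        area += exposed * 4.0 * np.pi * r * r
    return float(area)


def proximal_density(traj: SyntheticTrajectory, species: str,
                     protein_species: str = "protein",
                     dr: float = DEFAULT_DR_A,
                     r_max: float = 10.0,
                     n_sphere_points: int = DEFAULT_SASA_POINTS) -> ProximalDensityProfile:
    """Time-averaged proximal number density profile for one species.

    Water is measured at its oxygen.  SASA(r) is evaluated at shell
    midpoints per frame and averaged; for a rigid protein it is computed
    once.
    """
    if r_max > traj.box.edge_length / 2:
        raise ValueError("r_max beyond half the box edge")
    L = traj.box.edge_length
    prot_idx = traj.select(protein_species)
    heavy = prot_idx[np.asarray(traj.elements)[prot_idx] != "H"]
    if heavy.size == 0:
        raise ValueError("no protein heavy atoms")
    sp_idx = traj.select(species)
    edges = np.arange(0.0, r_max + dr, dr)
    edges = edges[edges <= r_max + 1e-12]
    mids = 0.5 * (edges[1:] + edges[:-1])
    counts = np.zeros(len(mids))
    rigid = np.allclose(traj.coords[:, heavy], traj.coords[0, heavy])
    sasa_acc = np.zeros(len(mids))
    for t in range(traj.n_frames):
        d = proximal_distance(traj.coords[t, sp_idx], traj.coords[t, heavy], L)
        counts += np.histogram(d, bins=edges)[0]
        if not rigid:
            sasa_acc += [sasa_at_distance(traj.coords[t, heavy], r, n_sphere_points)
                         for r in mids]
    counts /= traj.n_frames
    if rigid:
        sasa = np.asarray([sasa_at_distance(traj.coords[0, heavy], r, n_sphere_points)
                           for r in mids])
    else:
        sasa = sasa_acc / traj.n_frames
    rho_A3 = np.divide(counts, dr * sasa, out=np.zeros_like(counts), where=sasa > 0)
    return ProximalDensityProfile(species, edges, counts, sasa,
                                  per_A3_to_per_nm3(rho_A3), dr)


def cumulative_number(profile: ProximalDensityProfile, r_cut: float) -> float:
    """Mean number of species within ``r_cut`` of the surface (Σ shell counts)."""
    if not (profile.edges[0] <= r_cut <= profile.edges[-1] + 1e-9):
        raise ValueError("r_cut outside the profile range")
    mask = profile.edges[1:] <= r_cut + 1e-9
    return float(profile.counts[mask].sum())


def _water_geometry(traj: SyntheticTrajectory, frame: int, species: str = "water"):
    """(O, H1, H2) position triplets for every water molecule in a frame."""
    mask = (traj.species == species)
    idx = np.flatnonzero(mask)
    if idx.size == 0 or idx.size % 3 != 0:
        raise ValueError("malformed water: expected O,H1,H2 triplets")
    names = traj.names[idx]
    if not (np.all(names[0::3] == "OW") and np.all(names[1::3] == "HW1")):
        raise ValueError("malformed water: unexpected atom ordering")
    xyz = traj.coords[frame, idx].reshape(-1, 3, 3)
    return xyz[:, 0], xyz[:, 1], xyz[:, 2]


def hbond_census(o_w: np.ndarray, h_w: np.ndarray, acceptors: np.ndarray,
                 criterion: HBondCriterion = HBondCriterion(),
                 box_length: float | None = None) -> int:
    """Count water→acceptor donations satisfying the strong-bond criterion.

    ``o_w`` (n, 3) water oxygens, ``h_w`` (n, 2, 3) their hydrogens,
    ``acceptors`` (m, 3).  Each (water, acceptor) pair contributes at most
    one bond; the angle is maximized over the two hydrogens.
    """
    o_w = np.atleast_2d(o_w)
    acceptors = np.atleast_2d(acceptors)
    h_w = np.asarray(h_w, dtype=float).reshape(len(o_w), 2, 3)
    if len(o_w) == 0 or len(acceptors) == 0:
        return 0
    d_oa = o_w[:, None, :] - acceptors[None, :, :]
    if box_length is not None:
        d_oa -= box_length * np.round(d_oa / box_length)
    dist = np.sqrt((d_oa ** 2).sum(-1))            # (n, m)
    within = dist < criterion.max_distance
    if not within.any():
        return 0
    # acceptor position relative to each water oxygen (minimum image)
    a_rel = o_w[:, None, :] - d_oa                  # (n, m, 3)
    count = 0
    cos_min = np.cos(np.deg2rad(criterion.min_angle))
    for hi in range(2):
        h = h_w[:, hi]
        if criterion.angle_at == "hydrogen":
            v1 = o_w[:, None, :] - h[:, None, :]    # H→O
            v2 = a_rel - h[:, None, :]              # H→A
        else:
            v1 = h[:, None, :] - o_w[:, None, :]    # O→H bond vector
            v2 = a_rel - o_w[:, None, :]            # O→A vector
        num = (v1 * v2).sum(-1)
        den = np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
        cosang = num / np.where(den > 0, den, np.inf)
        if criterion.angle_at == "hydrogen":
            ok = cosang < cos_min                   # angle at H > min_angle
        else:
            ok = cosang > np.cos(np.deg2rad(180.0 - criterion.min_angle))
        if hi == 0:
            bonded = within & ok
        else:
            bonded |= within & ok
    count = int(bonded.sum())
    return count


def hbond_census_trajectory(traj: SyntheticTrajectory,
                            criterion: HBondCriterion = HBondCriterion(),
                            protein_species: str = "protein") -> np.ndarray:
    """Per-frame strong-bond counts between water and protein N/O acceptors."""
    prot = traj.select(protein_species)
    acc_mask = np.isin(traj.elements[prot], criterion.acceptor_elements)
    acc_idx = prot[acc_mask]
    out = np.empty(traj.n_frames, dtype=int)
    for t in range(traj.n_frames):
        o, h1, h2 = _water_geometry(traj, t)
        out[t] = hbond_census(o, np.stack([h1, h2], axis=1),
                              traj.coords[t, acc_idx], criterion,
                              traj.box.edge_length)
    return out


def hbond_surface_density(mean_count: float, mean_sasa: float) -> dict:
    """σ_HB = n̄_HB/SASA̅, reported per Å² and per nm²."""
    if mean_sasa <= 0:
        raise ValueError("SASA must be positive")
    per_A2 = mean_count / mean_sasa
    return {"per_A2": per_A2, "per_nm2": per_A2 * 100.0}


def classify_residue(resname: str, his_charged: bool = False,
                     overrides: dict[str, str] | None = None) -> str:
    name = resname.upper()
    if overrides and name in overrides:
        return overrides[name]
    if name in ACIDIC:
        return "acidic"
    if name in BASIC or (his_charged and name == "HIS"):
        return "basic"
    if name in POLAR:
        return "polar"
    if name in APOLAR:
        return "apolar"
    raise ValueError(f"unknown residue {resname!r}; provide a classification override")


def composition_metrics(resnames, mean_sasa: float, his_charged: bool = False,
                        overrides: dict[str, str] | None = None) -> SurfaceCompositionMetrics:
    """Residue-class counts, net charge and per-area surface densities.

    ``resnames`` is one name per residue.  Acidic residues carry −1 e,
    basic +1 e.  Densities are counts (or charge) per mean SASA.
    """
    counts = {"acidic": 0, "basic": 0, "polar": 0, "apolar": 0}
    for rn in resnames:
        counts[classify_residue(rn, his_charged, overrides)] += 1
    net = counts["basic"] - counts["acidic"]
    if mean_sasa <= 0:
        raise ValueError("SASA must be positive")
    return SurfaceCompositionMetrics(
        counts["acidic"], counts["basic"], counts["polar"], counts["apolar"],
        float(net), float(mean_sasa),
        counts["acidic"] / mean_sasa, net / mean_sasa,
    )


def linear_correlation(x, y) -> dict:
    """Ordinary least squares slope/intercept plus the Pearson coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "pearson_r": float(res.rvalue)}
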