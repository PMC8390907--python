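"""Synthetic electrolyte boxes, Brownian trajectories and toy protein systems.

Everything the analysis pipeline consumes can be generated here with a
*known* correlation structure, diffusion coefficient or solvation geometry,
so that every downstream estimator can be tested against the generator's
ground truth.  Nothing in this module is physically realistic: there is no
force field and no thermostat.  Water is a rigid 3-site molecule (one O,
two H at the fixed TIP3P-like bond length/angle, randomly oriented) purely
so that hydrogen-bond geometry is exercisable.

Random-number protocol: each generator takes one root seed; independent
streams (placement, orientation, displacement noise) are derived from it
via ``numpy.random.SeedSequence.spawn``, so regeneration with the same seed
is bit-identical; replica ensembles mimicking independent production runs
draw their per-replica seeds from one root via :func:`replica_seeds`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .units import WATER_HOH_ANGLE_DEG, WATER_OH_BOND_A

#: minimum separation (Å) enforced between independently placed particles;
#: avoids degenerate near-zero RDF bins, not a physical excluded volume
MIN_SEPARATION_A = 0.5

ROLES = ("water", "cation", "anion", "protein_heavy", "protein_hydrogen")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxSpec:
    """Cubic periodic simulation box.

    Parameters
    ----------
    edge_length : float
        Edge length L in Å; the box volume is L³.
    temperature_label : float
        Nominal temperature in K.  Metadata only — nothing here is
        thermalized.
    """

    edge_length: float
    periodic: bool = True
    temperature_label: float = 298.0

    def __post_init__(self):
        if self.edge_length <= 0:
            raise ValueError("box edge_length must be positive")
        if not self.periodic:
            raise ValueError("only periodic boxes are supported")

    @property
    def volume(self) -> float:
        """Box volume in Å³."""
        return self.edge_length ** 3


@dataclass(frozen=True)
class Species:
    label: str
    count: int
    role: str

    def __post_init__(self):
        if self.count < 0:
            raise ValueError(f"negative count for species {self.label!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class SpeciesRoster:
    """Per-species labels, counts and roles for a synthetic system."""

    species: tuple[Species, ...]
    electroneutral: bool = True

    def __post_init__(self):
        if self.electroneutral and self.count_role("cation") != self.count_role("anion"):
            raise ValueError("electroneutral roster requires equal cation and anion counts")

    @staticmethod
    def of(electroneutral: bool = True, **label_to_count_role) -> "SpeciesRoster":
        """Shorthand: ``SpeciesRoster.of(K=(500, 'cation'), ...)``."""
        sp = tuple(Species(lbl, c, r) for lbl, (c, r) in label_to_count_role.items())
        return SpeciesRoster(sp, electroneutral=electroneutral)

    def count_role(self, role: str) -> int:
        return sum(s.count for s in self.species if s.role == role)

    def labels_with_role(self, role: str) -> list[str]:
        return [s.label for s in self.species if s.role == role]

    @property
    def n_ions(self) -> int:
        """n_c = n₊ + n₋, the indistinguishable-ion (cosolvent) count."""
        return self.count_role("cation") + self.count_role("anion")


@dataclass
class SyntheticTrajectory:
    """Ordered configurations of a labeled particle system.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å.  ``species``,
    ``names``, ``elements``, ``roles``, ``resnums`` and ``resnames`` are
    per-atom arrays.  When ``wrapped`` is true all coordinates lie inside
    the box; for Brownian trajectories generated wrapped, the continuous
    coordinates remain retrievable via ``unwrapped_coords``.
    """

    coords: np.ndarray
    species: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    roles: np.ndarray
    box: BoxSpec
    timestep: float = 1.0
    seed: int | None = None
    wrapped: bool = True
    unwrapped_coords: np.ndarray | None = None
    resnums: np.ndarray | None = None
    resnames: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] < 1:
            raise ValueError("coords must be (n_frames >= 1, n_atoms, 3)")
        n = self.n_atoms
        if self.resnums is None:
            self.resnums = np.arange(1, n + 1)
        if self.resnames is None:
            self.resnames = np.asarray([s[:3].upper() or "UNK" for s in self.species])

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, label: str, atoms: str = "primary") -> np.ndarray:
        """Indices of atoms belonging to species ``label``.

        ``atoms='primary'`` returns, for water, only the oxygen (the
        convention every density/RDF observable uses); for anything else,
        all atoms of the species.  ``atoms='all'`` returns every atom;
        ``atoms='hydrogen'`` only hydrogens.
        """
        mask = self.species == label
        if atoms == "all":
            pass
        elif atoms == "hydrogen":
            mask &= self.elements == "H"
        elif atoms == "primary":
            mask &= np.where(self.roles == "water", self.elements == "O", True)
        else:
            raise ValueError(f"unknown atom subset {atoms!r}")
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"no atoms selected for species {label!r} ({atoms})")
        return idx

    def positions(self, label: str, frame: int | None = None) -> np.ndarray:
        idx = self.select(label)
        return self.coords[:, idx] if frame is None else self.coords[frame, idx]

    def get_unwrapped(self) -> np.ndarray:
        if self.unwrapped_coords is not None:
            return self.unwrapped_coords
        if not self.wrapped:
            return self.coords
        raise ValueError("trajectory was generated wrapped without continuous coordinates")


@dataclass(frozen=True)
class ContactSite:
    site_id: int
    resnum: int
    resname: str
    oxygen_name: str
    r_cryst: float  # Å

    def __post_init__(self):
        if self.r_cryst <= 0:
            raise ValueError("r_cryst must be positive")


@dataclass(frozen=True)
class ContactSiteTable:
    """Crystal contact-site distances between a cation and carboxylate oxygens."""

    sites: tuple[ContactSite, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": s.site_id,
                    "resnum": s.resnum,
                    "resname": s.resname,
                    "atom": s.oxygen_name,
                    "r_cryst_A": s.r_cryst,
                }
                for s in self.sites
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "ContactSiteTable":
        df = pd.read_csv(path)
        sites = tuple(
            ContactSite(int(r.site_id), int(r.resnum), str(r.resname), str(r.atom), float(r.r_cryst_A))
            for r in df.itertuples()
        )
        return ContactSiteTable(sites)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def replica_seeds(root_seed: int, n_replicas: int) -> list[int]:
    """Deterministic per-replica child seeds from one root seed.

    Replica runs (mimicking independent production simulations) must not
    share streams with each other or with the root; spawning via
    ``SeedSequence`` guarantees independence while keeping the whole
    ensemble reproducible from a single integer.
    """
    children = np.random.SeedSequence(root_seed).spawn(n_replicas)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def water_hydrogens(o_pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random rigid-water hydrogens for oxygens ``o_pos`` (n, 3) → (n, 2, 3)."""
    n = len(o_pos)
    h1_dir = _random_unit_vectors(rng, n)
    # random direction at the H-O-H angle from h1
    aux = _random_unit_vectors(rng, n)
    perp = np.cross(h1_dir, aux)
    norm = np.linalg.norm(perp, axis=1, keepdims=True)
    # re-draw the rare near-parallel aux vectors
    bad = norm[:, 0] < 1e-8
    while bad.any():
        aux[bad] = _random_unit_vectors(rng, int(bad.sum()))
        perp[bad] = np.cross(h1_dir[bad], aux[bad])
        norm = np.linalg.norm(perp, axis=1, keepdims=True)
        bad = norm[:, 0] < 1e-8
    perp /= norm
    theta = np.deg2rad(WATER_HOH_ANGLE_DEG)
    h2_dir = np.cos(theta) * h1_dir + np.sin(theta) * perp
    h = np.stack([h1_dir, h2_dir], axis=1) * WATER_OH_BOND_A
    return o_pos[:, None, :] + h


def _assemble_atoms(roster: SpeciesRoster):
    """Per-atom metadata arrays and the per-species molecule slots."""
    species, names, elements, roles, resnums, resnames = [], [], [], [], [], []
    slots: dict[str, dict] = {}
    resnum = 0
    _ELEMENT = {"cation": "K", "anion": "Cl"}
    for sp in roster.species:
        start = len(species)
        for i in range(sp.count):
            resnum += 1
            if sp.role == "water":
                for nm, el in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
                    species.append(sp.label)
                    names.append(nm)
                    elements.append(el)
                    roles.append("water")
                    resnums.append(resnum)
                    resnames.append("SOL")
            else:
                species.append(sp.label)
                names.append(sp.label[:4].upper())
                elements.append(_ELEMENT.get(sp.role, sp.label[:2].capitalize()))
                roles.append(sp.role)
                resnums.append(resnum)
                resnames.append(sp.label[:3].upper())
        slots[sp.label] = {"role": sp.role, "start": start, "stop": len(species), "count": sp.count}
    meta = dict(
        species=np.asarray(species),
        names=np.asarray(names),
        elements=np.asarray(elements),
        roles=np.asarray(roles),
        resnums=np.asarray(resnums),
        resnames=np.asarray(resnames),
    )
    return meta, slots


def _enforce_min_separation(points: np.ndarray, L: float, rng: np.random.Generator,
                            frozen: np.ndarray | None = None) -> np.ndarray:
    """Redraw uniformly-placed points closer than MIN_SEPARATION_A.

    ``frozen`` marks points that must not be moved (e.g. scripted pairs).
    """
    points = points.copy()
    if frozen is None:
        frozen = np.zeros(len(points), dtype=bool)
    for _ in range(100):
        tree = cKDTree(np.mod(points, L), boxsize=L)
        pairs = tree.query_pairs(MIN_SEPARATION_A, output_type="ndarray")
        if len(pairs) == 0:
            return points
        movable = np.unique(pairs.ravel())
        movable = movable[~frozen[movable]]
        if movable.size == 0:  # only frozen atoms clash: give up, caller decides
            return points
        points[movable] = rng.uniform(0.0, L, size=(movable.size, 3))
    raise RuntimeError("could not satisfy minimum separation; box too dense")


def _fill_frame(slots, meta, placements: dict[str, np.ndarray], L: float,
                rng: np.random.Generator) -> np.ndarray:
    """One frame (n_atoms, 3) from per-species molecule positions."""
    frame = np.empty((len(meta["species"]), 3))
    for label, slot in slots.items():
        pos = placements[label]
        if slot["role"] == "water":
            h = water_hydrogens(pos, rng)
            block = np.concatenate([pos[:, None, :], h], axis=1).reshape(-1, 3)
        else:
            block = pos
        frame[slot["start"]:slot["stop"]] = block
    return np.mod(frame, L)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_ideal_solution(roster: SpeciesRoster, box: BoxSpec, n_frames: int,
                       seed: int) -> SyntheticTrajectory:
    """Uncorrelated (Poisson) solution: every molecule i.i.d. uniform per frame.

    All pair correlation functions equal 1 in expectation, which makes this
    the null model for every Kirkwood-Buff observable.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if box.volume <= 0:
        raise ValueError("zero box volume")
    n_mol = sum(s.count for s in roster.species)
    if n_mol == 0:
        raise ValueError("empty roster")
    if n_mol / box.volume > 0.04:  # beyond liquid-like number density
        raise ValueError("roster does not fit the box at liquid-like density")
    meta, slots = _assemble_atoms(roster)
    L = box.edge_length
    place_rng, orient_rng = [np.random.default_rng(s) for s in
                             np.random.SeedSequence(seed).spawn(2)]
    frames = []
    for _ in range(n_frames):
        pts = place_rng.uniform(0.0, L, size=(n_mol, 3))
        pts = _enforce_min_separation(pts, L, place_rng)
        placements, k = {}, 0
        for sp in roster.species:
            placements[sp.label] = pts[k:k + sp.count]
            k += sp.count
        frames.append(_fill_frame(slots, meta, placements, L, orient_rng))
    return SyntheticTrajectory(np.asarray(frames), box=box, seed=seed, wrapped=True, **meta)


def gen_paired_solution(roster: SpeciesRoster, box: BoxSpec, cip_distance: float,
                        paired_fraction: float, peak_width: float,
                        seed: int, n_frames: int = 1) -> SyntheticTrajectory:
    """Solution with a scripted contact-ion-pair population.

    A fraction of cation-anion pairs is placed at Gaussian-distributed
    separation (mean ``cip_distance``, sd ``peak_width``); all remaining
    particles are uniform.  The cation-anion RDF then shows a first peak at
    a *known* position — the ground truth for the Gaussian peak fitter.
    """
    if not 0.0 <= paired_fraction <= 1.0:
        raise ValueError("paired_fraction must lie in [0, 1]")
    if cip_distance >= box.edge_length / 4:
        raise ValueError("cip_distance must be below box/4")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    meta, slots = _assemble_atoms(roster)
    L = box.edge_length
    cations = roster.labels_with_role("cation")
    anions = roster.labels_with_role("anion")
    if len(cations) != 1 or len(anions) != 1:
        raise ValueError("paired generator needs exactly one cation and one anion species")
    c_lbl, a_lbl = cations[0], anions[0]
    n_pair_max = min(slots[c_lbl]["count"], slots[a_lbl]["count"])
    n_paired = int(round(paired_fraction * n_pair_max))
    place_rng, pair_rng, orient_rng = [np.random.default_rng(s) for s in
                                       np.random.SeedSequence(seed).spawn(3)]
    n_mol = sum(s.count for s in roster.species)
    frames = []
    for _ in range(n_frames):
        pts = place_rng.uniform(0.0, L, size=(n_mol, 3))
        frozen = np.zeros(n_mol, dtype=bool)
        placements, k = {}, 0
        offsets = {}
        for sp in roster.species:
            placements[sp.label] = pts[k:k + sp.count]
            offsets[sp.label] = k
            k += sp.count
        if n_paired:
            d = pair_rng.normal(cip_distance, peak_width, size=n_paired)
            d = np.clip(d, MIN_SEPARATION_A, None)
            u = _random_unit_vectors(pair_rng, n_paired)
            placements[a_lbl][:n_paired] = placements[c_lbl][:n_paired] + d[:, None] * u
            frozen[offsets[c_lbl]:offsets[c_lbl] + n_paired] = True
            frozen[offsets[a_lbl]:offsets[a_lbl] + n_paired] = True
        pts = _enforce_min_separation(pts, L, place_rng, frozen=frozen)
        frames.append(_fill_frame(slots, meta, placements, L, orient_rng))
    return SyntheticTrajectory(np.asarray(frames), box=box, seed=seed, wrapped=True, **meta)


def gen_brownian(roster: SpeciesRoster, box: BoxSpec, D_per_species: dict[str, float],
                 timestep: float, n_steps: int, seed: int,
                 wrapped: bool = False) -> SyntheticTrajectory:
    """Free Brownian motion with species-specific diffusion coefficients.

    Each Cartesian increment is drawn with variance 2·D·Δt, so the ensemble
    MSD is exactly 6·D·τ — the ground truth for the diffusion fit.  With
    ``wrapped=True`` the stored coordinates are re-imaged into the box while
    the continuous coordinates stay retrievable via ``get_unwrapped``.
    """
    if timestep <= 0:
        raise ValueError("timestep must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    for lbl, D in D_per_species.items():
        if D < 0:
            raise ValueError(f"negative diffusion coefficient for {lbl!r}")
    meta, slots = _assemble_atoms(roster)
    L = box.edge_length
    init_rng, walk_rng, orient_rng = [np.random.default_rng(s) for s in
                                      np.random.SeedSequence(seed).spawn(3)]
    n_frames = n_steps + 1
    n_atoms = len(meta["species"])
    unwrapped = np.empty((n_frames, n_atoms, 3))
    for sp in roster.species:
        slot = slots[sp.label]
        if sp.count == 0:
            continue
        D = D_per_species.get(sp.label, 0.0)
        if D < 0:
            raise ValueError("negative D")
        start = init_rng.uniform(0.0, L, size=(sp.count, 3))
        sigma = np.sqrt(2.0 * D * timestep)
        steps = (walk_rng.normal(0.0, sigma, size=(n_steps, sp.count, 3))
                 if sigma > 0 else np.zeros((n_steps, sp.count, 3)))
        path = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
        if slot["role"] == "water":
            h = water_hydrogens(start, orient_rng) - start[:, None, :]
            block = path[:, :, None, :] + h[None]  # rigid molecule translates
            unwrapped[:, slot["start"]:slot["stop"]] = block.reshape(n_frames, -1, 3)
        else:
            unwrapped[:, slot["start"]:slot["stop"]] = path
    if wrapped:
        return SyntheticTrajectory(np.mod(unwrapped, L), box=box, timestep=timestep,
                                   seed=seed, wrapped=True, unwrapped_coords=unwrapped, **meta)
    return SyntheticTrajectory(unwrapped, box=box, timestep=timestep, seed=seed,
                               wrapped=False, **meta)


# ---------------------------------------------------------------------------
# toy protein system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryEntry:
    """One scripted solvent placement relative to a protein anchor atom.

    ``angle`` is the O_w-H⋯A angle at the hydrogen for water placements
    (degrees); it is ignored for monoatomic species.  ``anchor`` indexes
    the toy protein's anchor list (carboxylate O sites first).
    """

    species: str
    distance: float
    angle: float = 180.0
    anchor: int = 0

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("scripted distance must be positive")


#: toy protein scaffold: (resnum, resname, [(atom name, element)]) — five
#: acidic sites with carboxylate-like oxygens, one basic N, one polar O,
#: one apolar C, arranged on a widely spaced ring so placements never clash
_TOY_RESIDUES = [
    (10, "ASP", [("CA", "C"), ("OD1", "O"), ("OD2", "O")]),
    (20, "GLU", [("CA", "C"), ("OE1", "O"), ("OE2", "O")]),
    (30, "ASP", [("CA", "C"), ("OD1", "O"), ("OD2", "O")]),
    (40, "GLU", [("CA", "C"), ("OE1", "O"), ("OE2", "O")]),
    (50, "ASP", [("CA", "C"), ("OD1", "O"), ("OD2", "O")]),
    (60, "LYS", [("CA", "C"), ("NZ", "N")]),
    (70, "SER", [("CA", "C"), ("OG", "O")]),
    (80, "ALA", [("CA", "C"), ("CB", "C")]),
]


@dataclass
class ToyProtein:
    """Rigid pseudo-protein with labeled heavy atoms and anchor sites."""

    positions: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    resnums: np.ndarray
    resnames: np.ndarray
    anchor_indices: np.ndarray   # atom index of each anchor
    anchor_outward: np.ndarray   # unit vector pointing into solvent per anchor

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


def _build_toy_protein(center: np.ndarray, ring_radius: float = 14.0) -> ToyProtein:
    pos, names, elements, resnums, resnames = [], [], [], [], []
    anchors, outward = [], []
    n_res = len(_TOY_RESIDUES)
    for i, (resnum, resname, atoms) in enumerate(_TOY_RESIDUES):
        phi = 2 * np.pi * i / n_res
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        ca = center + ring_radius * u
        for j, (nm, el) in enumerate(atoms):
            if nm == "CA":
                p = ca
            else:
                # side-chain atoms 1.3 Å outward, split vertically for pairs
                dz = 0.0 if len(atoms) == 2 else (0.9 if j == 1 else -0.9)
                p = ca + 1.3 * u + np.array([0.0, 0.0, dz])
                if el in ("O", "N") or (resname == "ALA" and nm == "CB"):
                    anchors.append(len(pos))
                    out = p - center
                    outward.append(out / np.linalg.norm(out))
            pos.append(p)
            names.append(nm)
            elements.append(el)
            resnums.append(resnum)
            resnames.append(resname)
    return ToyProtein(np.asarray(pos), np.asarray(names), np.asarray(elements),
                      np.asarray(resnums), np.asarray(resnames),
                      np.asarray(anchors), np.asarray(outward))


def _place_water_at(anchor: np.ndarray, direction: np.ndarray, distance: float,
                    angle_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Water (O, H1, H2) with O at ``distance`` from the acceptor along
    ``direction`` and one hydrogen making the requested O_w-H⋯A angle at H."""
    o = anchor + distance * direction
    theta = np.deg2rad(angle_deg)
    r_oh, d = WATER_OH_BOND_A, distance
    # triangle O_w-H-A: angle at H is theta, |O_w H| = r_oh, |O_w A| = d
    sin_at_a = np.clip(r_oh * np.sin(theta) / d, -1.0, 1.0)
    ang_a = np.arcsin(sin_at_a)
    ang_o = np.pi - theta - ang_a  # angle at O_w between O→A and O→H
    to_a = -direction
    aux = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(aux, to_a)) > 0.99:
        aux = np.array([0.0, 1.0, 0.0])
    perp = np.cross(to_a, aux)
    perp /= np.linalg.norm(perp)
    h1_dir = np.cos(ang_o) * to_a + np.sin(ang_o) * perp
    h1 = o + r_oh * h1_dir
    hoh = np.deg2rad(WATER_HOH_ANGLE_DEG)
    perp2 = np.cross(h1_dir, perp)
    perp2 /= np.linalg.norm(perp2)
    h2_dir = np.cos(hoh) * h1_dir + np.sin(hoh) * perp2
    h2 = o + r_oh * h2_dir
    return np.stack([o, h1, h2])


def gen_toy_protein_system(geometry_spec: list[GeometryEntry], seed: int = 0,
                           box: BoxSpec | None = None, n_frames: int = 1,
                           noise: float = 0.0):
    """Rigid pseudo-protein with solvent scripted at exact distances/angles.

    Returns ``(protein, trajectory, contact_table)``.  Cation entries are
    recorded in the contact table with their scripted distance as r_cryst.
    ``noise`` adds per-frame isotropic Gaussian jitter (Å) to the solvent,
    for peak-width studies; the default is exactly rigid.
    """
    if box is None:
        box = BoxSpec(60.0)
    center = np.full(3, box.edge_length / 2.0)
    protein = _build_toy_protein(center)
    rng = np.random.default_rng(seed)

    solv_pos, solv_species, solv_names, solv_elements, solv_roles = [], [], [], [], []
    solv_resnums, solv_resnames = [], []
    sites = []
    resnum = 1000
    for k, entry in enumerate(geometry_spec):
        if entry.anchor >= len(protein.anchor_indices):
            raise ValueError(f"geometry entry {k} references undefined anchor {entry.anchor}")
        a_idx = protein.anchor_indices[entry.anchor]
        anchor = protein.positions[a_idx]
        direction = protein.anchor_outward[entry.anchor]
        resnum += 1
        if entry.species == "water":
            xyz = _place_water_at(anchor, direction, entry.distance, entry.angle, rng)
            solv_pos.extend(xyz)
            solv_species.extend(["water"] * 3)
            solv_names.extend(["OW", "HW1", "HW2"])
            solv_elements.extend(["O", "H", "H"])
            solv_roles.extend(["water"] * 3)
            solv_resnums.extend([resnum] * 3)
            solv_resnames.extend(["SOL"] * 3)
        else:
            solv_pos.append(anchor + entry.distance * direction)
            solv_species.append(entry.species)
            solv_names.append(entry.species[:4].upper())
            solv_elements.append(entry.species[:2].capitalize())
            solv_roles.append("cation" if entry.species.upper().startswith(("K", "NA")) else "anion")
            solv_resnums.append(resnum)
            solv_resnames.append(entry.species[:3].upper())
            if solv_roles[-1] == "cation":
                sites.append(ContactSite(len(sites) + 1,
                                         int(protein.resnums[a_idx]),
                                         str(protein.resnames[a_idx]),
                                         str(protein.names[a_idx]),
                                         entry.distance))
    solv_pos = np.asarray(solv_pos).reshape(-1, 3)

    all_pos = np.concatenate([protein.positions, solv_pos]) if len(solv_pos) else protein.positions
    if len(all_pos) > 1:
        tree = cKDTree(all_pos)
        if tree.query_pairs(MIN_SEPARATION_A):
            raise ValueError("clashing placements: two particles closer than 0.5 Å")

    n_prot = protein.n_atoms
    species = np.concatenate([np.full(n_prot, "protein"), np.asarray(solv_species, dtype=object)]).astype(str)
    names = np.concatenate([protein.names, np.asarray(solv_names, dtype=object)]).astype(str)
    elements = np.concatenate([protein.elements, np.asarray(solv_elements, dtype=object)]).astype(str)
    roles = np.concatenate([np.full(n_prot, "protein_heavy"), np.asarray(solv_roles, dtype=object)]).astype(str)
    resnums = np.concatenate([protein.resnums, np.asarray(solv_resnums, dtype=int)]) if solv_resnums else protein.resnums
    resnames = np.concatenate([protein.resnames, np.asarray(solv_resnames, dtype=object)]).astype(str)

    frames = np.repeat(all_pos[None], n_frames, axis=0)
    if noise > 0 and len(solv_pos):
        frames[:, n_prot:] += rng.normal(0.0, noise, size=frames[:, n_prot:].shape)
    traj = SyntheticTrajectory(frames, species=species, names=names, elements=elements,
                               roles=roles, box=box, seed=seed, wrapped=True,
                               resnums=resnums, resnames=resnames)
    return protein, traj, ContactSiteTable(tuple(sites))


# ---------------------------------------------------------------------------
# writers (standard formats, via MDAnalysis)
# ---------------------------------------------------------------------------

def _to_universe(traj: SyntheticTrajectory):
    import MDAnalysis as mda

    n = traj.n_atoms
    n_res = len(np.unique(traj.resnums))
    _, res_idx = np.unique(traj.resnums, return_inverse=True)
    u = mda.Universe.empty(n_atoms=n, n_residues=n_res, atom_resindex=res_idx,
                           residue_segindex=np.zeros(n_res, dtype=int), trajectory=True)
    u.add_TopologyAttr("names", traj.names)
    u.add_TopologyAttr("elements", traj.elements)
    first = np.unique(traj.resnums, return_index=True)[1]
    u.add_TopologyAttr("resnames", traj.resnames[np.sort(first)])
    u.add_TopologyAttr("resids", np.unique(traj.resnums))
    L = traj.box.edge_length
    u.dimensions = [L, L, L, 90.0, 90.0, 90.0]
    return u


def write_structure(traj: SyntheticTrajectory, path, frame: int = 0) -> None:
    """Write a single frame as PDB or GRO (chosen by extension)."""
    u = _to_universe(traj)
    u.atoms.positions = traj.coords[frame]
    u.atoms.write(str(path))


def write_trajectory(traj: SyntheticTrajectory, path) -> None:
    """Write all frames as DCD or multi-frame PDB (chosen by extension)."""
    import MDAnalysis as mda

    u = _to_universe(traj)
    L = traj.box.edge_length
    with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
        for frame in traj.coords:
            u.atoms.positions = frame
            u.dimensions = [L, L, L, 90.0, 90.0, 90.0]
            w.write(u.atoms)


def read_trajectory(top_path, traj_path=None) -> np.ndarray:
    """Read coordinates (n_frames, n_atoms, 3) back from written files."""
    import MDAnalysis as mda

    u = mda.Universe(str(top_path)) if traj_path is None else mda.Universe(str(top_path), str(traj_path))
    return np.asarray([u.atoms.positions.copy() for _ in u.trajectory])
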