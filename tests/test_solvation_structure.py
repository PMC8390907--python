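"""Proximal distances/densities, SASA(r), hydrogen bonds, composition metrics."""

import numpy as np
import pytest

from halosolv import solvation_structure as ss
from halosolv import synthetic as syn


class TestProximalDistance:
    def test_single_atom_protein(self):
        d = ss.proximal_distance(np.array([5.0, 0, 0]), np.zeros((1, 3)))
        assert d[0] == pytest.approx(5.0)

    def test_matches_brute_force_minimum(self, rng):
        atoms = rng.uniform(0, 30, size=(200, 3))
        pts = rng.uniform(0, 30, size=(50, 3))
        fast = ss.proximal_distance(pts, atoms)
        slow = np.array([min(np.linalg.norm(p - a) for a in atoms) for p in pts])
        assert np.allclose(fast, slow)

    def test_periodic_image_used(self):
        """Point across the boundary is near the image, not the in-box atom."""
        L = 20.0
        atom = np.array([[1.0, 10.0, 10.0]])
        point = np.array([19.0, 10.0, 10.0])
        d = ss.proximal_distance(point, atom, box_length=L)
        assert d[0] == pytest.approx(2.0)  # not 18

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            ss.proximal_distance(np.zeros(3), np.empty((0, 3)))


class TestSasaAtDistance:
    def test_single_sphere_closed_form(self):
        """One atom: the r-isosurface is the full sphere 4πr²."""
        area = ss.sasa_at_distance(np.zeros((1, 3)), 2.0, 960)
        assert area == pytest.approx(4 * np.pi * 4.0, rel=5e-3)

    def test_two_overlapping_spheres_closed_form(self):
        """Two centers d < 2r: union area is 4πr(r + d/2)."""
        atoms = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        area = ss.sasa_at_distance(atoms, 2.0, 960)
        assert area == pytest.approx(4 * np.pi * 2.0 * (2.0 + 1.5), rel=5e-3)

    def test_disjoint_spheres(self):
        atoms = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        area = ss.sasa_at_distance(atoms, 2.0, 960)
        assert area == pytest.approx(8 * np.pi * 4.0, rel=1e-9)

    def test_converges_with_point_count(self):
        atoms = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        a1 = ss.sasa_at_distance(atoms, 2.0, 960)
        a2 = ss.sasa_at_distance(atoms, 2.0, 1920)
        assert abs(a2 - a1) / a1 < 5e-3

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValueError):
            ss.sasa_at_distance(np.zeros((1, 3)), 0.0)


def _single_atom_protein_traj(solvent_positions, box, n_frames=1):
    """Minimal system: one protein carbon + point 'water' oxygens."""
    solvent_positions = np.atleast_2d(solvent_positions)
    n_s = len(solvent_positions)
    coords = np.concatenate([np.full((1, 3), box.edge_length / 2), solvent_positions])
    coords = np.repeat(coords[None], n_frames, axis=0)
    return syn.SyntheticTrajectory(
        coords,
        species=np.array(["protein"] + ["water"] * n_s),
        names=np.array(["CA"] + ["OW"] * n_s),
        elements=np.array(["C"] + ["O"] * n_s),
        roles=np.array(["protein_heavy"] + ["water"] * n_s),
        box=box,
    )


class TestProximalDensity:
    def test_single_scripted_water_closed_form(self):
        """One water at r₀ from one atom: ρ = 1/(dr·4πr₀²) in that shell only."""
        box = syn.BoxSpec(40.0)
        c = box.edge_length / 2
        r0, dr = 3.225, 0.05
        traj = _single_atom_protein_traj(np.array([[c + r0, c, c]]), box)
        prof = ss.proximal_density(traj, "water", dr=dr, r_max=6.0)
        k = int(r0 / dr)
        r_mid = prof.r_mid[k]
        expected = 1.0 / (dr * 4 * np.pi * r_mid ** 2) * 1e3  # per nm³
        assert prof.counts.sum() == pytest.approx(1.0)
        assert prof.rho_per_nm3[k] == pytest.approx(expected, rel=2e-3)
        assert np.all(prof.rho_per_nm3[np.arange(len(prof.counts)) != k] == 0)

    def test_uniform_solvent_is_flat_at_bulk_density(self):
        """Eq.-of-shape normalization cancels geometry: ρ(r) = N/V, flat."""
        box = syn.BoxSpec(60.0)
        rng = np.random.default_rng(77)
        n, n_frames = 3000, 40
        frames = [rng.uniform(0, 60, size=(n, 3)) for _ in range(n_frames)]
        prot, traj0, _ = syn.gen_toy_protein_system([], seed=0, box=box)
        coords = np.concatenate([
            np.repeat(traj0.coords, n_frames, axis=0),
            np.asarray(frames)], axis=1)
        traj = syn.SyntheticTrajectory(
            coords,
            species=np.concatenate([traj0.species, np.full(n, "water")]),
            names=np.concatenate([traj0.names, np.full(n, "OW")]),
            elements=np.concatenate([traj0.elements, np.full(n, "O")]),
            roles=np.concatenate([traj0.roles, np.full(n, "water")]),
            box=box,
        )
        prof = ss.proximal_density(traj, "water", dr=0.25, r_max=8.0)
        bulk = n / box.volume * 1e3  # per nm³
        sel = prof.r_mid > 1.0
        # per-shell SEM from Poisson counts over frames
        mean_counts = prof.counts[sel]
        sem_counts = np.sqrt(np.maximum(mean_counts, 1e-12) / n_frames)
        rho = prof.rho_per_nm3[sel]
        sem_rho = rho * sem_counts / mean_counts
        assert np.all(np.abs(rho - bulk) < 3.5 * sem_rho + 0.02 * bulk)
        assert abs(rho.mean() - bulk) / bulk < 0.02

    def test_peak_height_unaffected_by_far_field_ions(self):
        """Locality: adding distant particles leaves the shell peak alone."""
        box = syn.BoxSpec(40.0)
        c = box.edge_length / 2
        near = np.array([[c + 2.8, c, c]])
        far = np.array([[c + 15.0, c, c], [c, c + 15.0, c]])
        p1 = ss.proximal_density(_single_atom_protein_traj(near, box), "water",
                                 dr=0.05, r_max=6.0)
        p2 = ss.proximal_density(_single_atom_protein_traj(np.vstack([near, far]), box),
                                 "water", dr=0.05, r_max=6.0)
        assert p1.first_peak_height() == pytest.approx(p2.first_peak_height())

    def test_r_max_beyond_half_box_rejected(self):
        box = syn.BoxSpec(40.0)
        traj = _single_atom_protein_traj(np.array([[25.0, 20, 20]]), box)
        with pytest.raises(ValueError):
            ss.proximal_density(traj, "water", r_max=30.0)


class TestCumulativeNumber:
    def test_conservation_and_construction(self):
        box = syn.BoxSpec(40.0)
        c = box.edge_length / 2
        radii = [2.0, 2.5, 3.0, 3.5, 4.0]
        pos = np.array([[c + r, c, c] for r in radii])
        traj = _single_atom_protein_traj(pos, box)
        prof = ss.proximal_density(traj, "water", dr=0.05, r_max=6.0)
        assert ss.cumulative_number(prof, 4.5) == pytest.approx(5.0)
        assert ss.cumulative_number(prof, 2.2) == pytest.approx(1.0)
        assert ss.cumulative_number(prof, 6.0) == pytest.approx(5.0)

    def test_out_of_range_rejected(self):
        box = syn.BoxSpec(40.0)
        traj = _single_atom_protein_traj(np.array([[22.0, 20, 20]]), box)
        prof = ss.proximal_density(traj, "water", dr=0.05, r_max=6.0)
        with pytest.raises(ValueError):
            ss.cumulative_number(prof, 7.0)


def _water_at(o, h1, h2):
    return np.asarray(o)[None], np.asarray([[h1, h2]])


class TestHbondCensus:
    A = np.array([[0.0, 0.0, 0.0]])

    def test_ideal_linear_bond_counted(self):
        o = [2.8, 0, 0]
        h1 = [2.8 - 0.9572, 0, 0]   # on the O→A axis, angle at H = 180°
        h2 = [3.2, 0.9, 0]
        ow, hw = _water_at(o, h1, h2)
        assert ss.hbond_census(ow, hw, self.A) == 1

    def test_distance_cut_is_strict(self):
        o = [3.2, 0, 0]
        h1 = [3.2 - 0.9572, 0, 0]
        ow, hw = _water_at(o, h1, [3.6, 0.9, 0])
        assert ss.hbond_census(ow, hw, self.A) == 0

    def test_angle_cut(self):
        # hydrogen perpendicular to the O⋯A axis: angle at H near 70°, rejected
        o = [2.8, 0, 0]
        h1 = [2.8, 0.9572, 0]
        ow, hw = _water_at(o, h1, [2.8, -0.9572, 0])
        assert ss.hbond_census(ow, hw, self.A) == 0

    def test_matches_brute_force_on_random_geometries(self, rng):
        """1000 random waters straddling both cutoffs vs. an exhaustive loop."""
        crit = ss.HBondCriterion()
        n = 1000
        acceptors = rng.uniform(-2, 2, size=(3, 3))
        d = rng.uniform(2.5, 3.5, size=n)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        base = acceptors[rng.integers(0, 3, size=n)]
        o = base + d[:, None] * u
        h = o[:, None, :] + 0.9572 * rng.normal(size=(n, 2, 3)) / np.linalg.norm(
            rng.normal(size=(n, 2, 3)), axis=-1, keepdims=True)
        fast = ss.hbond_census(o, h, acceptors, crit)
        slow = 0
        for i in range(n):
            for a in acceptors:
                if np.linalg.norm(o[i] - a) >= crit.max_distance:
                    continue
                best = 0.0
                for k in range(2):
                    v1 = o[i] - h[i, k]
                    v2 = a - h[i, k]
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    best = max(best, np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if best > crit.min_angle:
                    slow += 1
        assert fast == slow

    def test_invariant_under_rigid_rotation_translation(self, rng):
        crit = ss.HBondCriterion()
        n = 200
        acceptors = rng.uniform(-2, 2, size=(2, 3))
        o = acceptors[rng.integers(0, 2, size=n)] + rng.uniform(2.4, 3.4, size=(n, 1)) \
            * (lambda v: v / np.linalg.norm(v, axis=1, keepdims=True))(rng.normal(size=(n, 3)))
        hdir = rng.normal(size=(n, 2, 3))
        hdir /= np.linalg.norm(hdir, axis=-1, keepdims=True)
        h = o[:, None, :] + 0.9572 * hdir
        before = ss.hbond_census(o, h, acceptors, crit)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.2]).as_matrix()
        t = np.array([5.0, -3.0, 7.0])
        after = ss.hbond_census(o @ R.T + t, h @ R.T + t, acceptors @ R.T + t, crit)
        assert before == after

    def test_oxygen_angle_definition_available(self):
        o = [2.8, 0, 0]
        h1 = [2.8 - 0.9572, 0, 0]  # O-H bond anti-parallel to O→A: at-O angle 180°
        ow, hw = _water_at(o, h1, [3.2, 0.9, 0])
        crit = ss.HBondCriterion(angle_at="oxygen")
        assert ss.hbond_census(ow, hw, np.array([[0.0, 0, 0]]), crit) == 1


class TestSurfaceDensityAndComposition:
    def test_hbond_surface_density_arithmetic(self):
        out = ss.hbond_surface_density(100.0, 1000.0)
        assert out["per_A2"] == pytest.approx(0.1)
        assert out["per_nm2"] == pytest.approx(10.0)

    def test_zero_sasa_rejected(self):
        with pytest.raises(ValueError):
            ss.hbond_surface_density(1.0, 0.0)

    def test_homogeneity(self):
        a = ss.hbond_surface_density(50.0, 500.0)
        b = ss.hbond_surface_density(100.0, 1000.0)
        assert a["per_A2"] == pytest.approx(b["per_A2"])

    def test_composition_worked_example(self):
        resnames = ["ASP", "GLU", "ASP", "GLU", "LYS"]
        m = ss.composition_metrics(resnames, mean_sasa=100.0)
        assert (m.n_acidic, m.n_basic) == (4, 1)
        assert m.net_charge == -3
        assert m.acidic_density == pytest.approx(0.04)
        assert m.charge_density == pytest.approx(-0.03)

    def test_unknown_residue_needs_override(self):
        with pytest.raises(ValueError):
            ss.composition_metrics(["XYZ"], 100.0)
        m = ss.composition_metrics(["XYZ"], 100.0, overrides={"XYZ": "polar"})
        assert m.n_polar == 1

    def test_order_invariance(self):
        a = ss.composition_metrics(["ASP", "LYS", "SER"], 50.0)
        b = ss.composition_metrics(["SER", "ASP", "LYS"], 50.0)
        assert a == b

    def test_his_titration_flag(self):
        charged = ss.composition_metrics(["HIS"], 10.0, his_charged=True)
        neutral = ss.composition_metrics(["HIS"], 10.0)
        assert charged.n_basic == 1 and neutral.n_polar == 1


class TestLinearCorrelation:
    def test_exact_line(self):
        x = np.arange(5.0)
        out = ss.linear_correlation(x, 2 * x + 1)
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(1.0)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.arange(4.0)
        assert ss.linear_correlation(x, -x)["pearson_r"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        out = ss.linear_correlation(x, y)
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert out["pearson_r"] == pytest.approx(r, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ss.linear_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ss.linear_correlation([1.0, 2.0], [1.0, 2.0])
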