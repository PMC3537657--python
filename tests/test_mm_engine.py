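"""Energy terms, analytic gradient, minimizer, conformational filters."""

import math

import numpy as np
import pytest

import titanoqsar as tq
from titanoqsar import mm_engine as mm
from titanoqsar.mm_engine import (SearchSettings, circular_difference_deg,
                                  conformational_search, is_duplicate,
                                  set_torsion, torsion_angle)

from conftest import fd_gradient


def naive_energy(mol, ff, coords):
    """Independent term-by-term re-summation of the same force field,
    written as a flat loop with its own angle/dihedral math."""
    e = 0.0
    # stretch
    for i, j, _ in mol.bonds:
        k, r0 = ff.bond_params(mol.elements[i], mol.elements[j])
        e += k * (np.linalg.norm(coords[i] - coords[j]) - r0) ** 2
    # bend via arccos
    nbrs = {i: sorted(mol.neighbors(i)) for i in range(mol.n_atoms)}
    for j in range(mol.n_atoms):
        ns = nbrs[j]
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                i, k = ns[a], ns[b]
                ka, t0 = ff.angle_params(mol.elements[i], mol.elements[j],
                                         mol.elements[k])
                u = coords[i] - coords[j]
                v = coords[k] - coords[j]
                cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                e += ka * (math.acos(np.clip(cos, -1, 1)) - t0) ** 2
    # torsions via the praxeolitic dihedral formula
    for j, k, _ in mol.bonds:
        for i in nbrs[j]:
            if i == k:
                continue
            for l in nbrs[k]:
                if l in (j, i):
                    continue
                params = ff.torsion_params(mol.elements[j], mol.elements[k])
                if params is None:
                    continue
                amp, n, phase = params
                b0 = coords[i] - coords[j]
                b1 = coords[k] - coords[j]
                b2 = coords[l] - coords[k]
                b1h = b1 / np.linalg.norm(b1)
                v = b0 - np.dot(b0, b1h) * b1h
                w = b2 - np.dot(b2, b1h) * b1h
                phi = math.atan2(np.dot(np.cross(b1h, v), w), np.dot(v, w))
                e += amp * (1 + math.cos(n * phi - phase))
    # nonbonded
    excl = set()
    for i, j, _ in mol.bonds:
        excl.add((min(i, j), max(i, j)))
    for j in range(mol.n_atoms):
        ns = nbrs[j]
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                excl.add((min(ns[a], ns[b]), max(ns[a], ns[b])))
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            if (i, j) in excl:
                continue
            ei, ri = ff.vdw_params(mol.elements[i])
            ej, rj = ff.vdw_params(mol.elements[j])
            eps, rmin = math.sqrt(ei * ej), ri + rj
            r = np.linalg.norm(coords[i] - coords[j])
            if ff.vdw_cutoff is not None and r > ff.vdw_cutoff:
                continue
            e += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
    # bond-dipole electrostatics (point dipoles at midpoints)
    dips = []
    for i, j, _ in mol.bonds:
        mu = ff.dipole(mol.elements[i], mol.elements[j])
        if mu:
            u = coords[j] - coords[i]
            dips.append((mu * u / np.linalg.norm(u),
                         0.5 * (coords[i] + coords[j]), {i, j}))
    for a in range(len(dips)):
        for b in range(a + 1, len(dips)):
            if dips[a][2] & dips[b][2]:
                continue
            rv = dips[b][1] - dips[a][1]
            r = np.linalg.norm(rv)
            ma, mb_ = dips[a][0], dips[b][0]
            e += (14.3928 / ff.dielectric) * (
                np.dot(ma, mb_) / r ** 3
                - 3 * np.dot(ma, rv) * np.dot(mb_, rv) / r ** 5)
    return e


class TestEnergy:
    def test_diatomic_at_equilibrium_has_zero_stretch(self, generic_ff):
        mol = tq.Molecule(elements=["C", "C"],
                          coords=[[0, 0, 0], [1.53, 0, 0]],
                          bonds=[(0, 1, 1)])
        conf = mm.energy(mol, generic_ff)
        assert conf.terms["stretch"] == pytest.approx(0.0, abs=1e-12)

    def test_vdw_pair_at_minimum(self):
        ff = mm.lj_forcefield(0.185, 3.4)
        mol = tq.Molecule(elements=["Ar", "Ar"],
                          coords=[[0, 0, 0], [3.4, 0, 0]])
        conf = mm.energy(mol, ff)
        assert conf.energy == pytest.approx(-0.185, abs=1e-12)

    def test_decomposition_sums_to_total(self, generic_ff):
        mol = tq.gen_random_molecule(8, ("C", "H", "O"), seed=1)
        conf = mm.energy(mol, generic_ff)
        assert sum(conf.terms.values()) == pytest.approx(conf.energy)

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_matches_naive_resummation_oracle(self, generic_ff, seed):
        mol = tq.gen_random_molecule(7, ("C", "H", "O", "Cl"), seed=seed)
        conf = mm.energy(mol, generic_ff)
        assert conf.energy == pytest.approx(
            naive_energy(mol, generic_ff, mol.coords), abs=1e-8)

    def test_dipole_term_matches_oracle(self, generic_ff):
        # two well-separated C-Cl bonds: a pure dipole-dipole interaction
        mol = tq.Molecule(elements=["C", "Cl", "C", "Cl"],
                          coords=[[0, 0, 0], [1.79, 0, 0],
                                  [0.3, 5.0, 0.4], [1.6, 5.8, 0.9]],
                          bonds=[(0, 1, 1), (2, 3, 1)])
        conf = mm.energy(mol, generic_ff)
        assert conf.terms["dipole"] != 0.0
        assert conf.energy == pytest.approx(
            naive_energy(mol, generic_ff, mol.coords), abs=1e-10)

    def test_translation_invariance(self, generic_ff):
        mol = tq.gen_random_molecule(6, ("C", "H"), seed=5)
        e0 = mm.energy(mol, generic_ff).energy
        e1 = mm.energy(mol, generic_ff, mol.coords + [10.0, -4.0, 2.5]).energy
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_unparameterized_interaction_errors(self):
        mol = tq.Molecule(elements=["C", "C"],
                          coords=[[0, 0, 0], [1.5, 0, 0]],
                          bonds=[(0, 1, 1)])
        with pytest.raises(mm.ParameterError):
            mm.energy(mol, mm.ForceField())


class TestGradient:
    def test_zero_at_diatomic_equilibrium(self, generic_ff):
        mol = tq.Molecule(elements=["C", "C"],
                          coords=[[0, 0, 0], [1.53, 0, 0]],
                          bonds=[(0, 1, 1)])
        assert np.abs(mm.gradient(mol, generic_ff)).max() < 1e-10

    @pytest.mark.parametrize("seed", [0, 2, 4, 7])
    def test_matches_finite_differences(self, generic_ff, seed):
        mol = tq.gen_random_molecule(7, ("C", "H", "O", "Si"), seed=seed)
        g = mm.gradient(mol, generic_ff)
        fd = fd_gradient(mol, generic_ff)
        scale = max(np.abs(fd).max(), 1.0)
        assert np.abs(g - fd).max() / scale < 1e-4

    def test_dipole_gradient_matches_finite_differences(self, generic_ff):
        mol = tq.Molecule(elements=["C", "Cl", "C", "Cl"],
                          coords=[[0, 0, 0], [1.79, 0, 0],
                                  [0.3, 5.0, 0.4], [1.6, 5.8, 0.9]],
                          bonds=[(0, 1, 1), (2, 3, 1)])
        g = mm.gradient(mol, generic_ff)
        fd = fd_gradient(mol, generic_ff)
        assert np.abs(g - fd).max() < 1e-6

    def test_translation_leaves_gradient_unchanged(self, generic_ff):
        mol = tq.gen_random_molecule(6, ("C", "H"), seed=5)
        g0 = mm.gradient(mol, generic_ff)
        g1 = mm.gradient(mol, generic_ff, mol.coords + [3.0, 3.0, 3.0])
        np.testing.assert_allclose(g0, g1, atol=1e-9)

    def test_rotation_equivariance(self, generic_ff):
        from scipy.spatial.transform import Rotation

        mol = tq.gen_random_molecule(6, ("C", "H", "O"), seed=9)
        rot = Rotation.from_euler("zyx", [30, 50, -20], degrees=True)
        g0 = mm.gradient(mol, generic_ff)
        g1 = mm.gradient(mol, generic_ff, rot.apply(mol.coords))
        np.testing.assert_allclose(g1, rot.apply(g0), atol=1e-8)


class TestMinimize:
    def test_start_at_minimum_returns_immediately(self, generic_ff):
        mol = tq.Molecule(elements=["C", "C"],
                          coords=[[0, 0, 0], [1.53, 0, 0]],
                          bonds=[(0, 1, 1)])
        conf, traj = mm.minimize(mol, generic_ff)
        assert traj[-1][0] <= 1

    def test_harmonic_bowl_converges_to_r0(self, generic_ff):
        mol = tq.Molecule(elements=["C", "C"],
                          coords=[[0, 0, 0], [2.03, 0, 0]],
                          bonds=[(0, 1, 1)])
        conf, traj = mm.minimize(mol, generic_ff)
        r = np.linalg.norm(conf.coords[1] - conf.coords[0])
        assert r == pytest.approx(1.53, abs=1e-3)
        energies = [e for _, e in traj]
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))
        assert energies[-1] <= energies[0]

    def test_matches_independent_minimizer(self, generic_ff):
        """Final energy agrees with a derivative-free Powell minimizer run
        from the same perturbed ethane-like start."""
        from scipy.optimize import minimize as sp_minimize

        mol = tq.gen_random_molecule(5, ("C", "H"), seed=12)
        rng = np.random.default_rng(0)
        start = mol.coords + rng.normal(0, 0.05, mol.coords.shape)
        conf, _ = mm.minimize(mol, generic_ff, coords=start,
                              rms_stop=1e-6, max_cycles=5000)
        res = sp_minimize(
            lambda v: mm.energy(mol, generic_ff,
                                v.reshape(-1, 3)).energy,
            start.ravel(), method="Powell",
            options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 100000})
        assert conf.energy == pytest.approx(res.fun, abs=1e-3)

    def test_frozen_atoms_do_not_move(self, generic_ff):
        mol = tq.Molecule(elements=["C", "C"],
                          coords=[[0, 0, 0], [2.0, 0, 0]],
                          bonds=[(0, 1, 1)])
        conf, _ = mm.minimize(mol, generic_ff, frozen=[0])
        np.testing.assert_array_equal(conf.coords[0], [0, 0, 0])

    def test_cycle_cap_default_is_15n(self):
        ff = mm.lj_forcefield(0.185, 3.4)
        mol = tq.Molecule(elements=["Ar"] * 2,
                          coords=[[0, 0, 0], [6.0, 0, 0]])
        _, traj = mm.minimize(mol, ff, rms_stop=1e-12)
        assert traj[-1][0] <= 15 * 2


class TestTorsionTools:
    def test_circular_difference(self):
        assert circular_difference_deg(359.0, 1.0) == pytest.approx(2.0)
        assert circular_difference_deg(-170.0, 170.0) == pytest.approx(20.0)

    def test_set_torsion_reaches_target(self, butane_like):
        quad = (0, 1, 2, 3)
        coords = set_torsion(butane_like, butane_like.coords, quad, 65.0)
        assert torsion_angle(coords, quad) == pytest.approx(65.0, abs=1e-9)

    def test_ring_bond_not_rotatable(self):
        ring = tq.Molecule(elements=["C"] * 3,
                           coords=[[0, 0, 0], [1.5, 0, 0], [0.75, 1.3, 0]],
                           bonds=[(0, 1, 1), (1, 2, 1), (2, 0, 1)])
        with pytest.raises(ValueError, match="ring"):
            set_torsion(ring, ring.coords, (2, 0, 1, 2), 10.0)


class TestDuplicateRule:
    def _conf(self, mol, coords, e, torsions=()):
        terms = {"stretch": e}
        return mm.Conformation(molecule=mol, coords=coords, energy=e,
                               terms=terms,
                               torsions=np.array([t for t, _ in torsions]),
                               flexible=tuple(q for _, q in torsions))

    def test_identical_conformations(self, butane_like):
        a = self._conf(butane_like, butane_like.coords, 1.0)
        assert is_duplicate(a, a)

    def test_all_criteria_failing(self, butane_like):
        quad = (0, 1, 2, 3)
        c0 = butane_like.coords
        c1 = set_torsion(butane_like, c0, quad, torsion_angle(c0, quad) + 180)
        a = self._conf(butane_like, c0, 0.0, [(torsion_angle(c0, quad), quad)])
        b = self._conf(butane_like, c1, 3.0, [(torsion_angle(c1, quad), quad)])
        assert not is_duplicate(a, b)

    def test_energy_criterion_alone_suffices(self, butane_like):
        quad = (0, 1, 2, 3)
        c0 = butane_like.coords
        c1 = set_torsion(butane_like, c0, quad, torsion_angle(c0, quad) + 170)
        a = self._conf(butane_like, c0, 1.00, [(0.0, quad)])
        b = self._conf(butane_like, c1, 1.04, [(170.0, quad)])
        assert is_duplicate(a, b)  # |dE| = 0.04 < 0.05

    def test_torsion_criterion_is_circular(self, butane_like):
        quad = (0, 1, 2, 3)
        a = self._conf(butane_like, butane_like.coords, 0.0, [(179.0, quad)])
        b = self._conf(butane_like, butane_like.coords + 5.0, 10.0,
                       [(-179.0, quad)])
        assert is_duplicate(a, b)  # 179 vs -179 differ by 2 degrees

    def test_different_molecules_rejected(self, butane_like):
        other = tq.Molecule(elements=["O", "O"],
                            coords=[[0, 0, 0], [1.2, 0, 0]],
                            bonds=[(0, 1, 1)])
        a = self._conf(butane_like, butane_like.coords, 0.0)
        b = self._conf(other, other.coords, 0.0)
        with pytest.raises(ValueError):
            is_duplicate(a, b)


class TestConformationalSearch:
    def test_rigid_molecule_single_conformation(self, generic_ff):
        mol = tq.Molecule(elements=["C", "C"],
                          coords=[[0, 0, 0], [1.6, 0, 0]],
                          bonds=[(0, 1, 1)])
        confs = conformational_search(mol, generic_ff)
        assert len(confs) == 1

    def test_anti_ranked_below_gauche(self, generic_ff, butane_like):
        """The threefold torsion profile puts the anti conformer below
        gauche; the search must list it first."""
        confs = conformational_search(
            butane_like, generic_ff, flexible=[(0, 1, 2, 3)],
            settings=SearchSettings(max_trials=40, seed=3))
        assert len(confs) >= 2
        assert circular_difference_deg(confs[0].torsions[0], 180.0) < 25
        # scan oracle: the minimized-anti energy really is the profile min
        energies = sorted(c.energy for c in confs)
        assert confs[0].energy == energies[0]

    def test_retained_conformers_sorted_and_distinct(self, generic_ff,
                                                     butane_like):
        confs = conformational_search(
            butane_like, generic_ff, flexible=[(0, 1, 2, 3)],
            settings=SearchSettings(max_trials=50, seed=7))
        energies = [c.energy for c in confs]
        assert energies == sorted(energies)
        assert len(confs) <= 20
        for i in range(len(confs)):
            for j in range(i + 1, len(confs)):
                assert not is_duplicate(confs[i], confs[j])

    def test_deterministic_per_seed(self, generic_ff, butane_like):
        s = SearchSettings(max_trials=25, seed=11)
        a = conformational_search(butane_like, generic_ff,
                                  flexible=[(0, 1, 2, 3)], settings=s)
        b = conformational_search(butane_like, generic_ff,
                                  flexible=[(0, 1, 2, 3)], settings=s)
        assert [c.energy for c in a] == [c.energy for c in b]

    def test_energy_window_respected(self, generic_ff, butane_like):
        confs = conformational_search(
            butane_like, generic_ff, flexible=[(0, 1, 2, 3)],
            settings=SearchSettings(max_trials=50, seed=1))
        e_min = confs[0].energy
        assert all(c.energy <= e_min + 4.0 for c in confs)

    def test_near_identical_trials_collapse_to_one(self, generic_ff):
        """A stiff one-minimum system: every trial re-minimizes into the
        same basin, so the duplicate rules leave a single survivor."""
        mol = tq.Molecule(elements=["C", "C", "C"],
                          coords=[[0, 0, 0], [1.53, 0, 0], [2.1, 1.4, 0]],
                          bonds=[(0, 1, 1), (1, 2, 1)])
        confs = conformational_search(
            mol, generic_ff, flexible=(),
            settings=SearchSettings(max_trials=30, seed=0))
        assert len(confs) == 1
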