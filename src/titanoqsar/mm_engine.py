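"""A minimal molecular-mechanics layer.

Implements the energy model used throughout the complexation protocol:
harmonic bond stretching, harmonic angle bending, cosine torsions,
12-6 Lennard-Jones van der Waals interactions, and bond-dipole
electrostatics (point dipoles at bond midpoints, MM2-style
14.3928/(D r^3) kernel with an effective dielectric D). Geometry
optimization is Polak-Ribiere conjugate gradient with an Armijo
backtracking line search, stopping when the RMS gradient drops below
0.005 kcal/mole/A or after fifteen times the atom count cycles (both
defaults overridable). A torsion-driving conformational search with the
protocol's acceptance window (4 kcal/mole above the running minimum),
duplicate filters (0.5 A heavy-atom displacement / 15 deg torsion
difference / 0.05 kcal/mole energy difference) and retention cap (20
conformers out of at most 1000 trials) sits on top.

The shipped generic parameter set is adequate for the small test systems
this package optimizes; absolute energies are deliberately not
comparable to any published force-field implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datasets_io import Molecule

__all__ = [
    "ForceField",
    "Conformation",
    "SearchSettings",
    "ParameterError",
    "generic_forcefield",
    "lj_forcefield",
    "energy",
    "gradient",
    "minimize",
    "conformational_search",
    "is_duplicate",
    "torsion_angle",
    "set_torsion",
    "circular_difference_deg",
]

#: dipole-dipole energy prefactor for debye^2 / A^3 -> kcal/mole
_DIPOLE_PREFACTOR = 14.3928


class ParameterError(KeyError):
    """A bonded tuple or nonbonded pair has no force-field parameters."""


def _pair_key(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ForceField:
    """Parameter tables keyed by element symbols.

    bond: (elem, elem) -> (k kcal/mole/A^2, r0 A)
    angle: (end, center, end) sorted ends -> (k kcal/mole/rad^2, theta0 rad)
    torsion: central (elem, elem) -> (amplitude kcal/mole, periodicity,
        phase rad); E = amp * (1 + cos(n*phi - phase))
    vdw: elem -> (well depth kcal/mole, half of the pair minimum-energy
        distance A); pairs combine as eps = sqrt(ei ej), rmin = ri + rj
    bond_dipole: (elem, elem) -> dipole magnitude (debye) pointing from
        the alphabetically first element toward the second
    """

    bond: Dict[Tuple[str, str], Tuple[float, float]] = field(
        default_factory=dict)
    angle: Dict[Tuple[str, str, str], Tuple[float, float]] = field(
        default_factory=dict)
    torsion: Dict[Tuple[str, str], Tuple[float, float, float]] = field(
        default_factory=dict)
    vdw: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    bond_dipole: Dict[Tuple[str, str], float] = field(default_factory=dict)
    dielectric: float = 1.5
    vdw_cutoff: Optional[float] = None
    #: wildcard parameters used when no specific entry exists; leave None
    #: for a strict field that errors on unparameterized tuples
    default_bond: Optional[Tuple[float, float]] = None
    default_angle: Optional[Tuple[float, float]] = None

    def bond_params(self, a: str, b: str):
        try:
            return self.bond[_pair_key(a, b)]
        except KeyError:
            if self.default_bond is not None:
                return self.default_bond
            raise ParameterError(f"no bond parameters for {a}-{b}")

    def angle_params(self, a: str, center: str, c: str):
        lo, hi = sorted((a, c))
        try:
            return self.angle[(lo, center, hi)]
        except KeyError:
            if self.default_angle is not None:
                return self.default_angle
            raise ParameterError(f"no angle parameters for {a}-{center}-{c}")

    def torsion_params(self, b: str, c: str):
        return self.torsion.get(_pair_key(b, c))

    def vdw_params(self, elem: str):
        try:
            return self.vdw[elem]
        except KeyError:
            raise ParameterError(f"no vdW parameters for {elem}")

    def dipole(self, a: str, b: str) -> float:
        """Signed dipole magnitude for a bond written a->b."""
        mu = self.bond_dipole.get(_pair_key(a, b), 0.0)
        if a > b:
            mu = -mu
        return mu


def generic_forcefield() -> ForceField:
    """A small documented generic parameter set (MM2-like forms) covering
    the elements of the test systems."""
    ff = ForceField()
    ff.bond = {
        _pair_key("C", "C"): (300.0, 1.53),
        _pair_key("C", "H"): (340.0, 1.09),
        _pair_key("C", "O"): (350.0, 1.43),
        _pair_key("O", "H"): (450.0, 0.96),
        _pair_key("C", "N"): (350.0, 1.47),
        _pair_key("C", "Si"): (250.0, 1.87),
        _pair_key("Si", "H"): (200.0, 1.48),
        _pair_key("C", "Cl"): (280.0, 1.79),
        _pair_key("C", "Ti"): (200.0, 2.35),
        _pair_key("Cl", "Ti"): (220.0, 2.30),
        _pair_key("Ar", "Ar"): (300.0, 3.40),
        _pair_key("He", "He"): (300.0, 2.60),
    }
    ff.angle = {
        ("C", "C", "C"): (60.0, math.radians(111.0)),
        ("C", "C", "H"): (45.0, math.radians(109.5)),
        ("H", "C", "H"): (40.0, math.radians(109.5)),
        ("C", "C", "O"): (60.0, math.radians(109.5)),
        ("C", "O", "H"): (50.0, math.radians(106.0)),
        ("C", "C", "Si"): (50.0, math.radians(112.0)),
        ("C", "Si", "C"): (45.0, math.radians(109.5)),
        ("Ar", "Ar", "Ar"): (80.0, math.radians(135.0)),
    }
    ff.torsion = {
        _pair_key("C", "C"): (1.4, 3.0, 0.0),
        _pair_key("C", "O"): (0.5, 3.0, 0.0),
        _pair_key("C", "Si"): (0.6, 3.0, 0.0),
    }
    ff.vdw = {
        "H": (0.020, 1.20), "C": (0.044, 1.75), "N": (0.055, 1.55),
        "O": (0.059, 1.40), "Si": (0.140, 2.10), "Cl": (0.240, 1.77),
        "Ti": (0.050, 2.20), "Ge": (0.200, 2.19),
        "He": (0.021, 1.30), "Ne": (0.069, 1.54), "Ar": (0.185, 1.88),
    }
    ff.bond_dipole = {
        _pair_key("C", "O"): 1.10,
        _pair_key("O", "H"): -1.51,
        _pair_key("C", "N"): 0.45,
        _pair_key("C", "Cl"): 1.90,
        _pair_key("C", "H"): -0.30,
    }
    ff.default_bond = (300.0, 1.50)
    ff.default_angle = (40.0, math.radians(109.5))
    return ff


def lj_forcefield(eps: float, rmin: float, k_bond: float = 500.0,
                  k_angle: float = 100.0,
                  cutoff: Optional[float] = None) -> ForceField:
    """Force field for Lennard-Jones toy particles (element Ar): pair
    well depth ``eps`` and pair minimum-energy distance ``rmin``; bonded
    terms (used by toy rings) are stiff harmonics whose r0/theta0 are
    taken from the input geometry at build time via ``bond``/``angle``
    overrides."""
    ff = ForceField()
    ff.vdw = {"Ar": (eps, rmin / 2.0)}
    ff.bond = {_pair_key("Ar", "Ar"): (k_bond, rmin)}
    ff.angle = {("Ar", "Ar", "Ar"): (k_angle, math.radians(135.0))}
    ff.vdw_cutoff = cutoff
    return ff


# --------------------------------------------------------------------------
# topology enumeration
# --------------------------------------------------------------------------

def _angles(mol: Molecule) -> List[Tuple[int, int, int]]:
    nbrs = [mol.neighbors(i) for i in range(mol.n_atoms)]
    out = []
    for j in range(mol.n_atoms):
        ns = sorted(nbrs[j])
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                out.append((ns[a], j, ns[b]))
    return out


def _torsions(mol: Molecule) -> List[Tuple[int, int, int, int]]:
    nbrs = [mol.neighbors(i) for i in range(mol.n_atoms)]
    out = []
    for j, k, _ in mol.bonds:
        for i in sorted(nbrs[j]):
            if i == k:
                continue
            for l in sorted(nbrs[k]):
                if l == j or l == i:
                    continue
                out.append((i, j, k, l))
    return out


def _excluded_pairs(mol: Molecule) -> set:
    """1-2 and 1-3 pairs, excluded from nonbonded terms."""
    excl = set()
    for i, j, _ in mol.bonds:
        excl.add(frozenset((i, j)))
    for a, j, c in _angles(mol):
        excl.add(frozenset((a, c)))
    return excl


def _dipole_bonds(mol: Molecule, ff: ForceField):
    out = []
    for i, j, _ in mol.bonds:
        mu = ff.dipole(mol.elements[i], mol.elements[j])
        if mu != 0.0:
            out.append((i, j, mu))
    return out


# --------------------------------------------------------------------------
# conformation container
# --------------------------------------------------------------------------

@dataclass
class Conformation:
    """A coordinate snapshot with its energy decomposition and, when
    flexible torsions are declared, the torsion-angle vector (degrees)."""

    molecule: Molecule
    coords: np.ndarray
    energy: float
    terms: Dict[str, float]
    torsions: np.ndarray = field(default_factory=lambda: np.empty(0))
    flexible: Tuple[Tuple[int, int, int, int], ...] = ()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        total = sum(self.terms.values())
        if abs(total - self.energy) > 1e-6 * max(1.0, abs(total)):
            raise ValueError("energy does not match its decomposition")
        if len(self.torsions) != len(self.flexible):
            raise ValueError("torsion vector length mismatch")


# --------------------------------------------------------------------------
# energy and gradient
# --------------------------------------------------------------------------

def torsion_angle(coords: np.ndarray, quad) -> float:
    """Signed dihedral angle in degrees for atoms (i, j, k, l)."""
    i, j, k, l = quad
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return math.degrees(math.atan2(y, x))


def _energy_terms(mol: Molecule, ff: ForceField, coords: np.ndarray,
                  want_gradient: bool):
    n = mol.n_atoms
    terms = {"stretch": 0.0, "bend": 0.0, "torsion": 0.0,
             "vdw": 0.0, "dipole": 0.0}
    grad = np.zeros((n, 3)) if want_gradient else None

    # stretch
    for i, j, _ in mol.bonds:
        k_b, r0 = ff.bond_params(mol.elements[i], mol.elements[j])
        d = coords[i] - coords[j]
        r = float(np.linalg.norm(d))
        terms["stretch"] += k_b * (r - r0) ** 2
        if want_gradient and r > 1e-12:
            g = 2 * k_b * (r - r0) * d / r
            grad[i] += g
            grad[j] -= g

    # bend
    for a, j, c in _angles(mol):
        k_a, theta0 = ff.angle_params(mol.elements[a], mol.elements[j],
                                      mol.elements[c])
        u = coords[a] - coords[j]
        v = coords[c] - coords[j]
        lu = float(np.linalg.norm(u))
        lv = float(np.linalg.norm(v))
        if lu < 1e-12 or lv < 1e-12:
            continue
        uh, vh = u / lu, v / lv
        cos_t = float(np.clip(uh @ vh, -1.0, 1.0))
        theta = math.acos(cos_t)
        terms["bend"] += k_a * (theta - theta0) ** 2
        if want_gradient:
            sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-12))
            dth_da = (cos_t * uh - vh) / (lu * sin_t)
            dth_dc = (cos_t * vh - uh) / (lv * sin_t)
            pref = 2 * k_a * (theta - theta0)
            grad[a] += pref * dth_da
            grad[c] += pref * dth_dc
            grad[j] -= pref * (dth_da + dth_dc)

    # torsion
    for quad in _torsions(mol):
        i, j, k, l = quad
        params = ff.torsion_params(mol.elements[j], mol.elements[k])
        if params is None:
            continue
        amp, period, phase = params
        b1 = coords[j] - coords[i]
        b2 = coords[k] - coords[j]
        b3 = coords[l] - coords[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        l2 = float(np.linalg.norm(b2))
        n1sq = float(n1 @ n1)
        n2sq = float(n2 @ n2)
        if l2 < 1e-12 or n1sq < 1e-18 or n2sq < 1e-18:
            continue
        phi = math.radians(torsion_angle(coords, quad))
        terms["torsion"] += amp * (1 + math.cos(period * phi - phase))
        if want_gradient:
            de_dphi = -amp * period * math.sin(period * phi - phase)
            # derivatives of the atan2-convention dihedral
            dphi_di = (l2 / n1sq) * n1
            dphi_dl = -(l2 / n2sq) * n2
            f1 = float(b1 @ b2) / (l2 * l2)
            f3 = float(b3 @ b2) / (l2 * l2)
            dphi_dj = -(1.0 + f1) * dphi_di + f3 * dphi_dl
            dphi_dk = f1 * dphi_di - (1.0 + f3) * dphi_dl
            grad[i] += de_dphi * dphi_di
            grad[j] += de_dphi * dphi_dj
            grad[k] += de_dphi * dphi_dk
            grad[l] += de_dphi * dphi_dl

    # van der Waals (12-6), excluding 1-2 and 1-3 pairs
    excl = _excluded_pairs(mol)
    cutoff = ff.vdw_cutoff
    for i in range(n):
        eps_i, ri = ff.vdw_params(mol.elements[i])
        for j in range(i + 1, n):
            if frozenset((i, j)) in excl:
                continue
            eps_j, rj = ff.vdw_params(mol.elements[j])
            eps = math.sqrt(eps_i * eps_j)
            rmin = ri + rj
            d = coords[i] - coords[j]
            r = float(np.linalg.norm(d))
            if r < 1e-9 or (cutoff is not None and r > cutoff):
                continue
            s6 = (rmin / r) ** 6
            terms["vdw"] += eps * (s6 * s6 - 2 * s6)
            if want_gradient:
                de_dr = 12 * eps * (-s6 * s6 + s6) / r
                g = de_dr * d / r
                grad[i] += g
                grad[j] -= g

    # bond-dipole electrostatics between non-adjacent bond dipoles
    dipoles = _dipole_bonds(mol, ff)
    pref = _DIPOLE_PREFACTOR / ff.dielectric
    for a in range(len(dipoles)):
        pa, qa, ma = dipoles[a]
        for b in range(a + 1, len(dipoles)):
            pb, qb, mb = dipoles[b]
            if len({pa, qa, pb, qb}) < 4:
                continue  # bonds sharing an atom: handled by bonded terms
            e, g4 = _dipole_pair(coords, pa, qa, ma, pb, qb, mb, pref,
                                 want_gradient)
            terms["dipole"] += e
            if want_gradient:
                for idx, gv in zip((pa, qa, pb, qb), g4):
                    grad[idx] += gv

    total = float(sum(terms.values()))
    return total, terms, grad


def _dipole_pair(coords, pa, qa, ma, pb, qb, mb, pref, want_gradient):
    """Point-dipole interaction between bond dipoles a (atoms pa->qa) and
    b (atoms pb->qb), located at the bond midpoints."""
    ba = coords[qa] - coords[pa]
    bb = coords[qb] - coords[pb]
    la = float(np.linalg.norm(ba))
    lb = float(np.linalg.norm(bb))
    ua = ba / la
    ub = bb / lb
    mua = ma * ua
    mub = mb * ub
    rv = 0.5 * (coords[pb] + coords[qb]) - 0.5 * (coords[pa] + coords[qa])
    r = float(np.linalg.norm(rv))
    if r < 1e-9:
        return 0.0, None
    s3 = r ** -3
    s5 = r ** -5
    A = float(mua @ mub)
    B = float(mua @ rv)
    C = float(mub @ rv)
    e = pref * (A * s3 - 3 * B * C * s5)
    if not want_gradient:
        return e, None
    s7 = r ** -7
    dE_drv = pref * (-3 * A * s5 * rv - 3 * (C * mua + B * mub) * s5
                     + 15 * B * C * s7 * rv)
    dE_dmua = pref * (mub * s3 - 3 * C * rv * s5)
    dE_dmub = pref * (mua * s3 - 3 * B * rv * s5)
    # chain rule through unit vectors and midpoints
    proj_a = (np.eye(3) - np.outer(ua, ua)) / la
    proj_b = (np.eye(3) - np.outer(ub, ub)) / lb
    g_qa = ma * proj_a @ dE_dmua - 0.5 * dE_drv
    g_pa = -ma * proj_a @ dE_dmua - 0.5 * dE_drv
    g_qb = mb * proj_b @ dE_dmub + 0.5 * dE_drv
    g_pb = -mb * proj_b @ dE_dmub + 0.5 * dE_drv
    return e, (g_pa, g_qa, g_pb, g_qb)


def energy(mol: Molecule, ff: ForceField,
           coords: Optional[np.ndarray] = None,
           flexible: Sequence = ()) -> Conformation:
    """Total potential energy with its term decomposition."""
    if coords is None:
        coords = mol.coords
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    total, terms, _ = _energy_terms(mol, ff, coords, want_gradient=False)
    tors = np.array([torsion_angle(coords, q) for q in flexible])
    return Conformation(molecule=mol, coords=coords.copy(), energy=total,
                        terms=terms, torsions=tors,
                        flexible=tuple(tuple(q) for q in flexible))


def gradient(mol: Molecule, ff: ForceField,
             coords: Optional[np.ndarray] = None) -> np.ndarray:
    """Analytic gradient of the total energy, kcal/mole/A, shape (n, 3)."""
    if coords is None:
        coords = mol.coords
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    _, _, grad = _energy_terms(mol, ff, coords, want_gradient=True)
    return grad


# --------------------------------------------------------------------------
# minimization
# --------------------------------------------------------------------------

def minimize(mol: Molecule, ff: ForceField,
             rms_stop: float = 0.005,
             max_cycles: Optional[int] = None,
             coords: Optional[np.ndarray] = None,
             frozen: Sequence[int] = (),
             flexible: Sequence = ()):
    """Polak-Ribiere conjugate-gradient minimization.

    Stops when the RMS gradient (over free coordinates) falls below
    ``rms_stop`` (default 0.005 kcal/mole/A) or after ``max_cycles``
    (default fifteen times the atom count). The line search is Armijo
    backtracking with quadratic interpolation; the direction restarts to
    steepest descent every 3N cycles or when the Polak-Ribiere beta is
    negative. ``frozen`` atom indices are held fixed.

    Returns ``(Conformation, trajectory)`` where trajectory is a list of
    ``(cycle, energy)`` pairs with strictly increasing cycle indices and
    final energy never above the initial energy.
    """
    if rms_stop <= 0:
        raise ValueError("rms_stop must be positive")
    if max_cycles is None:
        max_cycles = 15 * mol.n_atoms
    x = (mol.coords if coords is None else
         np.asarray(coords, dtype=float).reshape(-1, 3)).copy()
    free = np.ones_like(x, dtype=bool)
    for i in frozen:
        free[i] = False

    def eg(xx):
        e, _, g = _energy_terms(mol, ff, xx, want_gradient=True)
        g = np.where(free, g, 0.0)
        return e, g

    e, g = eg(x)
    trajectory = [(0, e)]
    best_x, best_e = x.copy(), e
    nfree = int(free.sum())
    d = -g
    g_prev = g
    cycle = 0
    while cycle < max_cycles:
        rms = math.sqrt(float(np.sum(g * g)) / max(nfree, 1))
        if rms < rms_stop:
            break
        cycle += 1
        if cycle % max(3 * mol.n_atoms, 1) == 0:
            d = -g
        slope = float(np.sum(g * d))
        if slope >= 0:
            d = -g
            slope = float(np.sum(g * d))
        # Armijo backtracking with quadratic interpolation
        gnorm = math.sqrt(max(float(np.sum(d * d)), 1e-30))
        alpha = min(1.0, 0.5 / gnorm)
        e_new, g_new, x_new = None, None, None
        ok = False
        for _ in range(40):
            x_try = x + alpha * d
            e_try, g_try = eg(x_try)
            if e_try <= e + 1e-4 * alpha * slope:
                e_new, g_new, x_new = e_try, g_try, x_try
                ok = True
                break
            # quadratic interpolation on the line, clamped
            denom = 2.0 * (e_try - e - alpha * slope)
            alpha_q = (-slope * alpha ** 2 / denom if denom > 0
                       else alpha / 2)
            alpha = min(max(alpha_q, 0.1 * alpha), 0.5 * alpha)
        if not ok:
            break  # line-search failure: return best-so-far
        x = x_new
        e = e_new
        g_prev, g = g, g_new
        trajectory.append((cycle, e))
        if e < best_e:
            best_e, best_x = e, x.copy()
        beta = float(np.sum(g * (g - g_prev)) / max(np.sum(g_prev * g_prev),
                                                    1e-30))
        if beta < 0:
            d = -g
        else:
            d = -g + beta * d
    conf = energy(mol, ff, coords=best_x, flexible=flexible)
    return conf, trajectory


# --------------------------------------------------------------------------
# conformational search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSettings:
    """Torsion-driving settings: trial displacements drawn uniformly from
    +/-[lo, hi] degrees, conformers accepted within ``window`` kcal/mole
    of the running minimum, at most ``max_keep`` retained from at most
    ``max_trials`` trials."""

    max_trials: int = 1000
    max_keep: int = 20
    window: float = 4.0
    torsion_lo: float = 60.0
    torsion_hi: float = 180.0
    seed: int = 0


def circular_difference_deg(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees (359 vs 1 -> 2)."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _heavy_indices(mol: Molecule) -> np.ndarray:
    return np.array([i for i, s in enumerate(mol.elements) if s != "H"],
                    dtype=int)


def _max_displacement_superposed(p: np.ndarray, q: np.ndarray) -> float:
    """Max point displacement after optimal rigid superposition (Kabsch)."""
    from scipy.spatial.transform import Rotation

    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    if len(pc) == 1:
        return 0.0
    rot, _ = Rotation.align_vectors(pc, qc)
    qr = rot.apply(qc)
    return float(np.max(np.linalg.norm(pc - qr, axis=1)))


def is_duplicate(a: Conformation, b: Conformation) -> bool:
    """Duplicate filter of the conformational protocol.

    Two conformations of the same molecule are duplicates when ANY of:
    heavy-atom displacement after optimal superposition below 0.5 A,
    every flexible-torsion difference below 15 degrees (circular), or
    energy difference below 0.05 kcal/mole. Hydrogens are excluded from
    the distance test; the torsion criterion is skipped when no flexible
    torsions are declared.
    """
    if a.molecule is not b.molecule and (
            a.molecule.elements != b.molecule.elements):
        raise ValueError("conformations belong to different molecules")
    if abs(a.energy - b.energy) < 0.05:
        return True
    if len(a.torsions) and len(a.torsions) == len(b.torsions):
        if all(circular_difference_deg(x, y) < 15.0
               for x, y in zip(a.torsions, b.torsions)):
            return True
    heavy = _heavy_indices(a.molecule)
    if len(heavy):
        if _max_displacement_superposed(a.coords[heavy],
                                        b.coords[heavy]) < 0.5:
            return True
    return False


def _bond_side(mol: Molecule, j: int, k: int) -> List[int]:
    """Atoms on the k side of bond (j, k) when that bond is removed."""
    adj = {i: set() for i in range(mol.n_atoms)}
    for a, b, _ in mol.bonds:
        adj[a].add(b)
        adj[b].add(a)
    adj[j].discard(k)
    adj[k].discard(j)
    seen = {k}
    stack = [k]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if j in seen:
        raise ValueError(f"bond ({j},{k}) is in a ring; not rotatable")
    seen.discard(k)
    return sorted(seen)


def set_torsion(mol: Molecule, coords: np.ndarray, quad,
                target_deg: float) -> np.ndarray:
    """Return coordinates with dihedral (i,j,k,l) rotated to
    ``target_deg`` by turning the l-side of bond (j,k)."""
    from scipy.spatial.transform import Rotation

    i, j, k, l = quad
    coords = np.asarray(coords, dtype=float).reshape(-1, 3).copy()
    current = torsion_angle(coords, quad)
    # rotating the l-side about +axis decreases the atan2-convention angle
    delta = -math.radians(target_deg - current)
    axis = coords[k] - coords[j]
    axis = axis / np.linalg.norm(axis)
    movers = _bond_side(mol, j, k)
    rot = Rotation.from_rotvec(delta * axis)
    coords[movers] = rot.apply(coords[movers] - coords[k]) + coords[k]
    return coords


def conformational_search(mol: Molecule, ff: ForceField,
                          flexible: Sequence = (),
                          settings: SearchSettings = SearchSettings()
                          ) -> List[Conformation]:
    """Random torsion driving with the protocol's filters.

    Each trial perturbs every declared flexible torsion by a displacement
    drawn uniformly from +/-[60, 180] degrees, minimizes, and applies the
    acceptance window and duplicate rules. Returns at most ``max_keep``
    conformers sorted ascending by energy; with no flexible torsions the
    minimized input is the single result. Deterministic per seed.
    """
    flexible = tuple(tuple(q) for q in flexible)
    base, _ = minimize(mol, ff, flexible=flexible)
    if not flexible:
        return [base]
    rng = np.random.default_rng(settings.seed)
    kept: List[Conformation] = [base]
    e_min = base.energy
    for _ in range(settings.max_trials):
        start = kept[int(rng.integers(len(kept)))]
        coords = start.coords.copy()
        for qi, quad in enumerate(flexible):
            lo, hi = settings.torsion_lo, settings.torsion_hi
            delta = rng.uniform(lo, hi) * (1 if rng.random() < 0.5 else -1)
            coords = set_torsion(mol, coords, quad,
                                 start.torsions[qi] + delta)
        cand, _ = minimize(mol, ff, coords=coords, flexible=flexible)
        if cand.energy < e_min:
            e_min = cand.energy
        kept = [c for c in kept if c.energy <= e_min + settings.window]
        if cand.energy > e_min + settings.window:
            continue
        replaced = False
        duplicate = False
        for idx, c in enumerate(kept):
            if is_duplicate(cand, c):
                duplicate = True
                if cand.energy < c.energy:
                    kept[idx] = cand
                    replaced = True
                break
        if not duplicate:
            kept.append(cand)
        elif not replaced:
            continue
        kept.sort(key=lambda c: c.energy)
        del kept[settings.max_keep:]
    kept.sort(key=lambda c: c.energy)
    return kept
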