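"""Generators for synthetic inputs with the statistical and geometric
structure the analysis assumes.

Three generators cover the three layers of the pipeline:

* :func:`gen_qsar_dataset` draws (x, y) data from the monolinear
  generative model y = a0 + b*x + N(0, sigma) that underlies the QSAR
  fits, keeping the truth for parameter-recovery tests. Defaults mirror
  the strongest published activity model (a0=3.40, b=0.69, logP-like x
  range, n=11) with sigma=0.15 pA units, the scale of the observed
  experimental-minus-predicted differences.
* :func:`gen_random_molecule` grows connected random 3D molecules with
  plausible bond lengths, used by the descriptor and mechanics property
  tests.
* :func:`gen_toy_complex` builds a Lennard-Jones ring host plus guest
  whose optimal axial interaction energy is known from a dense grid
  search, standing in for the cyclodextrin cavity geometry.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .datasets_io import Molecule
from .mm_engine import ForceField, lj_forcefield

__all__ = [
    "SyntheticQsarSpec",
    "ToyComplexSpec",
    "gen_qsar_dataset",
    "gen_random_molecule",
    "gen_toy_complex",
]


@dataclass(frozen=True)
class SyntheticQsarSpec:
    """Generative settings for a univariate linear activity model."""

    n: int = 11
    a0: float = 3.40
    b: float = 0.69
    x_range: Tuple[float, float] = (0.3, 1.7)
    sigma: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("n must be at least 3")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not self.x_range[1] > self.x_range[0]:
            raise ValueError("x_range must be increasing")


def gen_qsar_dataset(spec: SyntheticQsarSpec):
    """Draw one dataset; returns ``(x, y, truth)`` with truth carrying
    the generating coefficients. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(spec.x_range[0], spec.x_range[1], size=spec.n)
    noise = rng.normal(0.0, spec.sigma, size=spec.n) if spec.sigma > 0 \
        else np.zeros(spec.n)
    y = spec.a0 + spec.b * x + noise
    truth = {"a0": spec.a0, "b": spec.b, "sigma": spec.sigma}
    return x, y, truth


def gen_random_molecule(n_atoms: int, elements: Tuple[str, ...] = ("C",),
                        seed: int = 0, min_dist: float = 0.8,
                        bond_range: Tuple[float, float] = (1.0, 1.8),
                        max_retries: int = 200) -> Molecule:
    """Grow a connected random molecule: each new atom bonds to a random
    existing atom at a bond length in ``bond_range``, rejecting
    placements that bring any pair closer than ``min_dist``."""
    if n_atoms < 1:
        raise ValueError("n_atoms must be at least 1")
    rng = np.random.default_rng(seed)
    syms = [elements[int(rng.integers(len(elements)))]
            for _ in range(n_atoms)]
    coords = np.zeros((n_atoms, 3))
    bonds: List[Tuple[int, int, int]] = []
    for i in range(1, n_atoms):
        for attempt in range(max_retries):
            anchor = int(rng.integers(i))
            length = rng.uniform(*bond_range)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            pos = coords[anchor] + length * v
            d = np.linalg.norm(coords[:i] - pos, axis=1)
            if np.all(d >= min_dist):
                coords[i] = pos
                bonds.append((anchor, i, 1))
                break
        else:
            raise RuntimeError(
                f"could not place atom {i} after {max_retries} tries")
    return Molecule(elements=syms, coords=coords, bonds=bonds,
                    name=f"random{n_atoms}_{seed}")


@dataclass(frozen=True)
class ToyComplexSpec:
    """A Lennard-Jones ring host (cyclodextrin-cavity stand-in) and a
    small axial guest."""

    ring_atoms: int = 8
    ring_radius: float = 3.4   # A; near the LJ pair minimum for a snug fit
    guest_atoms: int = 1
    eps: float = 0.185         # kcal/mole (argon-like)
    rmin: float = 3.4          # A, pair minimum-energy distance
    guest_spacing: float = 1.2
    seed: int = 0

    def __post_init__(self):
        if self.ring_radius <= 0:
            raise ValueError("ring radius must be positive")
        if self.ring_atoms < 3 or self.guest_atoms < 1:
            raise ValueError("need >= 3 ring atoms and >= 1 guest atom")


def _ring_host(spec: ToyComplexSpec) -> Molecule:
    n = spec.ring_atoms
    angles = 2 * np.pi * np.arange(n) / n
    coords = np.column_stack([spec.ring_radius * np.cos(angles),
                              spec.ring_radius * np.sin(angles),
                              np.zeros(n)])
    bonds = [(i, (i + 1) % n, 1) for i in range(n)]
    return Molecule(elements=["Ar"] * n, coords=coords, bonds=bonds,
                    name=f"ring{n}r{spec.ring_radius:g}",
                    metadata={"primary_face_normal": (0.0, 0.0, 1.0)})


def _axial_guest(spec: ToyComplexSpec) -> Molecule:
    # guest particles are Ne so the toy force field can give the rod its
    # own bonded terms while keeping the same host-guest LJ pair
    n = spec.guest_atoms
    z = (np.arange(n) - (n - 1) / 2) * spec.guest_spacing
    coords = np.column_stack([np.zeros(n), np.zeros(n), z])
    bonds = [(i, i + 1, 1) for i in range(n - 1)]
    return Molecule(elements=["Ne"] * n, coords=coords, bonds=bonds,
                    name=f"guest{n}")


def _pair_lj(eps: float, rmin: float, r: np.ndarray) -> np.ndarray:
    s6 = (rmin / r) ** 6
    return eps * (s6 * s6 - 2 * s6)


def gen_toy_complex(spec: ToyComplexSpec):
    """Build the toy host-guest system and its axial oracle.

    Returns ``(host, guest, forcefield, oracle)`` where oracle is a dict
    with the optimal axial offset ``z_opt`` (A) and the rigid-geometry
    interaction energy ``e_int`` (kcal/mole) found by a dense grid
    search of the guest translated along the ring axis (0.005 A pitch).
    The oracle is an independent reference for the complex optimizer: it
    never calls the minimizer.
    """
    host = _ring_host(spec)
    guest = _axial_guest(spec)
    ff = lj_forcefield(spec.eps, spec.rmin)
    # stiff bonded terms matched to the built geometries keep host and
    # guest effectively rigid during complex optimization; Ne vdW set so
    # host-guest pairs see the same (eps, rmin) as Ar-Ar
    chord = 2 * spec.ring_radius * math.sin(math.pi / spec.ring_atoms)
    ff.bond = {("Ar", "Ar"): (500.0, chord),
               ("Ne", "Ne"): (500.0, spec.guest_spacing)}
    ff.angle = {("Ar", "Ar", "Ar"):
                (100.0, math.pi - 2 * math.pi / spec.ring_atoms),
                ("Ne", "Ne", "Ne"): (100.0, math.pi)}
    ff.vdw["Ne"] = (spec.eps, spec.rmin / 2.0)
    ring_xy = host.coords[:, :2]
    ring_r = np.linalg.norm(ring_xy, axis=1)
    guest_z = guest.coords[:, 2]
    zs = np.arange(-8.0, 8.0 + 1e-9, 0.005)
    inter = np.zeros_like(zs)
    for gz in guest_z:
        # distance from each ring atom to a guest atom at axial offset z+gz
        d = np.sqrt(ring_r[None, :] ** 2 + (zs[:, None] + gz) ** 2)
        inter += _pair_lj(spec.eps, spec.rmin, d).sum(axis=1)
    k = int(np.argmin(inter))
    oracle = {"z_opt": float(zs[k]), "e_int": float(-inter[k])}
    return host, guest, ff, oracle
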