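"""The six structural descriptors, computed from a 3D Molecule.

The study characterizes each titanocene by van der Waals surface area
S_vdw (A^2), van der Waals volume V_vdw (A^3, grid counting over the
union of atomic spheres), hydration energy E_hydr (kcal/mole, exposed
surface area weighted by an atom-class coefficient), logP and molar
refractivity Rf (sums of atomic contributions, metal atoms excluded from
logP/Rf), and polarizability Pol (A^3, additive atom-type increments).

The original tool's internal parameter tables are unpublished, so this
module ships its own versioned registry (:data:`PARAMS_V1`) assembled in
the style of the cited literature sources: Gavezzotti-type van der Waals
radii, Ghose-Crippen-type logP/refractivity atomic contributions,
Miller-type polarizability increments, and Ooi-type hydration
coefficients per exposed A^2. Absolute agreement with the published
descriptor table is therefore not expected (nor asserted anywhere);
correctness is established against geometric and additive oracles.

Contribution classes are assigned from the bond orders given in the
input structure (aromatic = order 4); there is no aromaticity or
hybridization re-perception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .datasets_io import Molecule

__all__ = [
    "AtomParams",
    "ParamRegistry",
    "DescriptorSet",
    "PARAMS_V1",
    "MissingParameterError",
    "contribution_class",
    "is_metal",
    "vdw_volume_grid",
    "vdw_surface_area",
    "hydration_energy",
    "logp_atomic",
    "refractivity_atomic",
    "polarizability_miller",
    "descriptor_set",
]


class MissingParameterError(KeyError):
    """No parameter entry for an element or contribution class."""


@dataclass(frozen=True)
class AtomParams:
    """Per contribution class: vdW radius (A), logP contribution, molar
    refractivity contribution (A^3), polarizability increment (A^3) and
    hydration coefficient (kcal/mole per exposed A^2), with a provenance
    note."""

    radius: float
    logp: Optional[float]
    mr: Optional[float]
    pol: Optional[float]
    hydr: float
    provenance: str = ""

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class ParamRegistry:
    version: str
    entries: Dict[str, AtomParams]
    #: elements stripped from logP/Rf sums ("metal atoms were excluded");
    #: all d- and f-block elements by default.
    extra_metals: Tuple[str, ...] = ()

    def get(self, cls: str) -> AtomParams:
        try:
            return self.entries[cls]
        except KeyError:
            raise MissingParameterError(
                f"no parameters for contribution class {cls!r} "
                f"in set {self.version!r}")


_D_F_BLOCK = (set(range(21, 31)) | set(range(39, 49)) |
              set(range(57, 81)) | set(range(89, 104)))

_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Si": 14, "P": 15, "S": 16,
      "Cl": 17, "Ti": 22, "Fe": 26, "Zn": 30, "Ge": 32, "Br": 35,
      "Zr": 40, "I": 53}


def is_metal(symbol: str, registry: Optional[ParamRegistry] = None) -> bool:
    """True for d-/f-block elements (plus any registry-configured extras)."""
    if registry is not None and symbol in registry.extra_metals:
        return True
    z = _Z.get(symbol)
    if z is None:
        from rdkit import Chem
        z = Chem.GetPeriodicTable().GetAtomicNumber(symbol)
    return z in _D_F_BLOCK


# Radii follow Gavezzotti-style crystallographic vdW values; contribution
# values are literature-style per-class increments chosen to keep the
# additive sums on the published scale. Keys: element, optionally
# suffixed with a hybridization/aromaticity class for C and N.
_GAV = "Gavezzotti-type vdW radius"
_GC = "Ghose-Crippen-type atomic contribution"
_MIL = "Miller-type polarizability increment"
_OOI = "Ooi-type hydration coefficient"

PARAMS_V1 = ParamRegistry(
    version="titanoqsar-v1",
    entries={
        "H":    AtomParams(1.17, 0.123, 1.057, 0.387, 0.000,
                           f"{_GAV}; {_GC}; {_MIL}"),
        "C.3":  AtomParams(1.75, 0.195, 2.503, 1.061, 0.008,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "C.2":  AtomParams(1.75, 0.236, 3.625, 1.382, 0.008,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "C.1":  AtomParams(1.75, 0.331, 3.884, 1.283, 0.008,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "C.ar": AtomParams(1.75, 0.294, 3.509, 1.352, 0.008,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "N.3":  AtomParams(1.55, -0.598, 2.134, 0.964, -0.172,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "N.ar": AtomParams(1.55, -0.239, 2.751, 1.030, -0.172,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "N.+":  AtomParams(1.55, -1.950, 2.998, 1.090, -0.186,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "O":    AtomParams(1.40, -0.467, 1.637, 0.637, -0.172,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "F":    AtomParams(1.30, 0.375, 1.157, 0.296, -0.021,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "Si":   AtomParams(2.10, 0.540, 7.870, 3.962, 0.008,
                           f"{_GAV}; {_GC}; {_MIL}"),
        "P":    AtomParams(1.80, -0.447, 6.920, 1.538, -0.021,
                           f"{_GAV}; {_GC}; {_MIL}"),
        "S":    AtomParams(1.80, 0.419, 7.365, 2.994, -0.021,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "Cl":   AtomParams(1.77, 0.512, 5.853, 2.315, -0.021,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "Br":   AtomParams(1.92, 0.850, 8.927, 3.013, -0.021,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        "I":    AtomParams(2.06, 1.050, 14.02, 5.415, -0.021,
                           f"{_GAV}; {_GC}; {_MIL}; {_OOI}"),
        # metals: radius for geometry; no logP/Rf contribution (excluded)
        "Ti":   AtomParams(2.20, None, None, 3.240, 0.000,
                           f"{_GAV}; {_MIL}"),
        "Zr":   AtomParams(2.30, None, None, 4.100, 0.000,
                           f"{_GAV}; {_MIL}"),
        "Fe":   AtomParams(2.05, None, None, 2.560, 0.000,
                           f"{_GAV}; {_MIL}"),
        "Ge":   AtomParams(2.19, 0.630, 8.540, 4.300, 0.008,
                           f"{_GAV}; {_GC}; {_MIL}"),
        # noble-gas probe particles used by the toy mechanics layer
        "He":   AtomParams(1.40, 0.000, 0.520, 0.205, 0.000, _GAV),
        "Ne":   AtomParams(1.54, 0.000, 0.999, 0.396, 0.000, _GAV),
        "Ar":   AtomParams(1.88, 0.000, 4.197, 1.641, 0.000, _GAV),
    },
)


@dataclass(frozen=True)
class DescriptorSet:
    """One computed Table-of-descriptors row plus provenance of how the
    grid volume was obtained."""

    s_vdw: float
    v_vdw: float
    e_hydr: float
    logp: float
    rf: float
    pol: float
    grid_spacing: float
    params_version: str
    n_metal_skipped: int = 0


# --------------------------------------------------------------------------
# class assignment
# --------------------------------------------------------------------------

def contribution_class(mol: Molecule, i: int) -> str:
    """Contribution class for atom ``i`` from the bond orders as given.

    Carbon and nitrogen are split by bonding environment (sp3/sp2/sp,
    aromatic via order-4 bonds, protonated N via formal charge); every
    other element maps to its symbol.
    """
    sym = mol.elements[i]
    if sym not in ("C", "N"):
        return sym
    orders = [o for a, b, o in mol.bonds if i in (a, b)]
    aromatic = any(o == 4 for o in orders)
    if sym == "N":
        if mol.charges is not None and mol.charges[i] > 0:
            return "N.+"
        return "N.ar" if aromatic else "N.3"
    if aromatic:
        return "C.ar"
    if any(o == 3 for o in orders) or orders.count(2) >= 2:
        return "C.1"
    if any(o == 2 for o in orders):
        return "C.2"
    return "C.3"


def _radii(mol: Molecule, registry: ParamRegistry) -> np.ndarray:
    if mol.radii is not None:
        return np.asarray(mol.radii, dtype=float)
    out = np.empty(mol.n_atoms)
    for i, sym in enumerate(mol.elements):
        out[i] = registry.get(contribution_class(mol, i)).radius
    return out


# --------------------------------------------------------------------------
# geometric descriptors
# --------------------------------------------------------------------------

def vdw_volume_grid(mol: Molecule, spacing: float = 0.2,
                    registry: ParamRegistry = PARAMS_V1) -> float:
    """Van der Waals volume (A^3) by grid counting.

    A cubic grid of pitch ``spacing`` is anchored at the molecular
    bounding box minus one maximum-radius margin; the volume is the
    number of grid points falling inside the union of atomic spheres
    times spacing^3. Deterministic for a given molecule and spacing.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if mol.n_atoms == 0:
        return 0.0
    radii = _radii(mol, registry)
    rmax = float(radii.max())
    lo = mol.coords.min(axis=0) - rmax - spacing
    hi = mol.coords.max(axis=0) + rmax + spacing
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    shape = tuple(len(a) for a in axes)
    inside = np.zeros(shape, dtype=bool)
    for center, r in zip(mol.coords, radii):
        # restrict to the sub-box around this sphere
        sl, local = [], []
        for d in range(3):
            a = axes[d]
            i0 = int(np.searchsorted(a, center[d] - r))
            i1 = int(np.searchsorted(a, center[d] + r, side="right"))
            sl.append(slice(i0, i1))
            local.append(a[i0:i1] - center[d])
        dx2 = local[0][:, None, None] ** 2
        dy2 = local[1][None, :, None] ** 2
        dz2 = local[2][None, None, :] ** 2
        inside[tuple(sl)] |= (dx2 + dy2 + dz2) <= r * r
    return float(inside.sum()) * spacing ** 3


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def vdw_surface_area(mol: Molecule, n_points: int = 960,
                     registry: ParamRegistry = PARAMS_V1):
    """Exposed van der Waals surface area (A^2).

    Each atomic sphere is sampled with a deterministic Fibonacci lattice;
    a point is exposed if it lies outside every other atomic sphere. The
    per-atom exposed areas (needed by the hydration-energy term) are
    returned alongside the total.
    """
    radii = _radii(mol, registry)
    n = mol.n_atoms
    per_atom = np.zeros(n)
    unit = _fibonacci_sphere(n_points)
    for i in range(n):
        pts = mol.coords[i] + radii[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - mol.coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        per_atom[i] = 4 * np.pi * radii[i] ** 2 * exposed.mean()
    return float(per_atom.sum()), per_atom


def hydration_energy(mol: Molecule, registry: ParamRegistry = PARAMS_V1,
                     exposed_areas: Optional[np.ndarray] = None) -> float:
    """Hydration free energy (kcal/mole): sum over atoms of exposed
    surface area times the atom-class coefficient. Negative values favour
    hydration. ``exposed_areas`` may be supplied to freeze the exposure
    (used by the additivity properties)."""
    if exposed_areas is None:
        _, exposed_areas = vdw_surface_area(mol, registry=registry)
    total = 0.0
    for i in range(mol.n_atoms):
        total += exposed_areas[i] * registry.get(
            contribution_class(mol, i)).hydr
    return float(total)


# --------------------------------------------------------------------------
# additive descriptors
# --------------------------------------------------------------------------

def _additive(mol: Molecule, registry: ParamRegistry, attr: str,
              skip_metals: bool, strict_ge: bool = False):
    total = 0.0
    skipped = 0
    for i, sym in enumerate(mol.elements):
        metal = is_metal(sym, registry) or (strict_ge and sym == "Ge")
        if skip_metals and metal:
            skipped += 1
            continue
        params = registry.get(contribution_class(mol, i))
        value = getattr(params, attr)
        if value is None:
            if skip_metals and metal:  # pragma: no cover
                skipped += 1
                continue
            raise MissingParameterError(
                f"atom {i} ({sym}, class "
                f"{contribution_class(mol, i)!r}) has no {attr} "
                f"contribution")
        total += value
    return total, skipped


def logp_atomic(mol: Molecule, registry: ParamRegistry = PARAMS_V1,
                strict_ge: bool = False):
    """logP as a sum of atomic contributions; metal atoms (all d-/f-block
    elements) are skipped, mirroring the study's exclusion rule. Ge is
    parameterized by default; ``strict_ge=True`` skips it like a metal.

    Returns ``(logp, n_skipped)``.
    """
    return _additive(mol, registry, "logp", skip_metals=True,
                     strict_ge=strict_ge)


def refractivity_atomic(mol: Molecule, registry: ParamRegistry = PARAMS_V1,
                        strict_ge: bool = False):
    """Molar refractivity (A^3) by the same additive scheme as logP.

    Returns ``(rf, n_skipped)``.
    """
    return _additive(mol, registry, "mr", skip_metals=True,
                     strict_ge=strict_ge)


def polarizability_miller(mol: Molecule,
                          registry: ParamRegistry = PARAMS_V1) -> float:
    """Polarizability (A^3): sum of atom-type increments (metals
    included; the additive scheme has increments for them)."""
    total, _ = _additive(mol, registry, "pol", skip_metals=False)
    return total


def descriptor_set(mol: Molecule, spacing: float = 0.2,
                   registry: ParamRegistry = PARAMS_V1) -> DescriptorSet:
    """All six descriptors for one molecule, in the published units."""
    s, per_atom = vdw_surface_area(mol, registry=registry)
    v = vdw_volume_grid(mol, spacing=spacing, registry=registry)
    eh = hydration_energy(mol, registry=registry, exposed_areas=per_atom)
    lp, skipped = logp_atomic(mol, registry=registry)
    rf, _ = refractivity_atomic(mol, registry=registry)
    pol = polarizability_miller(mol, registry=registry)
    return DescriptorSet(s_vdw=s, v_vdw=v, e_hydr=eh, logp=lp, rf=rf,
                         pol=pol, grid_spacing=spacing,
                         params_version=registry.version,
                         n_metal_skipped=skipped)
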