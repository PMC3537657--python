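"""Readers/writers for molecular and tabular formats, plus the packaged
transcriptions of the published titanocene tables.

The three CSV fixtures shipped under ``titanoqsar/data`` are the single
source of tabular truth for the whole package:

``activities.csv``
    Cytotoxic activities of 11 titanocenes against HeLa, K562 and Fem-x
    cell lines: IC50 in micromolar with reported uncertainties, plus the
    pA (= pIC50) values as printed. pA is stored for display but is always
    recomputable from IC50 (see :func:`titanoqsar.qsar.pic50_from_uM`).
``descriptors.csv``
    The six structural descriptors per compound: van der Waals surface
    S_vdw (A^2) and volume V_vdw (A^3), hydration energy E_hydr
    (kcal/mole), logP, molar refractivity Rf (A^3) and polarizability
    Pol (A^3).
``energies.csv``
    Molecular-mechanics energies for the 33 titanocene/cyclodextrin
    pairings (11 guests x alpha/beta/gamma-CD): host energy E_CD, guest
    energy E_TC, their non-interacting sum, the complex energy, and the
    interaction energy E_int = (E_CD + E_TC) - E_complex (kcal/mole).

Molecular structures are carried by the lightweight :class:`Molecule`
container and read/written as plain XYZ or MDL MOL V2000 (via RDKit).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Molecule",
    "CompoundTable",
    "DescriptorRecord",
    "EnergyRecord",
    "FixtureError",
    "MoleculeParseError",
    "CELL_LINES",
    "PRINTED_EQUATIONS",
    "load_fixture",
    "read_molecule",
    "write_molecule",
    "write_report",
    "round_half_up",
]

CELL_LINES = ("hela", "k562", "femx")

#: Published regression coefficients (seven monolinear models) exactly as
#: printed, used by reports for side-by-side comparison with refits. The
#: ``asserted`` entries are the rounding-robust values (slopes, r, F); the
#: remaining printed values are rounding-fragile or not recomputable from
#: the printed input tables and are reported for information only.
PRINTED_EQUATIONS = {
    "eq1": dict(response="pa_hela", predictor="logp", a0=3.40, se_a0=0.17,
                b=0.69, se_b=0.17, r=0.80, F=16, n=11, q2cv=0.75,
                asserted=("b", "r", "F")),
    "eq2": dict(response="pa_k562", predictor="logp", a0=3.54, se_a0=0.23,
                b=0.69, se_b=0.30, r=0.70, F=5.5, n=8, q2cv=0.88,
                asserted=("b",)),
    "eq3": dict(response="pa_femx", predictor="logp", a0=3.63, se_a0=0.12,
                b=0.39, se_b=0.16, r=0.74, F=5.9, n=7, q2cv=0.80,
                asserted=("b",)),
    "eq4": dict(response="pa_k562", predictor="rf", a0=5.27, se_a0=0.37,
                b=-0.014, se_b=0.004, r=0.80, F=10.5, n=8, q2cv=0.75,
                asserted=("b", "F")),
    "eq5": dict(response="e_int_aCD", predictor="e_hydr", a0=15.54,
                se_a0=0.57, b=0.356, se_b=0.137, r=0.656, F=6.8, n=11,
                q2cv=None, asserted=("a0", "b")),
    "eq6": dict(response="e_int_bCD", predictor="logp", a0=16.24,
                se_a0=1.64, b=4.459, se_b=1.687, r=0.661, F=7.0, n=11,
                q2cv=None, asserted=("a0",)),
    "eq7": dict(response="e_int_gCD", predictor="logp", a0=21.46,
                se_a0=1.99, b=4.347, se_b=2.047, r=0.578, F=4.1, n=11,
                q2cv=None, asserted=("a0", "r")),
}


class FixtureError(ValueError):
    """A packaged fixture is missing, malformed, or violates an invariant."""


class MoleculeParseError(ValueError):
    """A molecular structure file could not be parsed."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, the convention used for all report
    display values (matches every reproduced printed number)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Molecule container
# --------------------------------------------------------------------------

def _periodic_symbols() -> frozenset:
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    syms = set()
    for z in range(1, 119):
        try:
            syms.add(pt.GetElementSymbol(z))
        except Exception:  # pragma: no cover
            break
    return frozenset(syms)


_SYMBOLS = None


def known_element(symbol: str) -> bool:
    global _SYMBOLS
    if _SYMBOLS is None:
        _SYMBOLS = _periodic_symbols()
    return symbol in _SYMBOLS


def normalize_symbol(token: str) -> str:
    return token[:1].upper() + token[1:].lower()


@dataclass
class Molecule:
    """Element-typed atoms with 3D coordinates and bonds.

    ``bonds`` are ``(i, j, order)`` triples with 0-based atom indices;
    order 4 denotes an aromatic bond (MDL convention). ``radii`` and
    ``classes`` are optional per-atom annotations filled in by the
    descriptor layer; ``metadata`` carries free-form annotations such as a
    host's primary-face normal.
    """

    elements: list
    coords: np.ndarray
    bonds: list = field(default_factory=list)
    charges: Optional[list] = None
    radii: Optional[np.ndarray] = None
    classes: Optional[list] = None
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coordinate block {self.coords.shape} does not match "
                f"{n} atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for sym in self.elements:
            if not known_element(sym):
                raise ValueError(f"unknown element symbol {sym!r}")
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def copy(self) -> "Molecule":
        return Molecule(
            elements=list(self.elements),
            coords=self.coords.copy(),
            bonds=[tuple(b) for b in self.bonds],
            charges=None if self.charges is None else list(self.charges),
            radii=None if self.radii is None else self.radii.copy(),
            classes=None if self.classes is None else list(self.classes),
            name=self.name,
            metadata=dict(self.metadata),
        )

    def neighbors(self, i: int) -> list:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


# --------------------------------------------------------------------------
# Tabular fixture records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorRecord:
    code: str
    s_vdw: float   # A^2
    v_vdw: float   # A^3
    e_hydr: float  # kcal/mole
    logp: float
    rf: float      # A^3
    pol: float     # A^3


@dataclass(frozen=True)
class EnergyRecord:
    complex_code: str
    cd: str
    e_cd: float       # kcal/mole, shared across one cyclodextrin
    e_tc: float       # kcal/mole
    e_sum: float      # kcal/mole, E_cd + E_tc (no interaction)
    e_complex: float  # kcal/mole
    e_int: float      # kcal/mole, (E_cd + E_tc) - E_complex
    face: Optional[str] = None


@dataclass
class CompoundTable:
    """Activity table keyed by compound code (11 titanocenes).

    IC50 values are micromolar; missing activities are NaN (three cell
    lines were not assayed for every compound). Stored pA columns mirror
    the printed table; statistics should use pA recomputed from IC50 at
    full precision.
    """

    df: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df["code"].duplicated().any():
            dup = df.loc[df["code"].duplicated(), "code"].iloc[0]
            raise FixtureError(f"duplicate compound code {dup!r}")
        for line in CELL_LINES:
            ic = df[f"ic50_{line}"]
            pa = df[f"pa_{line}"]
            bad = ic.notna() & (ic <= 0)
            if bad.any():
                raise FixtureError(
                    f"non-positive IC50 for {df.loc[bad, 'code'].iloc[0]}")
            parity = ic.notna() ^ pa.notna()
            if parity.any():
                raise FixtureError(
                    "IC50/pA presence mismatch for "
                    f"{df.loc[parity, 'code'].iloc[0]} ({line})")

    @property
    def codes(self) -> list:
        return list(self.df["code"])

    def ic50(self, line: str) -> pd.Series:
        return self.df.set_index("code")[f"ic50_{line}"]

    def pa(self, line: str, recompute: bool = True) -> pd.Series:
        """pA = pIC50 per compound; recomputed from IC50 at full precision
        by default, or the stored printed column if ``recompute=False``."""
        if recompute:
            ic = self.ic50(line)
            return 6.0 - np.log10(ic)
        return self.df.set_index("code")[f"pa_{line}"]


# --------------------------------------------------------------------------
# Fixture loading
# --------------------------------------------------------------------------

def _fixture_path(name: str) -> Path:
    path = resources.files("titanoqsar").joinpath("data", name)
    if not path.is_file():
        raise FixtureError(f"packaged fixture {name!r} not found")
    return Path(str(path))


def load_fixture(table_name: str):
    """Load and validate one packaged table.

    Parameters
    ----------
    table_name : {"activities", "descriptors", "energies"}

    Returns
    -------
    CompoundTable, list of DescriptorRecord, or list of EnergyRecord.
    """
    if table_name == "activities":
        df = pd.read_csv(_fixture_path("activities.csv"))
        if len(df) != 11:
            raise FixtureError(f"activities fixture has {len(df)} rows, "
                               "expected 11")
        return CompoundTable(df)

    if table_name == "descriptors":
        df = pd.read_csv(_fixture_path("descriptors.csv"))
        if len(df) != 11:
            raise FixtureError(f"descriptors fixture has {len(df)} rows, "
                               "expected 11")
        records = []
        for _, row in df.iterrows():
            rec = DescriptorRecord(code=row["code"],
                                   s_vdw=float(row["s_vdw"]),
                                   v_vdw=float(row["v_vdw"]),
                                   e_hydr=float(row["e_hydr"]),
                                   logp=float(row["logp"]),
                                   rf=float(row["rf"]),
                                   pol=float(row["pol"]))
            for f in ("s_vdw", "v_vdw", "rf", "pol"):
                if getattr(rec, f) <= 0:
                    raise FixtureError(
                        f"{rec.code}: descriptor {f} must be positive")
            records.append(rec)
        if len({r.code for r in records}) != len(records):
            raise FixtureError("duplicate descriptor codes")
        return records

    if table_name == "energies":
        df = pd.read_csv(_fixture_path("energies.csv"))
        if len(df) != 33:
            raise FixtureError(f"energies fixture has {len(df)} rows, "
                               "expected 33 (11 guests x 3 hosts)")
        records = []
        for _, row in df.iterrows():
            rec = EnergyRecord(complex_code=row["complex_code"],
                               cd=row["cd"],
                               e_cd=float(row["e_cd"]),
                               e_tc=float(row["e_tc"]),
                               e_sum=float(row["e_sum"]),
                               e_complex=float(row["e_complex"]),
                               e_int=float(row["e_int"]))
            if abs(rec.e_sum - (rec.e_cd + rec.e_tc)) > 0.01:
                raise FixtureError(
                    f"{rec.complex_code}: E_sum != E_CD + E_TC "
                    f"({rec.e_sum} vs {rec.e_cd + rec.e_tc})")
            if rec.e_int <= 0:
                raise FixtureError(
                    f"{rec.complex_code}: non-positive E_int")
            records.append(rec)
        if len({r.complex_code for r in records}) != 33:
            raise FixtureError("duplicate complex codes")
        return records

    raise FixtureError(f"unknown fixture table {table_name!r}")


# --------------------------------------------------------------------------
# Molecular file formats
# --------------------------------------------------------------------------

def read_molecule(path, fmt: Optional[str] = None) -> Molecule:
    """Read a structure from plain XYZ or MDL MOL V2000.

    ``fmt`` defaults to the file suffix (``.xyz`` or ``.mol``). Element
    symbols are normalized to standard capitalization; unknown elements
    raise :class:`MoleculeParseError` with the offending line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "mol":
        return _read_mol(path)
    raise MoleculeParseError(f"unsupported format {fmt!r}")


def _read_xyz(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if not lines:
        raise MoleculeParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise MoleculeParseError(f"{path}:1: expected atom count")
    if len(lines) < n + 2:
        raise MoleculeParseError(
            f"{path}: header declares {n} atoms but file has "
            f"{len(lines) - 2} atom lines")
    elements, coords = [], []
    for k in range(n):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise MoleculeParseError(f"{path}:{lineno}: short atom line")
        sym = normalize_symbol(parts[0])
        if not known_element(sym):
            raise MoleculeParseError(
                f"{path}:{lineno}: unknown element {parts[0]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise MoleculeParseError(f"{path}:{lineno}: bad coordinate")
        elements.append(sym)
        coords.append(xyz)
    return Molecule(elements=elements, coords=np.array(coords),
                    name=path.stem)


_MDL_ORDER = {1: 1, 2: 2, 3: 3, 4: 4}


def _read_mol(path: Path) -> Molecule:
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise MoleculeParseError(f"{path}: not a parsable MDL MOL V2000 file")
    conf = mol.GetConformer()
    elements, coords, charges = [], [], []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if not known_element(sym):
            raise MoleculeParseError(
                f"{path}: unknown element {sym!r} at atom "
                f"{atom.GetIdx() + 1}")
        elements.append(sym)
        p = conf.GetAtomPosition(atom.GetIdx())
        coords.append([p.x, p.y, p.z])
        charges.append(atom.GetFormalCharge())
    bonds = []
    for bond in mol.GetBonds():
        bt = bond.GetBondType()
        order = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
                 Chem.BondType.TRIPLE: 3, Chem.BondType.AROMATIC: 4}.get(bt, 1)
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    return Molecule(elements=elements, coords=np.array(coords), bonds=bonds,
                    charges=charges, name=path.stem)


def write_molecule(mol: Molecule, path, fmt: Optional[str] = None) -> None:
    """Write a Molecule as XYZ or MDL MOL V2000 (coordinates to 4 dp)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        lines = [str(mol.n_atoms), mol.name or ""]
        for sym, (x, y, z) in zip(mol.elements, mol.coords):
            lines.append(f"{sym} {x:.4f} {y:.4f} {z:.4f}")
        path.write_text("\n".join(lines) + "\n")
        return
    if fmt == "mol":
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        rw = Chem.RWMol()
        for k, sym in enumerate(mol.elements):
            atom = Chem.Atom(sym)
            atom.SetNoImplicit(True)
            if mol.charges is not None:
                atom.SetFormalCharge(int(mol.charges[k]))
            rw.AddAtom(atom)
        bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
              3: Chem.BondType.TRIPLE, 4: Chem.BondType.AROMATIC}
        for i, j, order in mol.bonds:
            rw.AddBond(int(i), int(j), bt.get(order, Chem.BondType.SINGLE))
        conf = Chem.Conformer(mol.n_atoms)
        for k, (x, y, z) in enumerate(mol.coords):
            conf.SetAtomPosition(k, Point3D(float(x), float(y), float(z)))
        m = rw.GetMol()
        m.AddConformer(conf)
        m.SetProp("_Name", mol.name or "")
        path.write_text(Chem.MolToMolBlock(m, kekulize=False))
        return
    raise MoleculeParseError(f"unsupported format {fmt!r}")


# --------------------------------------------------------------------------
# Model report
# --------------------------------------------------------------------------

def _model_record(m) -> dict:
    return {
        "response": m.response,
        "predictor": m.predictor,
        "a0": m.a0, "b": m.b,
        "se_a0": m.se_a0, "se_b": m.se_b,
        "r": m.r, "F": m.F, "n": m.n,
        "q2cv": m.q2cv,
    }


def write_report(models: Sequence, path) -> None:
    """Write a machine-readable JSON report for fitted monolinear models.

    Each model contributes one record (coefficients, standard errors, r,
    F, n, q2cv at full precision plus 2-dp display rounding) and, where
    its (response, predictor) pairing matches one of the seven published
    equations, a side-by-side comparison against the printed coefficients.
    Output is byte-stable for identical inputs.
    """
    printed_by_pair = {(v["response"], v["predictor"]): (k, v)
                       for k, v in PRINTED_EQUATIONS.items()}
    records = []
    for m in models:
        rec = _model_record(m)
        rec["rounded"] = {k: (None if rec[k] is None
                              else round_half_up(rec[k], 3 if k == "b" and
                                                 abs(rec[k]) < 0.1 else 2))
                          for k in ("a0", "b", "r", "F", "q2cv")}
        key = (m.response, m.predictor)
        if key in printed_by_pair:
            eq, printed = printed_by_pair[key]
            rec["equation"] = eq
            rec["printed"] = {k: printed[k] for k in
                              ("a0", "b", "r", "F", "n", "q2cv")}
        records.append(rec)
    payload = json.dumps({"models": records}, indent=2, sort_keys=True,
                         allow_nan=True)
    Path(path).write_text(payload + "\n")
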