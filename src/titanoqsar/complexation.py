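"""Host-guest complexation protocol.

A guest (titanocene, or a toy stand-in) is placed with its principal
axis perpendicular to the host's mean plane, centred ~8 A from the
host's centre of gravity on the chosen rim side (primary face A or
secondary face B of a cyclodextrin torus), and the complex is then
energy-minimized. The interaction energy follows the convention

    E_int = (E_host + E_guest) - E_complex,

with the monomer energies taken from their separately minimized
structures, so positive E_int favours complexation. A per-cycle E_int
trajectory is recorded during complex optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datasets_io import EnergyRecord, Molecule
from .mm_engine import ForceField, energy, minimize

__all__ = [
    "ComplexPose",
    "InteractionResult",
    "place_guest",
    "interaction_energy",
    "optimize_complex",
    "screen_library",
]

log = logging.getLogger("titanoqsar.complexation")

FACES = ("primary", "secondary")


@dataclass
class ComplexPose:
    """A placed host-guest pair prior to optimization."""

    host: Molecule
    guest: Molecule          # copy with placed coordinates
    face: str                # "primary" (A) or "secondary" (B)
    separation: float        # centroid-centroid distance, A
    orientation: np.ndarray  # guest principal axis, unit vector

    def __post_init__(self):
        if self.face not in FACES:
            raise ValueError(f"face must be one of {FACES}")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        norm = float(np.linalg.norm(self.orientation))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("orientation must be unit-norm")


@dataclass
class InteractionResult:
    e_host: float
    e_guest: float
    e_complex: float
    e_int: float
    trajectory: List[Tuple[int, float]] = field(default_factory=list)

    def __post_init__(self):
        expected = (self.e_host + self.e_guest) - self.e_complex
        if abs(self.e_int - expected) > 1e-6:
            raise ValueError("E_int != (E_host + E_guest) - E_complex")
        cycles = [c for c, _ in self.trajectory]
        if any(b <= a for a, b in zip(cycles, cycles[1:])):
            raise ValueError("trajectory cycles must be strictly increasing")


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Eigenvectors of the coordinate covariance, descending variance."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    return v[:, ::-1], w[::-1]


def _canonical_sign(vec: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude component positive."""
    k = int(np.argmax(np.abs(vec)))
    return vec if vec[k] > 0 else -vec


def host_face_normal(host: Molecule) -> np.ndarray:
    """Unit normal of the host mean plane pointing out of the primary (A)
    face.

    Honours a ``primary_face_normal`` metadata annotation when present;
    otherwise the normal is the least-variance principal axis, oriented
    toward the half-space holding fewer atoms (the narrower, primary rim
    of a cyclodextrin torus), with a deterministic tie-break.
    """
    if "primary_face_normal" in host.metadata:
        v = np.asarray(host.metadata["primary_face_normal"], dtype=float)
        return v / np.linalg.norm(v)
    axes, variances = _principal_axes(host.coords)
    if variances[1] < 1e-12:
        raise ValueError("degenerate host geometry (collinear atoms)")
    normal = axes[:, 2]
    signed = (host.coords - host.coords.mean(axis=0)) @ normal
    above = int(np.sum(signed > 1e-9))
    below = int(np.sum(signed < -1e-9))
    if above > below:
        normal = -normal
    elif above == below:
        normal = _canonical_sign(normal)
    return normal / np.linalg.norm(normal)


def _guest_axis(guest: Molecule) -> Optional[np.ndarray]:
    if guest.n_atoms < 2:
        return None
    axes, variances = _principal_axes(guest.coords)
    if variances[0] < 1e-12:
        return None
    return _canonical_sign(axes[:, 0])


def place_guest(host: Molecule, guest: Molecule, face: str = "secondary",
                separation: float = 8.0) -> ComplexPose:
    """Pose the guest against the chosen host face.

    The guest is rotated (minimal rotation) so its largest-variance
    principal axis is perpendicular to the host mean plane, and
    translated so the centroids are ``separation`` apart on the chosen
    side. Re-placing an already placed pose is a no-op on coordinates.
    """
    from scipy.spatial.transform import Rotation

    if face not in FACES:
        raise ValueError(f"face must be one of {FACES}")
    normal = host_face_normal(host)
    direction = normal if face == "primary" else -normal
    placed = guest.copy()
    axis = _guest_axis(placed)
    if axis is not None:
        target = direction if float(axis @ direction) >= 0 else -direction
        cross = np.cross(axis, target)
        dot = float(np.clip(axis @ target, -1.0, 1.0))
        sin = float(np.linalg.norm(cross))
        if sin > 1e-12:
            rotvec = cross / sin * np.arctan2(sin, dot)
            rot = Rotation.from_rotvec(rotvec)
            centroid = placed.centroid()
            placed.coords = rot.apply(placed.coords - centroid) + centroid
        orientation = target
    else:
        orientation = direction
    target_centroid = host.centroid() + direction * separation
    placed.coords = placed.coords + (target_centroid - placed.centroid())
    return ComplexPose(host=host, guest=placed, face=face,
                       separation=separation, orientation=orientation)


def interaction_energy(e_host: float, e_guest: float,
                       e_complex: float) -> float:
    """E_int = (E_host + E_guest) - E_complex; positive favours
    complexation."""
    return (e_host + e_guest) - e_complex


def _combine(host: Molecule, guest: Molecule) -> Molecule:
    offset = host.n_atoms
    return Molecule(
        elements=list(host.elements) + list(guest.elements),
        coords=np.vstack([host.coords, guest.coords]),
        bonds=[tuple(b) for b in host.bonds]
        + [(i + offset, j + offset, o) for i, j, o in guest.bonds],
        charges=None if host.charges is None and guest.charges is None
        else list(host.charges or [0] * host.n_atoms)
        + list(guest.charges or [0] * guest.n_atoms),
        name=f"{host.name}_{guest.name}" if host.name or guest.name else "",
    )


def optimize_complex(pose: ComplexPose, ff: ForceField,
                     e_host: Optional[float] = None,
                     e_guest: Optional[float] = None,
                     rms_stop: float = 0.005,
                     max_cycles: Optional[int] = None,
                     frozen_host: bool = False) -> InteractionResult:
    """Minimize the complex from the pose and report E_int.

    Monomer energies default to the energies of the separately minimized
    host and guest. The trajectory lists E_int after every minimizer
    cycle; its final entry equals the returned E_int.
    """
    if e_host is None:
        e_host = minimize(pose.host, ff)[0].energy
    if e_guest is None:
        e_guest = minimize(pose.guest, ff)[0].energy
    combined = _combine(pose.host, pose.guest)
    frozen = range(pose.host.n_atoms) if frozen_host else ()
    conf, traj = minimize(combined, ff, rms_stop=rms_stop,
                          max_cycles=max_cycles, frozen=frozen)
    e_sum = e_host + e_guest
    trajectory = [(c, e_sum - e) for c, e in traj]
    return InteractionResult(
        e_host=float(e_host), e_guest=float(e_guest),
        e_complex=float(conf.energy),
        e_int=interaction_energy(e_host, e_guest, conf.energy),
        trajectory=trajectory)


def screen_library(guests: Sequence[Molecule], hosts: Sequence[Molecule],
                   ff: ForceField, separation: float = 8.0,
                   frozen_host: bool = False, rms_stop: float = 0.005):
    """Optimize every guest against every host on both faces.

    Returns ``(records, failures)``: one :class:`EnergyRecord` per pair
    flagged with the better face (larger E_int), in deterministic
    guest-major order, plus a list of ``(complex_code, error)`` for pairs
    that failed. Monomer minimizations are shared across pairings.
    """
    host_e = {}
    for h in hosts:
        host_e[h.name] = minimize(h, ff)[0].energy
    guest_e = {}
    for g in guests:
        guest_e[g.name] = minimize(g, ff)[0].energy

    records, failures = [], []
    for g in guests:
        for h in hosts:
            code = f"{g.name}_{h.name}"
            try:
                best = None
                best_face = None
                for face in FACES:
                    pose = place_guest(h, g, face=face,
                                       separation=separation)
                    res = optimize_complex(
                        pose, ff, e_host=host_e[h.name],
                        e_guest=guest_e[g.name], frozen_host=frozen_host,
                        rms_stop=rms_stop)
                    if best is None or res.e_int > best.e_int:
                        best, best_face = res, face
                records.append(EnergyRecord(
                    complex_code=code, cd=h.name,
                    e_cd=host_e[h.name], e_tc=guest_e[g.name],
                    e_sum=host_e[h.name] + guest_e[g.name],
                    e_complex=best.e_complex, e_int=best.e_int,
                    face=best_face))
                log.info("screen %s: best face %s, E_int=%.3f",
                         code, best_face, best.e_int)
            except Exception as exc:  # per-pair failures are collected
                failures.append((code, exc))
                log.warning("screen %s failed: %s", code, exc)
    return records, failures
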