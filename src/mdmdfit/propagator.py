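"""Conformational samplers used inside MdMD sprints.

The demon only needs *some* stochastic propagator; two desk-scale engines
are built in:

* :class:`ElasticNetworkEngine` — a coarse-grained elastic network model
  (pairwise harmonic springs between sites within a 10 A contact radius,
  uniform spring constant) integrated with Langevin dynamics (BAOAB
  splitting).  Defaults: 300 K, 2 fs timestep, friction 1 ps^-1.
* :class:`HingeMonteCarloEngine` — a proposer that perturbs a declared
  hinge joint (bend angle and axial twist) by Gaussian steps whose width
  scales diffusively with sprint duration; used for fast synthetic
  fitting runs.

An :class:`ExternalCommandEngine` adapter lets a shell command stand in
as the propagator (it reads a PDB, writes an advanced PDB).

Units: Angstrom, picosecond, amu, kcal/mol.  Harmonic tether restraints
use the convention E = k * d^2 (NOT 1/2 k d^2), matching force constants
quoted per hydrogen-bonding atom in kcal/(mol*A^2).
"""

from __future__ import annotations

import copy
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import geometry
from .model_io import Structure, SelectionError, read_pdb, write_pdb

#: Boltzmann constant, kcal/(mol K).
KB_KCAL = 0.0019872041
#: kcal/mol expressed in amu A^2 / ps^2 (1 kcal/mol = 4.184 kJ/mol).
KCAL_TO_INTERNAL = 418.4
#: kB in internal units, amu A^2 / (ps^2 K).
KB_INTERNAL = KB_KCAL * KCAL_TO_INTERNAL


class IntegrationError(RuntimeError):
    """Non-finite forces or coordinates during propagation."""

    def __init__(self, message: str, atom_index: int | None = None):
        super().__init__(message)
        self.atom_index = atom_index


@dataclass
class PropagatorState:
    """Coordinates + velocities + RNG stream; the unit advanced per sprint."""

    coords: np.ndarray            # (N, 3), Angstrom
    velocities: np.ndarray        # (N, 3), Angstrom/ps
    rng: np.random.Generator
    time: float = 0.0             # ps

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        if self.coords.shape != self.velocities.shape:
            raise ValueError("coordinates and velocities must be congruent")

    @classmethod
    def from_structure(cls, structure: Structure,
                       seed: int | np.random.SeedSequence = 0) -> "PropagatorState":
        rng = np.random.default_rng(seed)
        return cls(structure.coords.copy(),
                   np.zeros_like(structure.coords), rng)

    def clone(self) -> "PropagatorState":
        return PropagatorState(self.coords.copy(), self.velocities.copy(),
                               copy.deepcopy(self.rng), self.time)


@dataclass
class TetherRestraint:
    """Harmonic position tether: E = k * |r - anchor|^2 per atom.

    Force constants of 1-10 kcal/(mol*A^2) per restrained (hydrogen-
    bonding) atom mimic codon-anticodon base pairing.
    """

    atom_indices: np.ndarray      # indices into the topology
    anchors: np.ndarray           # (n, 3) anchor positions, Angstrom
    force_constant: float         # kcal/(mol*A^2)

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.anchors = np.asarray(self.anchors, dtype=np.float64).reshape(-1, 3)
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if len(self.atom_indices) == 0:
            raise SelectionError("restraint selection resolves to zero atoms")
        if len(self.atom_indices) != len(self.anchors):
            raise ValueError("one anchor per restrained atom required")


def anticodon_tether(structure: Structure, force_constant: float = 5.0,
                     residues: Sequence[int] = (34, 35, 36),
                     elements: Sequence[str] = ("N", "O")) -> TetherRestraint:
    """Tether the hydrogen-bonding (N/O) base atoms of the anticodon.

    Anchors are the atoms' current positions, mimicking base pairing at
    the codon while the rest of the molecule moves.
    """
    mask = structure.mask(resids=residues, elements=elements)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise SelectionError(
            f"no H-bonding atoms found in residues {tuple(residues)}")
    return TetherRestraint(idx, structure.coords[idx].copy(), force_constant)


def apply_restraint_energy(
    coords_or_state, restraints: Sequence[TetherRestraint],
) -> tuple[float, np.ndarray]:
    """Total tether energy (kcal/mol) and forces (kcal/(mol*A)).

    Forces are the negative gradient of E = sum_i k |r_i - a_i|^2.
    """
    coords = (coords_or_state.coords
              if isinstance(coords_or_state, PropagatorState)
              else np.asarray(coords_or_state, dtype=float))
    energy = 0.0
    forces = np.zeros_like(coords)
    for r in restraints:
        d = coords[r.atom_indices] - r.anchors
        energy += r.force_constant * float(np.sum(d * d))
        np.add.at(forces, r.atom_indices, -2.0 * r.force_constant * d)
    return energy, forces


def reset_velocities(state: PropagatorState, masses: np.ndarray,
                     temperature: float,
                     seed=None) -> PropagatorState:
    """Redraw velocities from Maxwell-Boltzmann; coordinates untouched."""
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    new = state.clone()
    if seed is not None:
        new.rng = np.random.default_rng(seed)
    if temperature == 0:
        new.velocities = np.zeros_like(state.velocities)
        return new
    masses = np.asarray(masses, dtype=float).reshape(-1, 1)
    sigma = np.sqrt(KB_INTERNAL * temperature / masses)   # A/ps, per atom
    new.velocities = new.rng.normal(0.0, 1.0, size=state.velocities.shape) * sigma
    return new


def remove_com_motion(state: PropagatorState, masses: np.ndarray) -> PropagatorState:
    """Zero net linear and angular momentum ("flying ice-cube" fix).

    Subtracts the center-of-mass velocity and the rigid-rotation velocity
    field omega x r implied by the net angular momentum about the COM.
    Coordinates are unchanged.
    """
    if state.coords.shape[0] == 0:
        raise ValueError("state has no atoms")
    new = state.clone()
    m = np.asarray(masses, dtype=float).reshape(-1, 1)
    mtot = float(m.sum())
    v_com = (m * new.velocities).sum(axis=0) / mtot
    new.velocities = new.velocities - v_com
    r_com = (m * new.coords).sum(axis=0) / mtot
    r = new.coords - r_com
    L = np.sum(np.cross(r, m * new.velocities), axis=0)
    r2 = np.sum(r * r, axis=1)
    inertia = np.eye(3) * float(np.sum(m[:, 0] * r2)) \
        - np.einsum("i,ij,ik->jk", m[:, 0], r, r)
    # pseudo-inverse handles collinear (rank-deficient) geometries
    omega = np.linalg.pinv(inertia, rcond=1e-10) @ L
    new.velocities = new.velocities - np.cross(omega, r)
    return new


class Engine(Protocol):
    """What the MdMD driver requires of a propagator."""

    def propagate(self, state: PropagatorState, duration: float) -> PropagatorState: ...

    def thermalize(self, state: PropagatorState,
                   rng: np.random.Generator) -> PropagatorState: ...


# ---------------------------------------------------------------------------
# Elastic network model + Langevin dynamics
# ---------------------------------------------------------------------------

class ElasticNetworkModel:
    """Pairwise harmonic springs between sites within a contact radius.

    E = sum_pairs 1/2 k (d - d0)^2 with the equilibrium lengths d0 taken
    from the reference coordinates.  (Note the tether restraints use the
    k d^2 convention instead; see module docstring.)
    """

    def __init__(self, reference: Structure, contact_radius: float = 10.0,
                 spring_constant: float = 1.0):
        coords = reference.coords
        tree = cKDTree(coords)
        pairs = np.array(sorted(tree.query_pairs(contact_radius)), dtype=int)
        if len(pairs) == 0:
            raise ValueError("no spring pairs within the contact radius")
        self.pairs = pairs
        d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        self.eq_lengths = np.linalg.norm(d, axis=1)
        self.k = float(spring_constant)
        self.n_atoms = reference.n_atoms

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        d = coords[i] - coords[j]
        dist = np.linalg.norm(d, axis=1)
        stretch = dist - self.eq_lengths
        energy = 0.5 * self.k * float(np.sum(stretch ** 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(dist[:, None] > 0, d / dist[:, None], 0.0)
        f_pair = -self.k * stretch[:, None] * unit
        forces = np.zeros((self.n_atoms, 3))
        np.add.at(forces, i, f_pair)
        np.add.at(forces, j, -f_pair)
        return energy, forces


class ElasticNetworkEngine:
    """Langevin (BAOAB) dynamics on an elastic network model.

    With ``friction=0`` and ``temperature=0`` the integrator reduces to
    velocity Verlet (useful for energy-conservation checks).
    """

    def __init__(self, topology: Structure, contact_radius: float = 10.0,
                 spring_constant: float = 1.0, temperature: float = 300.0,
                 friction: float = 1.0, timestep: float = 0.002,
                 restraints: Sequence[TetherRestraint] = (),
                 com_correction: bool = True):
        self.model = ElasticNetworkModel(topology, contact_radius, spring_constant)
        self.masses = topology.masses.reshape(-1, 1)
        self.temperature = float(temperature)
        self.friction = float(friction)
        self.timestep = float(timestep)
        self.restraints = list(restraints)
        self.com_correction = bool(com_correction)

    def _forces(self, coords: np.ndarray) -> np.ndarray:
        e, f = self.model.energy_forces(coords)
        if self.restraints:
            _, fr = apply_restraint_energy(coords, self.restraints)
            f = f + fr
        if not np.all(np.isfinite(f)):
            bad = int(np.argwhere(~np.isfinite(f))[0][0])
            raise IntegrationError(f"non-finite force on atom {bad}", bad)
        return f

    def potential_energy(self, coords: np.ndarray) -> float:
        e, _ = self.model.energy_forces(coords)
        if self.restraints:
            er, _ = apply_restraint_energy(coords, self.restraints)
            e += er
        return e

    def kinetic_energy(self, state: PropagatorState) -> float:
        """Kinetic energy in kcal/mol."""
        return float(0.5 * np.sum(self.masses * state.velocities ** 2)
                     / KCAL_TO_INTERNAL)

    def propagate(self, state: PropagatorState, duration: float) -> PropagatorState:
        if duration < 0:
            raise ValueError("duration must be >= 0")
        new = state.clone()
        n_steps = int(round(duration / self.timestep))
        if n_steps == 0 and duration > 0:
            n_steps = 1
        dt = self.timestep
        m = self.masses
        # force -> acceleration: kcal/(mol A) / amu -> A/ps^2
        conv = KCAL_TO_INTERNAL / m
        if self.friction > 0:
            c1 = np.exp(-self.friction * dt)
            c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
        else:
            c1, c2 = 1.0, 0.0
        sigma_v = np.sqrt(KB_INTERNAL * self.temperature / m)
        x, v = new.coords, new.velocities
        f = self._forces(x)
        for _ in range(n_steps):
            v = v + 0.5 * dt * conv * f
            x = x + 0.5 * dt * v
            if c2 > 0 and self.temperature > 0:
                v = c1 * v + c2 * sigma_v * new.rng.normal(size=v.shape)
            else:
                v = c1 * v
            x = x + 0.5 * dt * v
            f = self._forces(x)
            v = v + 0.5 * dt * conv * f
        new.coords, new.velocities = x, v
        new.time = state.time + n_steps * dt
        return new

    def thermalize(self, state: PropagatorState,
                   rng: np.random.Generator) -> PropagatorState:
        new = state.clone()
        new.rng = rng
        out = reset_velocities(new, self.masses.ravel(), self.temperature)
        return out

    def postprocess_accepted(self, state: PropagatorState) -> PropagatorState:
        """Flying-ice-cube correction after each accepted sprint."""
        if not self.com_correction:
            return state
        return remove_com_motion(state, self.masses.ravel())


# ---------------------------------------------------------------------------
# Hinge Monte-Carlo proposer
# ---------------------------------------------------------------------------

class HingeMonteCarloEngine:
    """Propose rigid hinge-bend (and optional twist) moves on one arm.

    Each sprint draws a bend perturbation ~ N(0, step_scale*sqrt(t)) in
    degrees (t = sprint duration, ps) and rotates the declared arm about
    the hinge axis, exactly as :func:`mdmdfit.synthetic.deform_hinge`
    does.  The diffusive sqrt(t) scaling makes the demon's adaptive
    sprint length meaningful for this engine too.
    """

    def __init__(self, topology: Structure,
                 arm_residues: Sequence[int],
                 hinge_residues: Sequence[int] = (26, 44, 45),
                 step_scale: float = 2.0,        # deg / sqrt(ps)
                 twist_scale: float = 0.0):      # deg / sqrt(ps)
        self.topology = topology
        self.arm_mask = topology.mask(resids=list(arm_residues))
        if not self.arm_mask.any():
            raise SelectionError("arm residues resolve to zero atoms")
        hinge_mask = topology.mask(resids=list(hinge_residues),
                                   names=["P"])
        if not hinge_mask.any():
            hinge_mask = topology.mask(resids=list(hinge_residues))
        if not hinge_mask.any():
            raise SelectionError("hinge residues resolve to zero atoms")
        self.hinge_idx = np.flatnonzero(hinge_mask)
        self.p_mask = topology.mask(names=["P"])
        self.step_scale = float(step_scale)
        self.twist_scale = float(twist_scale)

    def _axes(self, coords: np.ndarray):
        p = self.p_mask if self.p_mask.any() else np.ones(len(coords), bool)
        arm_pts = coords[self.arm_mask & p]
        other_pts = coords[(~self.arm_mask) & p]
        pivot = coords[self.hinge_idx].mean(axis=0)
        u_arm = geometry.oriented_axis(arm_pts, away_from=pivot)
        u_other = geometry.oriented_axis(other_pts, away_from=pivot)
        normal = np.cross(u_other, u_arm)
        if np.linalg.norm(normal) < 1e-8:
            raise ValueError("degenerate hinge axis (arms are collinear)")
        return pivot, u_arm, normal / np.linalg.norm(normal)

    def move(self, coords: np.ndarray, d_angle: float,
             d_twist: float = 0.0) -> np.ndarray:
        """Apply a deterministic hinge move (degrees) to a coordinate set."""
        pivot, u_arm, normal = self._axes(coords)
        out = coords.copy()
        arm = out[self.arm_mask]
        arm = geometry.rotate_about_axis(arm, pivot, normal, d_angle)
        if d_twist != 0.0:
            rot_u = geometry.rotate_about_axis(
                u_arm[None, :] + pivot, pivot, normal, d_angle)[0] - pivot
            arm = geometry.rotate_about_axis(arm, pivot, rot_u, d_twist)
        out[self.arm_mask] = arm
        return out

    def propagate(self, state: PropagatorState, duration: float) -> PropagatorState:
        if duration < 0:
            raise ValueError("duration must be >= 0")
        new = state.clone()
        if duration == 0:
            return new
        width = self.step_scale * np.sqrt(duration)
        d_angle = float(new.rng.normal(0.0, width))
        d_twist = (float(new.rng.normal(0.0, self.twist_scale * np.sqrt(duration)))
                   if self.twist_scale > 0 else 0.0)
        new.coords = self.move(new.coords, d_angle, d_twist)
        new.time = state.time + duration
        return new

    def thermalize(self, state: PropagatorState,
                   rng: np.random.Generator) -> PropagatorState:
        # no velocities to redraw; installing the fresh stream is what
        # makes the retried sprint differ from the rejected one
        new = state.clone()
        new.rng = rng
        return new


# ---------------------------------------------------------------------------
# External command adapter
# ---------------------------------------------------------------------------

class ExternalCommandEngine:
    """Adapter: a shell command advances coordinates via PDB files.

    The command template may contain ``{in}``, ``{out}`` and
    ``{duration}`` placeholders.  This is an adapter contract only; no
    specific MD code is bundled.
    """

    def __init__(self, topology: Structure, command_template: str):
        self.topology = topology
        self.command_template = command_template

    def propagate(self, state: PropagatorState, duration: float) -> PropagatorState:
        new = state.clone()
        with tempfile.TemporaryDirectory() as tmp:
            fin = Path(tmp) / "in.pdb"
            fout = Path(tmp) / "out.pdb"
            write_pdb(self.topology.with_coords(new.coords), fin)
            cmd = self.command_template.format(
                **{"in": str(fin), "out": str(fout), "duration": duration})
            subprocess.run(cmd, shell=True, check=True)
            advanced = read_pdb(fout)
        if advanced.n_atoms != self.topology.n_atoms:
            raise IntegrationError("external engine changed the atom count")
        new.coords = advanced.coords.copy()
        new.time = state.time + duration
        return new

    def thermalize(self, state, rng):
        new = state.clone()
        new.rng = rng
        return new
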