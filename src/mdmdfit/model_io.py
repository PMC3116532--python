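"""Atomic structures, PDB I/O, superposition and RMSD.

Coordinates are in Angstrom throughout.  A :class:`Structure` is a flat,
order-preserving table of atom records (the order read from a PDB file is
the order written back); a :class:`Trajectory` is a stack of coordinate
frames sharing one topology Structure.

Superposition is least-squares rigid-body (rotation + translation, no
scaling); reflections are excluded so the chirality of nucleic acids is
preserved.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as _bst
import biotite.structure.io.pdb as _bpdb

logger = logging.getLogger(__name__)

#: Default RMSD convergence threshold (Angstrom).
CONVERGENCE_RMSD = 3.0

_WATER_RESNAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP3", "SOL"})

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "MG": 24.305, "NA": 22.990, "K": 39.098,
}
_DEFAULT_MASS = 12.011


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when an atom selection is empty or degenerate."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position (Angstrom)."""

    serial: int
    name: str
    resname: str
    chain: str
    resid: int
    position: np.ndarray
    element: str
    icode: str = ""


class Structure:
    """Ordered collection of atom records with selection support.

    Internally column-oriented (parallel numpy arrays) so selections and
    coordinate math are vectorized; :attr:`atoms` yields row views.
    """

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        resnames: Sequence[str],
        chains: Sequence[str],
        resids: Sequence[int],
        coords: np.ndarray,
        elements: Sequence[str] | None = None,
        icodes: Sequence[str] | None = None,
        annotation: dict | None = None,
    ):
        n = len(names)
        self.serials = np.asarray(serials, dtype=np.int64)
        self.names = np.asarray(names, dtype=object)
        self.resnames = np.asarray(resnames, dtype=object)
        self.chains = np.asarray(chains, dtype=object)
        self.resids = np.asarray(resids, dtype=np.int64)
        self._coords = np.asarray(coords, dtype=np.float64).reshape(n, 3)
        if elements is None:
            elements = [_guess_element(nm) for nm in names]
        self.elements = np.asarray(elements, dtype=object)
        if icodes is None:
            icodes = [""] * n
        self.icodes = np.asarray(icodes, dtype=object)
        self.annotation: dict = dict(annotation or {})
        if not np.all(np.isfinite(self._coords)):
            raise ValueError("atom positions must be finite")
        for arr in (self.serials, self.names, self.resnames, self.chains,
                    self.resids, self.elements, self.icodes):
            if len(arr) != n:
                raise ValueError("column length mismatch")

    # -- basic protocol ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return self.n_atoms

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Angstrom (a view; copy before mutating)."""
        return self._coords

    @property
    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                serial=int(self.serials[i]), name=str(self.names[i]),
                resname=str(self.resnames[i]), chain=str(self.chains[i]),
                resid=int(self.resids[i]), position=self._coords[i].copy(),
                element=str(self.elements[i]), icode=str(self.icodes[i]),
            )

    @property
    def masses(self) -> np.ndarray:
        """Atomic masses (amu) looked up by element symbol."""
        return np.array([
            _ELEMENT_MASSES.get(str(e).upper(), _DEFAULT_MASS)
            for e in self.elements
        ])

    def copy(self) -> "Structure":
        return self.with_coords(self._coords.copy())

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """New Structure sharing identity columns with replaced coordinates."""
        return Structure(
            self.serials, self.names, self.resnames, self.chains,
            self.resids, np.array(coords, dtype=np.float64),
            self.elements, self.icodes, self.annotation,
        )

    # -- selections --------------------------------------------------------
    def mask(
        self,
        resids: Sequence[int] | None = None,
        names: Sequence[str] | None = None,
        chains: Sequence[str] | None = None,
        elements: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms; criteria are ANDed, each is an OR-set."""
        m = np.ones(self.n_atoms, dtype=bool)
        if resids is not None:
            m &= np.isin(self.resids, np.asarray(list(resids)))
        if names is not None:
            m &= np.isin(self.names, np.asarray(list(names), dtype=object))
        if chains is not None:
            m &= np.isin(self.chains, np.asarray(list(chains), dtype=object))
        if elements is not None:
            m &= np.isin(self.elements, np.asarray(list(elements), dtype=object))
        return m

    def select(self, mask: np.ndarray | None = None, **criteria) -> "Structure":
        """Subset Structure preserving original atom order."""
        if mask is None:
            mask = self.mask(**criteria)
        idx = np.flatnonzero(np.asarray(mask))
        return Structure(
            self.serials[idx], self.names[idx], self.resnames[idx],
            self.chains[idx], self.resids[idx], self._coords[idx],
            self.elements[idx], self.icodes[idx], self.annotation,
        )

    def validate_unique(self) -> None:
        """Check the (chain, resid, icode, name) uniqueness invariant."""
        keys = set()
        for i in range(self.n_atoms):
            k = (self.chains[i], int(self.resids[i]), self.icodes[i], self.names[i])
            if k in keys:
                raise ValueError(f"duplicate atom key {k}")
            keys.add(k)

    def centroid(self) -> np.ndarray:
        return self._coords.mean(axis=0)


@dataclass
class Trajectory:
    """Stack of coordinate frames congruent with one topology Structure."""

    topology: Structure
    frames: np.ndarray                       # (F, N, 3), Angstrom
    metadata: list = field(default_factory=list)  # per-frame time / iteration

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def __iter__(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# PDB I/O (biotite behind the scenes)
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].upper() in _ELEMENT_MASSES and len(stripped) > 1 and stripped[1].islower():
        return stripped[:2]
    return stripped[0].upper()


def read_pdb(source, exclude_water: bool = True) -> Structure:
    """Read a PDB file (path, text, or file-like) into a Structure.

    Alternate locations are resolved to the highest-occupancy conformer
    (tie: first altloc, i.e. 'A').  Water is excluded by default; other
    HETATM records are kept.  Insertion codes are preserved.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    if not text.strip():
        raise PDBParseError("empty PDB input")
    try:
        pdbfile = _bpdb.PDBFile.read(io.StringIO(text))
        arr = pdbfile.get_structure(
            model=1, altloc="occupancy", extra_fields=["atom_id"])
    except Exception as exc:  # pinpoint the offending line for the user
        raise PDBParseError(_locate_bad_line(text, exc)) from exc
    if arr.array_length() == 0:
        raise PDBParseError("no ATOM/HETATM records found")
    keep = np.ones(arr.array_length(), dtype=bool)
    if exclude_water:
        keep &= ~np.isin(arr.res_name, list(_WATER_RESNAMES))
    arr = arr[keep]
    if arr.array_length() == 0:
        raise PDBParseError("no atoms left after filtering")
    icodes = (arr.get_annotation("ins_code")
              if "ins_code" in arr.get_annotation_categories()
              else [""] * arr.array_length())
    return Structure(
        serials=arr.get_annotation("atom_id"),
        names=arr.atom_name, resnames=arr.res_name, chains=arr.chain_id,
        resids=arr.res_id, coords=arr.coord, elements=arr.element,
        icodes=icodes,
    )


def _locate_bad_line(text: str, exc: Exception) -> str:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except (ValueError, IndexError):
                    return f"malformed coordinate field on line {lineno}: {line!r}"
    return f"PDB parse error: {exc}"


def _to_atom_array(structure: Structure) -> _bst.AtomArray:
    n = structure.n_atoms
    arr = _bst.AtomArray(n)
    arr.coord = structure.coords.astype(np.float32)
    arr.chain_id = structure.chains.astype("U4")
    arr.res_id = structure.resids
    arr.ins_code = structure.icodes.astype("U1")
    arr.res_name = structure.resnames.astype("U5")
    arr.atom_name = structure.names.astype("U6")
    arr.element = np.array([str(e).upper() for e in structure.elements], dtype="U2")
    arr.set_annotation("atom_id", structure.serials)
    hetero = np.isin(structure.resnames, list(_WATER_RESNAMES))
    arr.hetero = hetero
    return arr


def write_pdb(structure: Structure, dest) -> None:
    """Write a Structure as PDB (fixed columns, 3-decimal coordinates)."""
    pdbfile = _bpdb.PDBFile()
    pdbfile.set_structure(_to_atom_array(structure))
    if hasattr(dest, "write"):
        pdbfile.write(dest)
    else:
        pdbfile.write(str(dest))


def write_trajectory_pdb(traj: Trajectory, dest) -> None:
    """Write a Trajectory as a multi-model PDB."""
    arrays = []
    for i in range(traj.n_frames):
        a = _to_atom_array(traj.topology)
        a.coord = traj.frames[i].astype(np.float32)
        arrays.append(a)
    stack = _bst.stack(arrays)
    pdbfile = _bpdb.PDBFile()
    pdbfile.set_structure(stack)
    if hasattr(dest, "write"):
        pdbfile.write(dest)
    else:
        pdbfile.write(str(dest))


def read_trajectory_pdb(source, exclude_water: bool = True) -> Trajectory:
    """Read a multi-model PDB into a Trajectory (model 1 is the topology)."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    pdbfile = _bpdb.PDBFile.read(io.StringIO(text))
    stack = pdbfile.get_structure(altloc="occupancy", extra_fields=["atom_id"])
    if isinstance(stack, _bst.AtomArray):
        stack = _bst.stack([stack])
    keep = np.ones(stack.array_length(), dtype=bool)
    if exclude_water:
        keep &= ~np.isin(stack.res_name, list(_WATER_RESNAMES))
    stack = stack[..., keep]
    first = stack[0]
    icodes = (first.get_annotation("ins_code")
              if "ins_code" in first.get_annotation_categories()
              else [""] * first.array_length())
    topo = Structure(
        serials=first.get_annotation("atom_id"), names=first.atom_name,
        resnames=first.res_name, chains=first.chain_id, resids=first.res_id,
        coords=first.coord, elements=first.element, icodes=icodes,
    )
    return Trajectory(topo, stack.coord.astype(np.float64),
                      metadata=list(range(stack.stack_depth())))


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def pair_atoms(
    mobile: Structure, reference: Structure,
    selection: dict | np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays pairing mobile/reference atoms for superposition.

    ``selection`` may be a criteria dict (see :meth:`Structure.mask`)
    applied to both structures, or ``None`` for all atoms.  Pairing is by
    (chain, resid, icode, name); if fewer than 3 atoms match that way the
    chain is dropped and (resid, name) intersection is used.  Unmatched
    atoms are dropped with a logged count.
    """
    if selection is not None and not isinstance(selection, dict):
        # explicit common boolean mask / index array on both structures
        idx = np.flatnonzero(np.asarray(selection)) \
            if np.asarray(selection).dtype == bool else np.asarray(selection)
        return idx, idx
    crit = selection or {}
    mob = np.flatnonzero(mobile.mask(**crit))
    ref = np.flatnonzero(reference.mask(**crit))

    def _match(keyfun):
        ref_keys = {keyfun(reference, j): j for j in ref}
        mi, ri = [], []
        for i in mob:
            j = ref_keys.get(keyfun(mobile, i))
            if j is not None:
                mi.append(i)
                ri.append(j)
        return np.asarray(mi, dtype=int), np.asarray(ri, dtype=int)

    full_key = lambda s, i: (s.chains[i], int(s.resids[i]), s.icodes[i], s.names[i])
    loose_key = lambda s, i: (int(s.resids[i]), s.names[i])
    mi, ri = _match(full_key)
    if len(mi) < 3:
        mi, ri = _match(loose_key)
    dropped = max(len(mob), len(ref)) - len(mi)
    if dropped:
        logger.info("atom pairing dropped %d unmatched atoms", dropped)
    return mi, ri


def _kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray):
    """Optimal proper rotation + translation of mobile onto reference."""
    mc, rc = mobile_xyz.mean(axis=0), ref_xyz.mean(axis=0)
    a, b = mobile_xyz - mc, ref_xyz - rc
    # collinearity check: rank of the centered cloud
    if min(len(a), len(b)) < 3 or np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise SelectionError(
            "superposition needs >= 3 non-collinear paired atoms")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(b, a)
    return rot, mc, rc


def superpose(
    mobile: Structure, reference: Structure,
    selection: dict | np.ndarray | None = None,
) -> tuple[Structure, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the fully transformed mobile Structure and the RMSD (Angstrom)
    over the paired selection.  The rotation is proper (det = +1); no
    scaling, no reflection.
    """
    mi, ri = pair_atoms(mobile, reference, selection)
    if len(mi) < 3:
        raise SelectionError("superposition needs >= 3 paired atoms")
    mob_xyz = mobile.coords[mi]
    ref_xyz = reference.coords[ri]
    rot, mc, rc = _kabsch(mob_xyz, ref_xyz)
    moved = rot.apply(mobile.coords - mc) + rc
    rmsd = float(np.sqrt(np.mean(np.sum((rot.apply(mob_xyz - mc) + rc - ref_xyz) ** 2, axis=1))))
    return mobile.with_coords(moved), rmsd


def rmsd(
    mobile: Structure, reference: Structure,
    selection: dict | np.ndarray | None = None,
) -> float:
    """RMSD after optimal superposition (Angstrom)."""
    return superpose(mobile, reference, selection)[1]


def rmsd_matrix(
    traj_a: Trajectory, traj_b: Trajectory,
    selection: dict | np.ndarray | None = None,
) -> np.ndarray:
    """Pairwise RMSD-after-superposition matrix between two trajectories."""
    if traj_a.n_frames == 0 or traj_b.n_frames == 0:
        raise ValueError("empty trajectory")
    mi, ri = pair_atoms(traj_a.topology, traj_b.topology, selection)
    out = np.empty((traj_a.n_frames, traj_b.n_frames))
    for i in range(traj_a.n_frames):
        a = traj_a.frames[i][mi]
        for j in range(traj_b.n_frames):
            b = traj_b.frames[j][ri]
            rot, mc, rc = _kabsch(a, b)
            d = rot.apply(a - mc) + rc - b
            out[i, j] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return out


def check_convergence(rmsd_value: float, threshold: float = CONVERGENCE_RMSD) -> bool:
    """True iff the RMSD is below the convergence threshold (default 3 A)."""
    if rmsd_value < 0:
        raise ValueError("RMSD cannot be negative")
    return rmsd_value < threshold
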