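"""tRNA geometry and interaction analyses.

Covers the interarm (acceptor-stem vs anticodon-stem) bend angle, the
per-residue fluctuation profile of a trajectory, docking of a trajectory
into a ribosome reference frame via the anticodon anchor, the
ribosome-contact occupancy map under the 4 A rule, and the radius of
gyration.

Default residue windows follow the canonical cloverleaf numbering of a
76-nucleotide tRNA; every window is configuration, not code, and can be
overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import geometry
from .model_io import SelectionError, Structure, Trajectory, pair_atoms, superpose

#: Backbone / sugar atom names of nucleotides; everything else heavy is "base".
_SUGAR_PHOSPHATE = frozenset({
    "P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
    "O5*", "C5*", "C4*", "O4*", "C3*", "O3*", "C2*", "O2*", "C1*",
})

_RNA_RESNAMES = frozenset({"A", "C", "G", "U", "I", "RA", "RC", "RG", "RU",
                           "ADE", "CYT", "GUA", "URA", "PSU", "1MA", "5MC",
                           "7MG", "H2U", "M2G", "OMC", "OMG", "2MG", "YYG"})
_PROTEIN_RESNAMES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
})


@dataclass
class StemDefinition:
    """Residue windows for the two stems and the hinge (canonical numbering)."""

    acceptor_stem: frozenset = frozenset(range(1, 8)) | frozenset(range(66, 73))
    anticodon_stem: frozenset = frozenset(range(27, 32)) | frozenset(range(39, 44))
    hinge: frozenset = frozenset({26, 44, 45})

    def __post_init__(self):
        self.acceptor_stem = frozenset(self.acceptor_stem)
        self.anticodon_stem = frozenset(self.anticodon_stem)
        self.hinge = frozenset(self.hinge)
        if self.acceptor_stem & self.anticodon_stem:
            raise ValueError("stem residue sets must be disjoint")


def is_base_atom(name: str, element: str) -> bool:
    """Heavy, non-sugar, non-phosphate nucleotide atom."""
    return (str(element).upper() != "H"
            and str(name).upper() not in _SUGAR_PHOSPHATE)


def base_atom_mask(structure: Structure) -> np.ndarray:
    return np.array([is_base_atom(n, e) for n, e
                     in zip(structure.names, structure.elements)])


def _stem_p_coords(structure: Structure, resids: Sequence[int],
                   label: str) -> np.ndarray:
    sel = structure.select(resids=list(resids), names=["P"])
    if sel.n_atoms < 4:
        raise SelectionError(
            f"{label} stem resolves to {sel.n_atoms} P atoms (need >= 4)")
    return sel.coords


def stem_axes(structure: Structure,
              stems: StemDefinition | None = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outward-oriented principal axes of the two stems and the hinge point.

    Each stem axis is the dominant direction of its P-atom cloud, with the
    sign chosen to run from the stem end nearest the hinge residues
    outward — a true bend-angle convention, free of axis-sign ambiguity.
    """
    stems = stems or StemDefinition()
    acc = _stem_p_coords(structure, stems.acceptor_stem, "acceptor")
    ant = _stem_p_coords(structure, stems.anticodon_stem, "anticodon")
    hinge_sel = structure.select(resids=list(stems.hinge), names=["P"])
    if hinge_sel.n_atoms == 0:
        hinge_sel = structure.select(resids=list(stems.hinge))
    if hinge_sel.n_atoms == 0:
        raise SelectionError("hinge residues resolve to zero atoms")
    hinge_point = hinge_sel.centroid()
    u_acc = geometry.oriented_axis(acc, away_from=hinge_point)
    u_ant = geometry.oriented_axis(ant, away_from=hinge_point)
    return u_acc, u_ant, hinge_point


def interarm_angle(structure: Structure,
                   stems: StemDefinition | None = None) -> float:
    """Bend angle (degrees, [0, 180]) between acceptor and anticodon stems."""
    u_acc, u_ant, _ = stem_axes(structure, stems)
    cosang = float(np.clip(np.dot(u_acc, u_ant), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def per_residue_fluctuation(
    traj: Trajectory,
    alignment: dict | None = None,
    marker_atom: str = "P",
) -> dict[int, float]:
    """Per-residue RMSF (A) of the marker atom about its mean position.

    Frames are first superposed (via ``alignment``, a selection-criteria
    dict; default all atoms) onto the first frame, then onto their mean,
    before fluctuations are measured.  For proteins pass
    ``marker_atom='CA'``.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs >= 2 frames")
    ref = traj.frame(0)
    aligned = np.empty_like(traj.frames)
    for i in range(traj.n_frames):
        moved, _ = superpose(traj.frame(i), ref, alignment)
        aligned[i] = moved.coords
    mean_ref = traj.topology.with_coords(aligned.mean(axis=0))
    for i in range(traj.n_frames):
        moved, _ = superpose(traj.topology.with_coords(aligned[i]),
                             mean_ref, alignment)
        aligned[i] = moved.coords
    mean = aligned.mean(axis=0)
    topo = traj.topology
    marker = topo.mask(names=[marker_atom])
    out: dict[int, float] = {}
    for resid in np.unique(topo.resids[marker]):
        idx = np.flatnonzero(marker & (topo.resids == resid))
        d2 = np.sum((aligned[:, idx, :] - mean[idx]) ** 2, axis=2)
        out[int(resid)] = float(np.sqrt(d2.mean()))
    return out


def dock_trajectory(
    traj: Trajectory,
    reference: Structure,
    anchor: dict | None = None,
) -> Trajectory:
    """Superpose every frame into a reference frame via an anchor selection.

    The default anchor is the anticodon (residues 34-36), matching the
    placement of the bound tRNA in a static ribosome model.
    """
    anchor = anchor or {"resids": [34, 35, 36]}
    mi, ri = pair_atoms(traj.topology, reference, anchor)
    if len(mi) < 3:
        raise SelectionError("anchor selection yields fewer than 3 pairs")
    docked = np.empty_like(traj.frames)
    for i in range(traj.n_frames):
        moved, _ = superpose(traj.frame(i), reference, anchor)
        docked[i] = moved.coords
    return Trajectory(traj.topology, docked, metadata=list(traj.metadata))


@dataclass
class ContactMap:
    """Occupancy of (tRNA residue, partner chain+residue) contacts.

    ``entries`` maps (trna_resid, (partner_chain, partner_resid)) to the
    fraction of frames in which the pair was within the cutoff;
    ``modes`` records whether the contact is protein-Calpha-to-base
    ("ca-base") or base-to-base ("base-base").
    """

    entries: dict = field(default_factory=dict)
    modes: dict = field(default_factory=dict)
    cutoff: float = 4.0
    n_frames: int = 0

    def occupancy(self, trna_resid: int, partner_chain: str,
                  partner_resid: int) -> float:
        return self.entries.get((trna_resid, (partner_chain, partner_resid)), 0.0)

    def to_tsv(self, dest) -> None:
        lines = ["tRNA_resid\tpartner_chain\tpartner_resid\tmode\toccupancy"]
        for (resid, (chain, presid)), occ in sorted(self.entries.items()):
            mode = self.modes[(resid, (chain, presid))]
            lines.append(f"{resid}\t{chain}\t{presid}\t{mode}\t{occ:.6g}")
        text = "\n".join(lines) + "\n"
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            from pathlib import Path
            Path(dest).write_text(text)


def _partner_groups(partner: Structure):
    """Group partner atoms per residue: protein -> CA, RNA -> base atoms."""
    groups = []
    keys = list(dict.fromkeys(
        (str(c), int(r)) for c, r in zip(partner.chains, partner.resids)))
    base_mask = base_atom_mask(partner)
    for chain, resid in keys:
        rmask = (partner.chains == chain) & (partner.resids == resid)
        resname = str(partner.resnames[np.flatnonzero(rmask)[0]]).upper()
        if resname in _PROTEIN_RESNAMES:
            idx = np.flatnonzero(rmask & (partner.names == "CA"))
            mode = "ca-base"
        else:
            idx = np.flatnonzero(rmask & base_mask)
            mode = "base-base"
        if len(idx):
            groups.append(((chain, resid), mode, partner.coords[idx]))
    return groups


def contact_map(docked: Trajectory, partner: Structure,
                cutoff: float = 4.0) -> ContactMap:
    """Contact occupancies between a docked tRNA trajectory and a partner.

    A pair is in contact in a frame when any partner Calpha (protein) or
    partner base atom (RNA) lies within ``cutoff`` of any base atom of
    the tRNA residue.  Occupancy denominators count all frames.
    """
    groups = _partner_groups(partner)
    if not groups:
        raise SelectionError(
            "partner structure has neither Calpha nor base atoms")
    topo = docked.topology
    tbase = base_atom_mask(topo)
    if not tbase.any():
        raise SelectionError("tRNA topology has no base atoms")
    trna_resids = np.unique(topo.resids[tbase])
    trna_idx = {int(r): np.flatnonzero(tbase & (topo.resids == r))
                for r in trna_resids}
    counts: dict = {}
    modes: dict = {}
    for f in range(docked.n_frames):
        coords = docked.frames[f]
        trees = {int(r): cKDTree(coords[idx]) for r, idx in trna_idx.items()}
        for key, mode, pcoords in groups:
            ptree = cKDTree(pcoords)
            for r, tree in trees.items():
                hits = ptree.query_ball_tree(tree, cutoff)
                if any(len(h) for h in hits):
                    k = (r, key)
                    counts[k] = counts.get(k, 0) + 1
                    modes[k] = mode
    n = docked.n_frames
    entries = {k: c / n for k, c in counts.items()}
    return ContactMap(entries=entries, modes=modes, cutoff=cutoff, n_frames=n)


def radius_of_gyration(structure_or_coords, mass_weighted: bool = False,
                       masses: np.ndarray | None = None) -> float:
    """Radius of gyration (A) about the centroid (uniform weights default)."""
    if isinstance(structure_or_coords, Structure):
        coords = structure_or_coords.coords
        if mass_weighted and masses is None:
            masses = structure_or_coords.masses
    else:
        coords = np.asarray(structure_or_coords, dtype=float).reshape(-1, 3)
    if len(coords) == 0:
        raise ValueError("need at least one atom")
    if mass_weighted:
        w = np.asarray(masses, dtype=float)
    else:
        w = np.ones(len(coords))
    w = w / w.sum()
    center = (w[:, None] * coords).sum(axis=0)
    return float(np.sqrt(np.sum(w * np.sum((coords - center) ** 2, axis=1))))
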