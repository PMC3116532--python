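"""Interarm angle, RMSF, docking, contact map, radius of gyration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdmdfit.analysis import (ContactMap, StemDefinition, contact_map,
                              dock_trajectory, interarm_angle,
                              per_residue_fluctuation, radius_of_gyration)
from mdmdfit.model_io import SelectionError, Structure, Trajectory
from mdmdfit.synthetic import PseudoTrnaSpec, deform_hinge, make_pseudo_trna

from conftest import toy_structure


def rigid(coords, seed, shift=(10.0, -5.0, 3.0)):
    rot = Rotation.random(random_state=np.random.RandomState(seed))
    return rot.apply(coords) + np.asarray(shift)


class TestInterarmAngle:
    def test_orthogonal_straight_helices_give_90(self):
        """Two straight perpendicular stems built by hand."""
        coords, names, resids = [], [], []
        # acceptor stem along +x, residues 1-7 and 66-72 (paired heights)
        for i, r in enumerate(range(1, 8)):
            coords.append([10.0 + 3 * i, 1.0, 0.0]); resids.append(r)
        for i, r in enumerate(range(66, 73)):
            coords.append([10.0 + 3 * i, -1.0, 0.0]); resids.append(r)
        # anticodon stem along +y
        for i, r in enumerate(range(27, 32)):
            coords.append([1.0, 10.0 + 3 * i, 0.0]); resids.append(r)
        for i, r in enumerate(range(39, 44)):
            coords.append([-1.0, 10.0 + 3 * i, 0.0]); resids.append(r)
        # hinge residues at the corner
        for r in (26, 44, 45):
            coords.append([0.0, 0.0, 0.0]); resids.append(r)
        n = len(coords)
        s = Structure(range(n), ["P"] * n, ["G"] * n, ["A"] * n, resids,
                      np.array(coords, dtype=float))
        assert interarm_angle(s) == pytest.approx(90.0, abs=1e-6)

    def test_rotation_invariance(self, trna90):
        a0 = interarm_angle(trna90)
        moved = trna90.with_coords(rigid(trna90.coords, seed=4))
        assert interarm_angle(moved) == pytest.approx(a0, abs=1e-9)

    def test_atom_order_invariance(self, trna90, rng):
        perm = rng.permutation(trna90.n_atoms)
        shuffled = Structure(
            trna90.serials[perm], trna90.names[perm], trna90.resnames[perm],
            trna90.chains[perm], trna90.resids[perm], trna90.coords[perm],
            trna90.elements[perm])
        assert interarm_angle(shuffled) == pytest.approx(
            interarm_angle(trna90), abs=1e-9)

    @pytest.mark.parametrize("angle", [60.0, 75.0, 90.0, 105.0, 120.0])
    def test_generator_agreement_within_2_degrees(self, angle):
        s = make_pseudo_trna(PseudoTrnaSpec(hinge_angle=angle))
        assert interarm_angle(s) == pytest.approx(angle, abs=2.0)

    def test_unresolved_stems_raise(self, trna90):
        bad = StemDefinition(acceptor_stem=frozenset({200, 201, 202, 203}))
        with pytest.raises(SelectionError):
            interarm_angle(trna90, bad)

    def test_overlapping_stems_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            StemDefinition(acceptor_stem=frozenset({1, 2, 27}),
                           anticodon_stem=frozenset({27, 28}))


class TestPerResidueFluctuation:
    def test_identical_frames_zero_rmsf(self, trna90):
        traj = Trajectory(trna90, np.stack([trna90.coords] * 3))
        values = per_residue_fluctuation(traj)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in values.values())

    def test_two_point_oscillation_closed_form(self):
        """One atom at +/- d with symmetric sampling has RMSF exactly d."""
        base = np.array([[0.0, 0, 0], [10.0, 0, 0], [0.0, 10, 0],
                         [5.0, 5, 20]])
        d = 1.5
        up = base.copy(); up[3, 2] += d
        dn = base.copy(); dn[3, 2] -= d
        topo = toy_structure(base)
        traj = Trajectory(topo, np.stack([up, dn, up, dn]))
        values = per_residue_fluctuation(traj, alignment={"resids": [1, 2, 3]})
        assert values[4] == pytest.approx(d, abs=1e-9)
        assert values[1] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motions_removed_by_alignment(self, trna90):
        frames = np.stack([rigid(trna90.coords, seed=i) for i in range(4)])
        values = per_residue_fluctuation(Trajectory(trna90, frames))
        assert max(values.values()) < 1e-6

    def test_single_frame_rejected(self, trna90):
        with pytest.raises(ValueError, match="frames"):
            per_residue_fluctuation(Trajectory(trna90, trna90.coords[None]))


class TestDockTrajectory:
    def test_already_docked_unchanged(self, trna90):
        traj = Trajectory(trna90, np.stack([trna90.coords] * 2))
        docked = dock_trajectory(traj, trna90)
        np.testing.assert_allclose(docked.frames, traj.frames, atol=1e-6)

    def test_recovers_scrambled_frames(self, trna90, rng):
        noisy = np.stack([
            trna90.coords + rng.normal(0, 0.1, trna90.coords.shape)
            for _ in range(3)])
        # originals sit at their docking optimum; a rigid scramble must
        # then be inverted exactly by re-docking
        originals = dock_trajectory(Trajectory(trna90, noisy), trna90).frames
        scrambled = np.stack([rigid(originals[i], seed=20 + i)
                              for i in range(3)])
        docked = dock_trajectory(Trajectory(trna90, scrambled), trna90)
        np.testing.assert_allclose(docked.frames, originals, atol=1e-6)

    def test_docking_never_worsens_anchor_rmsd(self, trna90, rng):
        anchor = {"resids": [34, 35, 36]}
        mask = trna90.mask(**anchor)
        frames = np.stack([
            rigid(trna90.coords + rng.normal(0, 0.5, trna90.coords.shape),
                  seed=30 + i) for i in range(3)])
        traj = Trajectory(trna90, frames)
        docked = dock_trajectory(traj, trna90, anchor)
        ref = trna90.coords[mask]
        for i in range(3):
            before = np.sqrt(((frames[i][mask] - ref) ** 2).sum(1).mean())
            after = np.sqrt(((docked.frames[i][mask] - ref) ** 2).sum(1).mean())
            assert after <= before + 1e-9


def _partner(dist, resname="ALA", atom="CA", element="C"):
    """Single-residue partner at a given distance from tRNA base atom."""
    return Structure([1], [atom], [resname], ["R"], [501],
                     np.array([[dist, 0.0, 0.0]]), [element])


def _single_base_trna():
    """One-residue 'tRNA' with a base atom at the origin and P nearby."""
    return Structure([1, 2], ["P", "N1"], ["G", "G"], ["A", "A"], [1, 1],
                     np.array([[0.0, 5.0, 0.0], [0.0, 0.0, 0.0]]),
                     ["P", "N"])


class TestContactMap:
    def test_pair_within_4A_counted(self):
        trna = _single_base_trna()
        traj = Trajectory(trna, trna.coords[None])
        cmap = contact_map(traj, _partner(3.9))
        assert cmap.occupancy(1, "R", 501) == 1.0
        assert cmap.modes[(1, ("R", 501))] == "ca-base"

    def test_pair_beyond_4A_absent(self):
        trna = _single_base_trna()
        traj = Trajectory(trna, trna.coords[None])
        cmap = contact_map(traj, _partner(4.1))
        assert cmap.entries == {}

    def test_occupancy_counts_all_frames(self):
        trna = _single_base_trna()
        near = trna.coords
        far = trna.coords + [100.0, 0, 0]
        traj = Trajectory(trna, np.stack([near, far]))
        cmap = contact_map(traj, _partner(3.9))
        assert cmap.occupancy(1, "R", 501) == 0.5

    def test_rna_partner_uses_base_atoms(self):
        trna = _single_base_trna()
        traj = Trajectory(trna, trna.coords[None])
        # partner RNA residue: base atom at 3 A, phosphate at 3 A too;
        # only the base atom may establish the contact mode
        partner = Structure([1, 2], ["N3", "P"], ["U", "U"], ["S", "S"],
                            [88, 88], np.array([[3.0, 0, 0], [0, 3.0, 0]]),
                            ["N", "P"])
        cmap = contact_map(traj, partner)
        assert cmap.occupancy(1, "S", 88) == 1.0
        assert cmap.modes[(1, ("S", 88))] == "base-base"

    def test_protein_sidechain_does_not_count(self):
        trna = _single_base_trna()
        traj = Trajectory(trna, trna.coords[None])
        # CB at 2 A but CA at 20 A: no Calpha contact
        partner = Structure([1, 2], ["CB", "CA"], ["LYS", "LYS"], ["R", "R"],
                            [10, 10], np.array([[2.0, 0, 0], [20.0, 0, 0]]),
                            ["C", "C"])
        cmap = contact_map(traj, partner)
        assert cmap.entries == {}

    def test_occupancy_monotone_in_cutoff(self, trna90, rng):
        partner_coords = trna90.coords[::5] + rng.normal(0, 2, (46, 3))
        n = len(partner_coords)
        partner = Structure(range(n), ["N1"] * n, ["U"] * n, ["S"] * n,
                            range(100, 100 + n), partner_coords, ["N"] * n)
        traj = Trajectory(trna90, trna90.coords[None])
        occ3 = contact_map(traj, partner, cutoff=3.0)
        occ4 = contact_map(traj, partner, cutoff=4.0)
        occ6 = contact_map(traj, partner, cutoff=6.0)
        for key, v in occ3.entries.items():
            assert occ4.entries.get(key, 0.0) >= v
        for key, v in occ4.entries.items():
            assert occ6.entries.get(key, 0.0) >= v

    def test_partner_without_ca_or_base_rejected(self):
        trna = _single_base_trna()
        traj = Trajectory(trna, trna.coords[None])
        bare = Structure([1], ["P"], ["U"], ["S"], [5],
                         np.array([[1.0, 0, 0]]), ["P"])
        with pytest.raises(SelectionError):
            contact_map(traj, bare)

    def test_tsv_export(self, tmp_path):
        trna = _single_base_trna()
        traj = Trajectory(trna, trna.coords[None])
        cmap = contact_map(traj, _partner(3.9))
        out = tmp_path / "contacts.tsv"
        cmap.to_tsv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("tRNA_resid")
        assert lines[1].split("\t") == ["1", "R", "501", "ca-base", "1"]


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(toy_structure([[1, 2, 3]])) == 0.0

    def test_two_atoms_2A_apart_gives_1(self):
        s = toy_structure([[0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(s) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        coords = rng.normal(0, 5, size=(100, 3))
        rg = radius_of_gyration(coords)
        direct = np.sqrt(np.mean(np.sum(
            (coords - coords.mean(axis=0)) ** 2, axis=1)))
        assert rg == pytest.approx(direct, abs=1e-10)

    def test_mass_weighted_option(self):
        s = toy_structure([[0, 0, 0], [2.0, 0, 0]], names=["P", "N1"],
                          elements=["P", "N"])
        uniform = radius_of_gyration(s)
        weighted = radius_of_gyration(s, mass_weighted=True)
        assert weighted != uniform  # P is heavier, centroid shifts toward it

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))
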