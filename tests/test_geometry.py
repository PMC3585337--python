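import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_min_distance, quaternion_rmsd, \
    random_rigid_transform
from groovetraj.errors import InputError, SelectionError
from groovetraj.geometry import (backbone_dihedrals, min_distance_series,
                                 min_residue_distance, rmsd_series,
                                 superpose_kabsch, trajectory_dihedrals)
from groovetraj.structures import RegionMap, Structure, Trajectory
from groovetraj.synthetic import build_chain, build_helix


def _single_atom_residues(positions):
    n = len(positions)
    return Structure(
        serials=range(1, n + 1), names=["CA"] * n, elements=["C"] * n,
        residue_numbers=range(1, n + 1), residue_names=["ALA"] * n,
        chains=["A"] * n, coords=np.asarray(positions, dtype=float))


class TestBackboneDihedrals:
    def test_ideal_helix_interior_angles(self, ideal_helix):
        pairs = backbone_dihedrals(ideal_helix)
        for p in pairs[1:-1]:
            assert p.phi_deg == pytest.approx(-57.0, abs=0.5)
            assert p.psi_deg == pytest.approx(-47.0, abs=0.5)

    def test_chain_termini_undefined(self, ideal_helix):
        pairs = backbone_dihedrals(ideal_helix)
        assert pairs[0].phi_deg is None
        assert pairs[-1].psi_deg is None
        assert pairs[0].psi_deg is not None

    def test_fully_extended_chain(self):
        chain = build_chain("A" * 8, [180.0] * 8, [180.0] * 8)
        for p in backbone_dihedrals(chain)[1:-1]:
            assert abs(p.phi_deg) == pytest.approx(180.0, abs=0.5)
            assert abs(p.psi_deg) == pytest.approx(180.0, abs=0.5)

    def test_invariant_under_rigid_motion(self, ideal_helix, rng):
        ref = backbone_dihedrals(ideal_helix)
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            moved = ideal_helix.with_coords(ideal_helix.coords @ rot.T + trans)
            got = backbone_dihedrals(moved)
            for a, b in zip(ref, got):
                if a.phi_deg is not None:
                    assert b.phi_deg == pytest.approx(a.phi_deg, abs=1e-6)
                if a.psi_deg is not None:
                    assert b.psi_deg == pytest.approx(a.psi_deg, abs=1e-6)

    def test_chain_break_suppresses_spanning_dihedrals(self):
        # two helices under one chain id, 30 A apart: no peptide bond between
        a = build_helix("A" * 5, first_residue=1)
        b = build_helix("A" * 5, first_residue=6)
        coords = np.concatenate([a.coords, b.coords + [30.0, 0, 0]])
        merged = Structure(
            serials=range(1, a.n_atoms + b.n_atoms + 1),
            names=list(a.names) + list(b.names),
            elements=list(a.elements) + list(b.elements),
            residue_numbers=list(a.residue_numbers) + list(b.residue_numbers),
            residue_names=list(a.residue_names) + list(b.residue_names),
            chains=["A"] * (a.n_atoms + b.n_atoms), coords=coords)
        pairs = {p.residue_number: p for p in backbone_dihedrals(merged)}
        assert pairs[5].psi_deg is None   # would span the break
        assert pairs[6].phi_deg is None
        assert pairs[4].psi_deg is not None


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        _, _, rmsd = superpose_kabsch(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_invariance(self, rng):
        x = rng.normal(size=(8, 3))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        y = x @ rot.T + np.array([1.0, -2.0, 3.0])
        _, _, rmsd = superpose_kabsch(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_quaternion_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=(n, 3)) * 5
            y = rng.normal(size=(n, 3)) * 5
            _, _, rmsd = superpose_kabsch(x, y)
            assert rmsd == pytest.approx(quaternion_rmsd(x, y), abs=1e-8)

    def test_symmetric_in_arguments(self, rng):
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=(12, 3))
        _, _, ab = superpose_kabsch(x, y)
        _, _, ba = superpose_kabsch(y, x)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_rotation_is_proper(self, rng):
        # a reflected point set must not be matched by an improper transform
        x = rng.normal(size=(6, 3))
        y = x * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = superpose_kabsch(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InputError):
            superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_sets_still_return_transform(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        y = np.array([[0.0, 0, 0], [0, 1.0, 0], [0, 2.0, 0], [0, 3.0, 0]])
        rot, _, rmsd = superpose_kabsch(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)


class TestRmsdSeries:
    def _region_map(self):
        return RegionMap(regions={"R1": [(3, 18)]}, helix_names=["R1"])

    def test_rigid_motion_frames_give_zero(self, ideal_helix, rng):
        frames = []
        for _ in range(6):
            rot, trans = random_rigid_transform(rng)
            frames.append(ideal_helix.coords @ rot.T + trans)
        traj = Trajectory(topology=ideal_helix, frames=np.stack(frames))
        series = rmsd_series(traj, ideal_helix, self._region_map(), ["R1"])
        np.testing.assert_allclose(series.values_A, 0.0, atol=1e-6)

    def test_single_frame_equal_to_reference(self, ideal_helix):
        traj = Trajectory(topology=ideal_helix,
                          frames=ideal_helix.coords[None])
        series = rmsd_series(traj, ideal_helix, self._region_map(), ["R1"])
        assert series.values_A[0] == pytest.approx(0.0, abs=1e-9)

    def test_empty_selection_raises(self, ideal_helix):
        traj = Trajectory(topology=ideal_helix,
                          frames=ideal_helix.coords[None])
        rmap = RegionMap(regions={"FAR": [(500, 510)]})
        with pytest.raises(SelectionError):
            rmsd_series(traj, ideal_helix, rmap, ["FAR"])


class TestMinResidueDistance:
    def test_two_single_atom_residues(self):
        s = _single_atom_residues([[0, 0, 0], [3.5, 0, 0]])
        assert min_residue_distance(s, 1, 2) == pytest.approx(3.5)

    def test_symmetric(self, rng):
        s = _single_atom_residues(rng.normal(size=(2, 3)) * 5)
        assert min_residue_distance(s, 1, 2) == \
            min_residue_distance(s, 2, 1)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            ca = rng.normal(size=(12, 3)) * 4
            cb = rng.normal(size=(12, 3)) * 4 + 3
            n = 24
            s = Structure(
                serials=range(1, n + 1), names=["C"] * n, elements=["C"] * n,
                residue_numbers=[1] * 12 + [2] * 12,
                residue_names=["LEU"] * n, chains=["A"] * n,
                coords=np.concatenate([ca, cb]))
            assert min_residue_distance(s, 1, 2) == pytest.approx(
                brute_force_min_distance(ca, cb), abs=1e-9)

    def test_never_increases_when_atoms_added(self, rng):
        ca = rng.normal(size=(5, 3))
        cb = rng.normal(size=(5, 3)) + 4
        extra = rng.normal(size=(3, 3)) + 4

        def build(b_coords):
            nb = len(b_coords)
            return Structure(
                serials=range(1, 5 + nb + 1), names=["C"] * (5 + nb),
                elements=["C"] * (5 + nb),
                residue_numbers=[1] * 5 + [2] * nb,
                residue_names=["ALA"] * (5 + nb), chains=["A"] * (5 + nb),
                coords=np.concatenate([ca, b_coords]))

        d_small = min_residue_distance(build(cb), 1, 2)
        d_big = min_residue_distance(build(np.concatenate([cb, extra])), 1, 2)
        assert d_big <= d_small + 1e-12

    def test_missing_residue_raises(self):
        s = _single_atom_residues([[0, 0, 0]])
        with pytest.raises(SelectionError):
            min_residue_distance(s, 1, 99)

    def test_series_matches_per_frame_calls(self, rng):
        s = _single_atom_residues(rng.normal(size=(2, 3)))
        frames = rng.normal(size=(7, 2, 3)) * 3
        traj = Trajectory(topology=s, frames=frames)
        series = min_distance_series(traj, 1, 2)
        for i in range(7):
            assert series[i] == pytest.approx(
                min_residue_distance(traj.frame(i), 1, 2), abs=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_dihedrals_rigid_invariance_property(seed):
    """Dihedrals are invariant under any proper rigid motion of the frame."""
    rng = np.random.default_rng(seed)
    helix = build_helix("A" * 6)
    rot, trans = random_rigid_transform(rng)
    moved = helix.with_coords(helix.coords @ rot.T + trans)
    a = backbone_dihedrals(helix)
    b = backbone_dihedrals(moved)
    for pa, pb in zip(a, b):
        if pa.phi_deg is not None:
            assert abs(pa.phi_deg - pb.phi_deg) < 1e-6
        if pa.psi_deg is not None:
            assert abs(pa.psi_deg - pb.psi_deg) < 1e-6
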