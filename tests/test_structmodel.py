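"""Geometry substrate: PDB I/O, selection, superposition, contacts."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from mses.structmodel import (
    AtomRecord,
    EmptySelectionError,
    InsufficientPointsError,
    ModelNotFoundError,
    PDBFormatError,
    Structure,
    apply_transform,
    contacts_between,
    cross_crystal_rmsd,
    fit_rmsd,
    read_structure,
    select_sites,
    superpose,
    write_structure,
    write_trajectory_pdb,
)

from conftest import random_structure


class TestPDBIO:
    def test_three_atom_fixture_is_echoed(self, three_atom_pdb):
        s = read_structure(three_atom_pdb)
        assert len(s) == 3
        assert s.atoms[1].name == "CA"
        assert s.atoms[1].residue_name == "ALA"
        np.testing.assert_allclose(s.atoms[1].coordinates, (11.639, 6.071, -5.147))

    def test_write_read_round_trip(self, three_atom_pdb, tmp_path):
        s = read_structure(three_atom_pdb)
        out = tmp_path / "out.pdb"
        write_structure(s, out)
        s2 = read_structure(out)
        assert s.atoms == s2.atoms

    def test_residue_numbering_gaps_preserved(self, tmp_path):
        text = "".join(
            f"ATOM  {i + 1:5d}  CA  GLY A{r:4d}       0.000   0.000{i * 3.8:8.3f}  1.00  0.00           C\n"
            for i, r in enumerate((1, 2, 5))
        )
        p = tmp_path / "gap.pdb"
        p.write_text(text)
        s = read_structure(p)
        assert [a.residue_number for a in s.atoms] == [1, 2, 5]

    def test_non_a_altloc_dropped(self, tmp_path):
        text = (
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA BGLY A   1       1.000   0.000   0.000  1.00  0.00           C\n"
        )
        p = tmp_path / "altloc.pdb"
        p.write_text(text)
        s = read_structure(p)
        assert len(s) == 1
        assert s.atoms[0].coordinates[0] == 0.0

    def test_bad_record_names_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       xx.xxx   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(PDBFormatError, match="line 2"):
            read_structure(p)

    def test_missing_model_raises(self, three_atom_pdb):
        with pytest.raises(ModelNotFoundError):
            read_structure(three_atom_pdb, model=4)

    def test_written_pdb_readable_by_biotite(self, three_atom_pdb, tmp_path):
        """Independent-reader check: biotite parses our output identically."""
        import biotite.structure.io.pdb as bio_pdb

        s = read_structure(three_atom_pdb)
        out = tmp_path / "ours.pdb"
        write_structure(s, out)
        arr = bio_pdb.PDBFile.read(str(out)).get_structure(model=1)
        np.testing.assert_allclose(arr.coord, s.coordinates, atol=1e-3)
        assert list(arr.atom_name) == [a.name for a in s.atoms]
        assert list(arr.res_id) == [a.residue_number for a in s.atoms]

    def test_multi_model_trajectory_round_trip(self, three_atom_pdb, tmp_path):
        s = read_structure(three_atom_pdb)
        frames = [s.coordinates + i * np.array([1.0, 0, 0]) for i in range(3)]
        out = tmp_path / "traj.pdb"
        write_trajectory_pdb(s, frames, out)
        for i in range(3):
            m = read_structure(out, model=i + 1)
            np.testing.assert_allclose(m.coordinates, frames[i], atol=1e-3)


class TestSelection:
    def test_residue_range_counts(self, ten_residue_pdb):
        s = read_structure(ten_residue_pdb)
        assert len(select_sites(s, chain="A", residue_range=(1, 10))) == 10
        assert len(select_sites(s, chain="A", residue_range=(1, 7))) == 7

    def test_chain_restriction(self, two_chain_pdb):
        s = read_structure(two_chain_pdb)
        sites = select_sites(s, chain="B")
        assert len(sites) == 7
        assert all(c == "B" for c, _ in sites.labels)

    def test_empty_selection_is_an_error(self, ten_residue_pdb):
        s = read_structure(ten_residue_pdb)
        with pytest.raises(EmptySelectionError):
            select_sites(s, chain="Z")

    def test_inverted_range_rejected(self, ten_residue_pdb):
        s = read_structure(ten_residue_pdb)
        with pytest.raises(ValueError):
            select_sites(s, chain="A", residue_range=(7, 3))


def _rigid(coords, angle_deg=90.0, axis=(0, 0, 1), shift=(5.0, 0, 0)):
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(axis, float))
    return coords @ rot.as_matrix().T + np.asarray(shift, float)


def _brute_force_rmsd(mobile, reference, n_grid=14):
    """Oracle: dense rotation grid + local refinement, centred clouds."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        moved = mob @ Rotation.from_rotvec(rotvec).as_matrix().T
        return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

    best = (np.inf, None)
    angles = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    for ax in np.linspace(-1.2, 1.2, 7):
        for ay in np.linspace(-1.2, 1.2, 7):
            for az in angles:
                v = np.array([ax, ay, az])
                r = rmsd_of(v)
                if r < best[0]:
                    best = (r, v)
    res = minimize(rmsd_of, best[1], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return float(res.fun)


class TestSuperposition:
    def test_identity_gives_zero(self, rng):
        coords = rng.normal(0, 3, (8, 3))
        assert superpose(coords, coords).rmsd < 1e-12

    def test_rigid_motion_recovered(self, rng):
        ref = rng.normal(0, 3, (8, 3))
        res = superpose(_rigid(ref), ref)
        assert res.rmsd < 1e-10
        assert np.isclose(np.linalg.det(res.rotation), 1.0, atol=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = rng.normal(0, 3, (10, 3))
        b = a + rng.normal(0, 1, a.shape)
        assert abs(superpose(a, b).rmsd - superpose(b, a).rmsd) < 1e-10

    def test_invariant_under_joint_rigid_motion(self, rng):
        a = rng.normal(0, 3, (10, 3))
        b = a + rng.normal(0, 1, a.shape)
        base = superpose(a, b).rmsd
        moved = superpose(_rigid(a, 37.0, (1, 2, 0.5), (3, -2, 8)), _rigid(b, 37.0, (1, 2, 0.5), (3, -2, 8)))
        assert abs(moved.rmsd - base) < 1e-10

    def test_matches_brute_force_oracle(self, rng):
        a = rng.normal(0, 3, (8, 3))
        b = rng.normal(0, 3, (8, 3))
        assert abs(superpose(a, b).rmsd - _brute_force_rmsd(a, b)) < 1e-3

    def test_matches_scipy_align_vectors(self, rng):
        a = rng.normal(0, 3, (12, 3))
        b = a + rng.normal(0, 0.8, a.shape)
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        expected = rssd / np.sqrt(len(a))
        assert np.isclose(superpose(a, b).rmsd, expected, atol=1e-8)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_no_reflection_for_chiral_cloud(self, rng):
        a = rng.normal(0, 3, (8, 3))
        mirrored = a * np.array([1.0, 1.0, -1.0])
        res = superpose(mirrored, a)
        assert np.isclose(np.linalg.det(res.rotation), 1.0, atol=1e-12)
        assert res.rmsd > 0.1  # a proper rotation cannot undo a reflection


class TestFitRMSD:
    def test_identity_zero(self, rng):
        coords = rng.normal(0, 4, (12, 3))
        assert fit_rmsd(coords, coords, range(6), range(6, 12)) < 1e-12

    def test_translated_measure_subset(self, rng):
        ref = rng.normal(0, 4, (12, 3))
        frame = ref.copy()
        frame[6:] += np.array([2.0, 0.0, 0.0])
        assert np.isclose(fit_rmsd(frame, ref, range(6), range(6, 12)), 2.0, atol=1e-10)

    def test_fit_equals_measure_matches_superpose(self, rng):
        ref = rng.normal(0, 4, (10, 3))
        frame = ref + rng.normal(0, 0.5, ref.shape)
        assert np.isclose(
            fit_rmsd(frame, ref, range(10), range(10)),
            superpose(frame, ref).rmsd,
            atol=1e-10,
        )


class TestContacts:
    def test_cutoff_is_strict(self):
        a = np.array([[0.0, 0, 0]])
        assert contacts_between(a, np.array([[3.9, 0, 0]]), 4.0) == [(0, 0)]
        assert contacts_between(a, np.array([[4.0, 0, 0]]), 4.0) == []

    def test_matches_exhaustive_oracle(self, rng):
        a = rng.uniform(0, 10, (5, 3))
        b = rng.uniform(0, 10, (5, 3))
        expected = {
            (i, j)
            for i in range(5)
            for j in range(5)
            if np.linalg.norm(a[i] - b[j]) < 6.0
        }
        assert set(contacts_between(a, b, 6.0)) == expected

    def test_symmetric_under_group_swap(self, rng):
        a = rng.uniform(0, 8, (6, 3))
        b = rng.uniform(0, 8, (4, 3))
        fwd = set(contacts_between(a, b, 5.0))
        rev = {(j, i) for i, j in contacts_between(b, a, 5.0)}
        assert fwd == rev

    def test_empty_inputs(self):
        assert contacts_between(np.empty((0, 3)), np.empty((0, 3)), 4.0) == []


class TestCrossCrystal:
    def test_shared_calpha_rmsd_matches_oracle(self, rng, tmp_path):
        """Two synthetic 'crystal forms' of one chain: the shared-site RMSD
        must equal an independently computed Kabsch fit (scipy oracle)."""
        s = random_structure(rng, n=12)
        coords_b = _rigid(s.coordinates, 25.0, (0.3, 1, 0.2), (4, 4, 4))
        coords_b += rng.normal(0, 0.3, coords_b.shape)
        # second form misses two terminal residues
        atoms_b = [
            AtomRecord(a.serial, a.name, a.residue_name, a.chain_id, a.residue_number,
                       tuple(coords_b[i]), a.element)
            for i, a in enumerate(s.atoms)
        ][1:-1]
        pa, pb = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(s, pa)
        write_structure(Structure(atoms_b), pb)
        got = cross_crystal_rmsd(pa, pb)
        shared_a = np.array([s.coordinates[i] for i in range(1, 11)])
        shared_b = coords_b[1:11]
        rot, rssd = Rotation.align_vectors(
            shared_b - shared_b.mean(0), shared_a - shared_a.mean(0)
        )
        # PDB coordinates are written at 1e-3 A precision
        assert np.isclose(got, rssd / np.sqrt(10), atol=5e-3)
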