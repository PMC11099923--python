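import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nmrdock.errors import DataError, NumericError, ParseError
from nmrdock.structure import (Atom, Chain, Residue, RigidTransform, Structure,
                               apply_transform, interface_residues,
                               kabsch_superpose, read_pdb, salt_bridges,
                               write_pdb)

TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104  22.200   3.000  1.00 10.00           N
ATOM      2  CA  ALA A   1      12.560  22.123   3.456  1.00 11.00           C
END
"""


def _simple_structure():
    res = Residue(1, "ALA", [Atom("N", "N", [0.0, 0.0, 0.0]),
                             Atom("CA", "C", [1.5, 0.0, 0.0])])
    return Structure([Chain("A", [res])])


class TestReadPDB:
    def test_two_atom_file_fields_copied(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_ATOM_PDB)
        s = read_pdb(path)
        assert s.n_atoms == 2
        ca = s.chain("A").residue(1).atom("CA")
        assert np.allclose(ca.xyz, [12.560, 22.123, 3.456])
        assert ca.element == "C" and ca.bfactor == 11.0

    def test_write_read_roundtrip(self, tmp_path, gt7):
        path = tmp_path / "complex.pdb"
        write_pdb(gt7.structure, path)
        again = read_pdb(path)
        np.testing.assert_allclose(again.coords(), gt7.structure.coords(),
                                   atol=1e-3)
        assert [c.chain_id for c in again.chains] == ["A", "B"]

    def test_multi_model_keeps_first(self, tmp_path):
        body = TWO_ATOM_PDB.replace("END\n", "")
        text = "".join(f"MODEL     {i}\n{body}ENDMDL\n" for i in (1, 2, 3)) + "END\n"
        path = tmp_path / "models.pdb"
        path.write_text(text)
        assert read_pdb(path).n_atoms == 2  # one model's worth, not three

    def test_insertion_code_rejected(self, tmp_path):
        bad = TWO_ATOM_PDB.replace("ALA A   1 ", "ALA A   1A")
        path = tmp_path / "icode.pdb"
        path.write_text(bad)
        with pytest.raises(ParseError, match="line 1"):
            read_pdb(path)

    def test_malformed_coordinate_names_line(self, tmp_path):
        bad = TWO_ATOM_PDB.replace("12.560", "twelve")
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.raises(ParseError, match="line 2"):
            read_pdb(path)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(DataError):
            read_pdb(path)


class TestRigidTransform:
    def test_identity_leaves_coordinates(self):
        s = _simple_structure()
        out = apply_transform(s, RigidTransform.identity())
        np.testing.assert_array_equal(out.coords(), s.coords())

    def test_180_deg_z_rotation(self):
        t = RigidTransform.from_rotation(Rotation.from_euler("z", 180, degrees=True))
        np.testing.assert_allclose(t.apply(np.array([1.0, 0.0, 0.0])),
                                   [-1.0, 0.0, 0.0], atol=1e-12)

    def test_non_unit_quaternion_rejected(self):
        with pytest.raises(NumericError):
            RigidTransform(np.array([1.0, 0.1, 0.0, 0.0]), np.zeros(3))

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_roundtrip_and_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng)
        t = RigidTransform.from_rotation(rot, rng.normal(size=3) * 10)
        pts = rng.normal(size=(30, 3)) * 20
        # matrix oracle for the forward map
        np.testing.assert_allclose(t.apply(pts), pts @ rot.as_matrix().T + t.t,
                                   atol=1e-12)
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)
        # compose(t, inverse(t)) is the identity map
        ident = t.compose(t.inverse())
        np.testing.assert_allclose(ident.apply(pts), pts, atol=1e-9)

    def test_distances_preserved(self, gt7):
        rng = np.random.default_rng(1)
        t = RigidTransform.from_rotation(Rotation.random(rng=rng), [3.0, -2.0, 8.0])
        before = gt7.structure.coords()[:50]
        after = t.apply(before)
        d0 = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
        d1 = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, rng):
        pts = rng.normal(size=(20, 3))
        t, r = kabsch_superpose(pts, pts)
        assert r < 1e-6
        np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-6)

    def test_known_rotation_recovered(self, rng):
        pts = rng.normal(size=(25, 3)) * 10
        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True)
        t, r = kabsch_superpose(pts, pts @ rot.as_matrix().T)
        assert r < 1e-6
        np.testing.assert_allclose(t.matrix, rot.as_matrix(), atol=1e-8)
        assert np.isclose(np.linalg.det(t.matrix), 1.0)

    def test_noisy_copy_rmsd_band(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(100, 3)) * 15
        noisy = pts + rng.normal(scale=0.1, size=pts.shape)
        _, r = kabsch_superpose(noisy, pts)
        assert 0.10 <= r <= 0.25

    def test_symmetry(self, rng):
        a = rng.normal(size=(12, 3))
        b = a + rng.normal(scale=0.3, size=a.shape)
        _, rab = kabsch_superpose(a, b)
        _, rba = kabsch_superpose(b, a)
        assert abs(rab - rba) < 1e-9 and rab >= 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DataError):
            kabsch_superpose(line, line)


class TestInterface:
    @staticmethod
    def _pair(distance):
        a = Residue(1, "ALA", [Atom("CA", "C", [0.0, 0.0, 0.0])])
        b = Residue(1, "ALA", [Atom("CA", "C", [distance, 0.0, 0.0])])
        return Structure([Chain("A", [a]), Chain("B", [b])])

    def test_far_apart_empty(self):
        s = self._pair(100.0)
        assert interface_residues(s, "A", "B", 5.0) == (set(), set())

    def test_boundary_pair_included(self):
        s = self._pair(4.9)
        assert interface_residues(s, "A", "B", 5.0) == ({1}, {1})
        assert interface_residues(s, "A", "B", 4.9) == (set(), set())

    def test_matches_generator_truth(self, gt7):
        int_a, int_b = interface_residues(gt7.structure, "A", "B", 5.0)
        assert int_a == gt7.interface_receptor
        assert int_b == gt7.interface_ligand

    def test_symmetric_and_monotone(self, gt7):
        a1, b1 = interface_residues(gt7.structure, "A", "B", 5.0)
        b2, a2 = interface_residues(gt7.structure, "B", "A", 5.0)
        assert (a1, b1) == (a2, b2)
        a3, b3 = interface_residues(gt7.structure, "A", "B", 6.5)
        assert a1 <= a3 and b1 <= b3

    def test_unknown_chain(self, gt7):
        with pytest.raises(DataError):
            interface_residues(gt7.structure, "A", "Z", 5.0)


class TestSaltBridges:
    @staticmethod
    def _asp_arg(distance):
        asp = Residue(1, "ASP", [Atom("OD1", "O", [0.0, 0.0, 0.0]),
                                 Atom("OD2", "O", [-1.0, 1.8, 0.0])])
        arg = Residue(2, "ARG", [Atom("NH1", "N", [distance, 0.0, 0.0]),
                                 Atom("NE", "N", [distance + 1.4, 0.0, 0.0])])
        return Structure([Chain("A", [asp]), Chain("B", [arg])])

    def test_pair_at_3p5_reported(self):
        out = salt_bridges(self._asp_arg(3.5))
        assert len(out) == 1
        assert out[0].acidic == ("A", 1) and out[0].basic == ("B", 2)
        assert math.isclose(out[0].distance, 3.5)

    def test_pair_beyond_cutoff_absent(self):
        assert salt_bridges(self._asp_arg(4.5), cutoff=4.0) == []

    def test_engineered_bridge_found(self, gt7):
        found = salt_bridges(gt7.structure)
        pairs = {(b.acidic, b.basic) for b in found}
        assert (("B", gt7.bridge[1]), ("A", gt7.bridge[0])) in pairs
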