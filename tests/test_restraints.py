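import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrdock.errors import DataError, ParseError
from nmrdock.restraints import (Restraint, build_air,
                                effective_distance, effective_distance_from_coords,
                                read_restraints_json, read_tbl, restraint_energy,
                                violation_energy, write_restraints_json, write_tbl)
from nmrdock.structure import RigidTransform, apply_transform


def brute_force_deff(a, b):
    s = 0.0
    for p in a:
        for q in b:
            s += float(np.linalg.norm(p - q)) ** -6
    return s ** (-1.0 / 6.0)


class TestEffectiveDistance:
    def test_single_pair_is_plain_distance(self):
        assert effective_distance_from_coords([[0, 0, 0]], [[5, 0, 0]]) == pytest.approx(5.0)

    def test_short_pair_dominates(self):
        a = [[0, 0, 0]]
        b = [[3, 0, 0], [1000, 0, 0]]
        d = effective_distance_from_coords(a, b)
        assert d == pytest.approx(2.9999999999999996, abs=1e-12)
        assert d < 3.0

    @pytest.mark.parametrize("n", [1, 2, 5, 17])
    def test_equal_pairs_closed_form(self, n, rng):
        # n points all at distance d from one center: d_eff = d * n^(-1/6)
        d = 7.3
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        a = [[0.0, 0.0, 0.0]]
        b = d * dirs
        expected = d * n ** (-1.0 / 6.0)
        assert effective_distance_from_coords(a, b) == pytest.approx(expected, rel=1e-12)
        assert brute_force_deff(np.zeros((1, 3)), b) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 20, size=(rng.integers(1, 8), 3))
        b = rng.uniform(5, 30, size=(rng.integers(1, 12), 3))
        fast = effective_distance_from_coords(a, b)
        assert fast == pytest.approx(brute_force_deff(a, b), abs=1e-9)
        # permutation invariance
        perm = rng.permutation(len(b))
        assert effective_distance_from_coords(a, b[perm]) == pytest.approx(fast, rel=1e-12)

    def test_never_above_min_distance(self, rng):
        a = rng.uniform(0, 10, size=(6, 3))
        b = rng.uniform(0, 10, size=(9, 3))
        d_eff = effective_distance_from_coords(a, b)
        dmin = np.min(np.linalg.norm(a[:, None] - b[None, :], axis=-1))
        assert d_eff <= dmin + 1e-12

    def test_min_aggregation(self):
        a = [[0, 0, 0]]
        b = [[3, 0, 0], [4, 0, 0]]
        assert effective_distance_from_coords(a, b, "min") == pytest.approx(3.0)

    @settings(derandomize=True, max_examples=50)
    @given(shift=st.floats(min_value=0.0, max_value=5.0))
    def test_monotone_under_approach(self, shift):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[10.0, 0.0, 0.0], [12.0, 3.0, 0.0]])
        far = effective_distance_from_coords(a, b)
        near = effective_distance_from_coords(a, b - [shift, 0.0, 0.0])
        assert near <= far + 1e-12


class TestViolationEnergy:
    def test_satisfied_zero_at_truth(self, gt7, truth_restraints7):
        total, report = violation_energy(gt7.structure, truth_restraints7)
        assert total == pytest.approx(0.0, abs=1e-9)
        assert all(row[3] == 0.0 for row in report)

    def test_two_angstrom_violation(self):
        r = Restraint("unambiguous", (("A", 1, "CA"),), (("B", 1, "CA"),),
                      d_upper=3.0, weight=1.0)
        e, viol = restraint_energy(5.0, r)
        assert e == pytest.approx(4.0) and viol == pytest.approx(2.0)

    def test_truth_beats_random_poses(self, gt7, truth_restraints7):
        e_truth, _ = violation_energy(gt7.structure, truth_restraints7)
        rng = np.random.default_rng(0)
        from scipy.spatial.transform import Rotation
        worse = 0
        for _ in range(25):
            t = RigidTransform.from_rotation(Rotation.random(rng=rng),
                                             rng.normal(scale=15.0, size=3))
            moved = gt7.structure.copy()
            lig = apply_transform(gt7.ligand(), t)
            moved = type(moved)([gt7.receptor().chains[0], lig.chains[0]])
            e_rand, _ = violation_energy(moved, truth_restraints7)
            worse += e_rand > e_truth
        assert worse == 25

    def test_report_sorted_by_violation(self, gt7, truth_restraints7):
        lig = apply_transform(gt7.ligand(), RigidTransform.from_quat(
            [1, 0, 0, 0], [25.0, 0, 0]))
        moved = type(gt7.structure)([gt7.receptor().chains[0], lig.chains[0]])
        _, report = violation_energy(moved, truth_restraints7)
        viols = [row[2] for row in report]
        assert viols == sorted(viols, reverse=True)


class TestBuildAIR:
    def test_empty_active_set_rejected(self, gt7):
        with pytest.raises(DataError):
            build_air(set(), {1}, gt7.receptor(), gt7.ligand())

    def test_missing_resid_reported(self, gt7):
        with pytest.raises(DataError, match="9999"):
            build_air({9999}, gt7.interface_ligand, gt7.receptor(), gt7.ligand())

    def test_zero_passive_cutoff_means_active_only(self, gt7):
        airs = build_air(gt7.interface_receptor, gt7.interface_ligand,
                         gt7.receptor(), gt7.ligand(), passive_cutoff=0.0)
        pool_b = {rid for _, rid, _ in airs[0].selection_b}
        assert pool_b == gt7.interface_ligand

    def test_symmetric_counts_and_satisfied_at_truth(self, gt7):
        airs = build_air(gt7.interface_receptor, gt7.interface_ligand,
                         gt7.receptor(), gt7.ligand())
        assert len(airs) == len(gt7.interface_receptor) + len(gt7.interface_ligand)
        total = sum(restraint_energy(effective_distance(gt7.structure, r), r)[0]
                    for r in airs)
        assert total == pytest.approx(0.0, abs=1e-9)


class TestTblRoundTrip:
    def test_roundtrip(self, tmp_path):
        rs = [
            Restraint("unambiguous", (("A", 12, "N"),), (("B", 33, "N"),),
                      d_upper=6.0, weight=2.0, source="STD"),
            Restraint("ambiguous", (("A", 5, "*"),),
                      (("B", 3, "*"), ("B", 5, "*"), ("B", 9, "*")),
                      d_upper=3.5, source="CSP"),
            Restraint("ambiguous", (("A", 40, "H|HN|N"),),
                      (("B", 44, "SG"), ("B", 46, "SG")),
                      d_target=18.0, d_lower=14.0, d_upper=22.0,
                      source="PRE", aggregate="min"),
            Restraint("ambiguous", (("A", 41, "N"),), (("B", 44, "SG"),),
                      d_lower=22.622, source="PRE", aggregate="min"),
        ]
        path = tmp_path / "restraints.tbl"
        write_tbl(rs, path)
        again = read_tbl(path)
        assert again == rs

    def test_upper_bound_encoding(self, tmp_path):
        r = Restraint("unambiguous", (("A", 1, "N"),), (("B", 2, "N"),), d_upper=6.0)
        path = tmp_path / "u.tbl"
        write_tbl([r], path)
        line = [ln for ln in path.read_text().splitlines() if ln.startswith("assign")][0]
        assert line.endswith("6.000 6.000 0.000")  # d encodes the bound, dplus the slack

    def test_malformed_line(self, tmp_path):
        path = tmp_path / "bad.tbl"
        path.write_text("assign (segid A and resid 1 and name N) oops\n")
        with pytest.raises(ParseError, match="line 1"):
            read_tbl(path)

    def test_writer_is_deterministic(self, tmp_path, truth_restraints7):
        p1, p2 = tmp_path / "a.tbl", tmp_path / "b.tbl"
        write_tbl(truth_restraints7, p1)
        write_tbl(truth_restraints7, p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_json_dump_roundtrip(tmp_path, truth_restraints7):
    path = tmp_path / "restraints.json"
    write_restraints_json(truth_restraints7, path)
    assert read_restraints_json(path) == truth_restraints7


def test_restraint_validation():
    with pytest.raises(DataError):
        Restraint("unambiguous", (("A", 1, "N"),), (("B", 2, "N"),))  # no bounds
    with pytest.raises(DataError):
        Restraint("unambiguous", (("A", 1, "N"),), (("A", 2, "N"),), d_upper=5.0)
    with pytest.raises(DataError):
        Restraint("unambiguous", (("A", 1, "N"),), (("B", 2, "N"),),
                  d_lower=10.0, d_upper=5.0)
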