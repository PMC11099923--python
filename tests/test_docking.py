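import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import kstest

from nmrdock.docking import (DockParams, DockWeights, DockingEngine, Pose,
                             clash_score, clash_score_bruteforce, dock,
                             rescore_by_clash, sample_orientations)
from nmrdock.errors import DataError
from nmrdock.structure import (Atom, Chain, Residue, RigidTransform, Structure,
                               apply_transform)


def _small_params(**kw):
    base = dict(n_orient=30, trials=4, search_iters=12, refine_top=6,
                refine_iters=20)
    base.update(kw)
    return DockParams(**base)


@pytest.fixture(scope="module")
def engine7(gt7, truth_restraints7):
    return DockingEngine(gt7.receptor(), gt7.ligand(), truth_restraints7)


class TestSampleOrientations:
    def test_deterministic(self):
        q1 = sample_orientations(5, 123)
        q2 = sample_orientations(5, 123)
        np.testing.assert_array_equal(q1, q2)
        assert q1.shape == (5, 4)
        np.testing.assert_allclose(np.linalg.norm(q1, axis=1), 1.0, atol=1e-12)

    def test_rotation_angle_density(self):
        # uniform SO(3): angle density (1-cos t)/pi, CDF (t - sin t)/pi
        q = sample_orientations(10_000, 2024)
        angles = 2.0 * np.arccos(np.clip(np.abs(q[:, 0]), -1.0, 1.0))
        stat = kstest(angles, lambda t: (t - np.sin(t)) / np.pi)
        assert stat.pvalue > 0.01

    def test_mean_rotated_vector_near_zero(self):
        q = sample_orientations(10_000, 7)
        rots = Rotation.from_quat(q, scalar_first=True)
        v = rots.apply(np.array([0.0, 0.0, 1.0]))
        assert np.linalg.norm(v.mean(axis=0)) < 0.05

    def test_n_must_be_positive(self):
        with pytest.raises(DataError):
            sample_orientations(0, 1)


def _carbon_pair(distance):
    a = Structure([Chain("A", [Residue(1, "ALA", [Atom("CA", "C", [0.0, 0.0, 0.0])])])])
    b = Structure([Chain("B", [Residue(1, "ALA", [Atom("CA", "C", [distance, 0.0, 0.0])])])])
    return a, b


class TestClashScore:
    def test_far_apart_zero(self):
        a, b = _carbon_pair(100.0)
        assert clash_score(a, b) == 0.0

    def test_boundary_exact_zero(self):
        a, b = _carbon_pair(0.8 * (1.7 + 1.7))
        assert clash_score(a, b) == 0.0

    def test_overlap_quadratic(self):
        a, b = _carbon_pair(0.8 * 3.4 - 0.5)
        assert clash_score(a, b) == pytest.approx(0.25, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_equals_bruteforce(self, seed, gt7):
        rng = np.random.default_rng(seed)
        t = RigidTransform.from_rotation(Rotation.random(rng=rng),
                                         rng.normal(scale=4.0, size=3))
        lig = apply_transform(gt7.ligand(), t)
        fast = clash_score(gt7.receptor(), lig)
        slow = clash_score_bruteforce(gt7.receptor(), lig)
        assert fast == pytest.approx(slow, abs=1e-9)


class TestScoring:
    def test_truth_pose_restraint_energies_zero(self, engine7):
        pose = engine7.score_pose(Pose(0, RigidTransform.identity()))
        assert pose.e_air == pytest.approx(0.0, abs=1e-9)
        assert pose.e_pre == 0.0 and pose.e_std == 0.0
        assert pose.score == pytest.approx(
            engine7.params.weights.w_clash * pose.e_clash, abs=1e-9)

    def test_zero_weights_zero_score(self, engine7):
        w = DockWeights(0.0, 0.0, 0.0, 0.0)
        pose = engine7.score_pose(Pose(0, RigidTransform.from_quat(
            [1, 0, 0, 0], [30.0, 0.0, 0.0])), weights=w)
        assert pose.score == 0.0

    def test_score_linear_in_weights(self, engine7):
        t = RigidTransform.from_quat([1, 0, 0, 0], [15.0, 0.0, 0.0])
        p1 = engine7.score_pose(Pose(0, t), weights=DockWeights(1.0, 0.0, 0.0, 0.0))
        p2 = engine7.score_pose(Pose(0, t), weights=DockWeights(2.0, 0.0, 0.0, 0.0))
        assert p2.score == pytest.approx(2.0 * p1.score, rel=1e-12)

    def test_invariance_under_joint_rigid_motion(self, gt7, truth_restraints7, engine7):
        rng = np.random.default_rng(11)
        g = RigidTransform.from_rotation(Rotation.random(rng=rng),
                                         rng.normal(scale=10.0, size=3))
        pose_t = RigidTransform.from_quat(
            Rotation.random(rng=rng).as_quat(scalar_first=True),
            rng.normal(scale=5.0, size=3))
        moved_engine = DockingEngine(apply_transform(gt7.receptor(), g),
                                     apply_transform(gt7.ligand(), g),
                                     truth_restraints7)
        # the equivalent pose in the moved frame: g . pose . g^-1
        pose_moved = g.compose(pose_t).compose(g.inverse())
        s0 = engine7.score_pose(Pose(0, pose_t)).score
        s1 = moved_engine.score_pose(Pose(0, pose_moved)).score
        assert s1 == pytest.approx(s0, rel=1e-6, abs=1e-8)


class TestPlacements:
    def test_count_distinct_deterministic(self, engine7):
        a = engine7.initial_placements(10, seed=4)
        b = engine7.initial_placements(10, seed=4)
        assert len(a) == 10
        keys = {tuple(np.round(p.transform.t, 6)) for p in a}
        assert len(keys) == 10  # no two initial poses identical
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.transform.t, pb.transform.t)
            np.testing.assert_array_equal(pa.transform.q, pb.transform.q)

    def test_placements_start_mostly_outside_contact(self, engine7):
        # reference scale: the true ligand pressed 2 Å into the receptor
        into = engine7.rec_xyz.mean(axis=0) - engine7.lig_centroid0
        into = 2.0 * into / np.linalg.norm(into)
        pressed = engine7.score_pose(Pose(0, RigidTransform.from_quat(
            [1, 0, 0, 0], into)))
        assert pressed.e_clash > 0
        clashes = [engine7.score_pose(p).e_clash
                   for p in engine7.initial_placements(20, seed=9)]
        assert max(clashes) < 0.1 * pressed.e_clash

    def test_unguided_docking_rejected(self, gt7):
        with pytest.raises(DataError):
            DockingEngine(gt7.receptor(), gt7.ligand(), []).initial_placements(5, 0)


class TestMinimize:
    def test_never_worse_than_input(self, engine7):
        pose = engine7.initial_placements(3, seed=2)[1]
        s_in = engine7.score_pose(pose).score
        out = engine7.minimize_pose(pose, trials=2, seed=3)
        assert out.score <= s_in + 1e-9

    def test_truth_is_a_fixed_point(self, engine7):
        start = engine7.score_pose(Pose(0, RigidTransform.identity()))
        assert start.score == pytest.approx(0.0, abs=1e-9)
        out = engine7.minimize_pose(start, trials=3, seed=5)
        assert out.score == pytest.approx(start.score, abs=1e-6)

    def test_displaced_pose_recovered(self, gt7):
        # tight restraints (0.5 Å PRE margins) pin the minimum to the truth
        from nmrdock.synthetic import ground_truth_restraints
        sharp = ground_truth_restraints(gt7, pre_margin=0.5)
        engine = DockingEngine(gt7.receptor(), gt7.ligand(), sharp)
        displaced = Pose(0, RigidTransform.from_quat([1, 0, 0, 0],
                                                     [2.3, -2.3, 2.0]))
        out = engine.minimize_pose(displaced, trials=10, seed=8, n_iter=60)
        rmsd = engine.ligand_rmsd(out, RigidTransform.identity())
        assert rmsd <= 1.0
        assert out.score == pytest.approx(0.0, abs=1e-6)

    def test_more_trials_never_worse(self, engine7):
        # same restart stream: the 10-trial best subsumes the 1-trial best
        pose = engine7.initial_placements(2, seed=6)[0]
        for seed in range(20):
            s1 = engine7.minimize_pose(pose, trials=1, seed=seed).score
            s10 = engine7.minimize_pose(pose, trials=10, seed=seed).score
            assert s10 <= s1 + 1e-9


class TestRankSelect:
    def test_z_scores_hand_example(self, engine7):
        poses = [Pose(0, RigidTransform.identity(), score=-10.0, e_air=0.0),
                 Pose(1, RigidTransform.from_quat([1, 0, 0, 0], [1.0, 0, 0]),
                      score=-5.0, e_air=0.0)]
        ranked = engine7.rank_select(poses, top_n=2)
        assert ranked[0].z_score == pytest.approx(-math.sqrt(0.5), abs=1e-9)
        assert ranked[1].z_score == pytest.approx(+math.sqrt(0.5), abs=1e-9)

    def test_identical_scores_zero_z(self, engine7):
        poses = [Pose(i, RigidTransform.from_quat([1, 0, 0, 0], [float(i), 0, 0]),
                      score=2.0, e_air=0.0) for i in range(3)]
        ranked = engine7.rank_select(poses, top_n=3)
        assert all(p.z_score == 0.0 for p in ranked)
        assert [p.index for p in ranked] == [0, 1, 2]  # tie-break by index

    def test_z_scores_standardised(self, engine7):
        rng = np.random.default_rng(3)
        poses = [Pose(i, RigidTransform.from_quat([1, 0, 0, 0], [float(i), 0, 0]),
                      score=float(s), e_air=0.0)
                 for i, s in enumerate(rng.normal(10, 4, size=20))]
        ranked = engine7.rank_select(poses, top_n=20)
        z = np.array([p.z_score for p in ranked])
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_needs_two_poses(self, engine7):
        with pytest.raises(DataError):
            engine7.rank_select([Pose(0, RigidTransform.identity(), score=1.0)], 1)


class TestDockEndToEnd:
    def test_deterministic_ranked_list(self, gt7, truth_restraints7):
        kw = dict(params=_small_params(), seed=5)
        r1 = dock(gt7.receptor(), gt7.ligand(), truth_restraints7, **kw)
        r2 = dock(gt7.receptor(), gt7.ligand(), truth_restraints7, **kw)
        for a, b in zip(r1.ranked, r2.ranked):
            assert a.index == b.index and a.score == b.score
            np.testing.assert_array_equal(a.transform.q, b.transform.q)
            np.testing.assert_array_equal(a.transform.t, b.transform.t)

    def test_recovers_truth_cluster(self, gt7, truth_restraints7):
        res = dock(gt7.receptor(), gt7.ligand(), truth_restraints7,
                   params=_small_params(n_orient=100, trials=8, search_iters=20,
                                        refine_top=15, refine_iters=40),
                   seed=2)
        eng = res.engine
        top = res.ranked[0]
        # the truth pose would join the top-ranked pose's cluster
        assert eng.ligand_rmsd(top, RigidTransform.identity()) <= eng.params.cluster_cutoff

    def test_clash_only_control_is_worse(self, gt7, truth_restraints7):
        res = dock(gt7.receptor(), gt7.ligand(), truth_restraints7,
                   params=_small_params(), seed=3)
        eng = res.engine
        control = rescore_by_clash(res)
        guided_rmsd = eng.ligand_rmsd(res.ranked[0], RigidTransform.identity())
        control_rmsd = eng.ligand_rmsd(control[0], RigidTransform.identity())
        assert guided_rmsd < control_rmsd
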