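"""Rigid alignment: coarse offsets, correspondences, SVD estimate, ICP."""

import numpy as np
import pytest

import railphen as rp

from conftest import random_cloud


def random_rigid(rng, max_angle_deg=5.0, max_trans=0.10):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.normal(size=3)
    t *= rng.uniform(0, max_trans) / np.linalg.norm(t)
    return rp.RigidTransform(R, t)


class TestRigidTransform:
    def test_rejects_non_rotation(self):
        with pytest.raises(ValueError):
            rp.RigidTransform(np.eye(3) * 2, np.zeros(3))

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            rp.RigidTransform(np.diag([1, 1, -1]), np.zeros(3))

    def test_compose_inverse_is_identity(self, rng):
        T = random_rigid(rng)
        I = T.compose(T.inverse())
        assert np.allclose(I.R, np.eye(3), atol=1e-12)
        assert np.allclose(I.t, 0, atol=1e-12)


class TestCoarseOffset:
    def test_first_block_is_origin(self):
        assert np.array_equal(rp.coarse_offset(1), np.zeros(3))

    def test_second_block_moves_one_spacing(self):
        # stop spacing 190 cm: block 2 moves 1.90 m along the travel axis
        assert np.allclose(rp.coarse_offset(2, 1.90), [0, 0, 1.90])

    def test_fourth_block(self):
        assert np.allclose(rp.coarse_offset(4, 1.90), [0, 0, 5.70])

    def test_index_below_one_rejected(self):
        with pytest.raises(ValueError):
            rp.coarse_offset(0)


class TestFindCorrespondences:
    def test_identical_clouds_all_zero(self, rng):
        c = random_cloud(rng, 50)
        i, j, d = rp.find_correspondences(c, c, 0.05)
        assert len(i) == 50 and np.allclose(d, 0)

    def test_uniform_shift_within_gate(self, rng):
        # brute-force check of every nearest pair under a 1 cm shift
        src = random_cloud(rng, 40)
        tgt = src.translated([0.01, 0, 0])
        i, j, d = rp.find_correspondences(src, tgt, 0.05)
        assert len(i) == 40
        full = np.linalg.norm(tgt.xyz[:, None, :] - src.xyz[None, :, :], axis=2)
        assert np.array_equal(j, full.argmin(axis=1)[i])
        assert np.allclose(d, full.min(axis=1), atol=1e-12)

    def test_gate_excludes_distant_clouds(self, rng):
        src = random_cloud(rng, 20)
        tgt = src.translated([50.0, 0, 0])
        i, j, d = rp.find_correspondences(src, tgt, 0.05)
        assert len(i) == 0


class TestEstimateTransform:
    def test_identity_pairs(self, rng):
        c = random_cloud(rng, 10)
        idx = np.arange(10)
        T = rp.estimate_transform(idx, idx, c, c)
        assert np.allclose(T.R, np.eye(3), atol=1e-12)
        assert np.allclose(T.t, 0, atol=1e-12)

    def test_recovers_known_motion_to_1e9(self, rng):
        for _ in range(50):
            src = random_cloud(rng, 30)
            T0 = random_rigid(rng, 5.0, 0.10)
            tgt = src.transformed(T0.R, T0.t)
            idx = np.arange(30)
            T = rp.estimate_transform(idx, idx, src, tgt)
            assert np.allclose(T.R, T0.R, atol=1e-9)
            assert np.allclose(T.t, T0.t, atol=1e-9)
            # proper rotation invariants
            assert np.allclose(T.R @ T.R.T, np.eye(3), atol=1e-9)
            assert np.isclose(np.linalg.det(T.R), 1.0, atol=1e-9)

    def test_collinear_pairs_rejected(self):
        line = rp.PointCloud(np.outer(np.arange(5.0), [1, 1, 1]))
        idx = np.arange(5)
        with pytest.raises(ValueError, match="degenerate"):
            rp.estimate_transform(idx, idx, line, line)

    def test_too_few_pairs_rejected(self, rng):
        c = random_cloud(rng, 5)
        with pytest.raises(ValueError, match="3"):
            rp.estimate_transform(np.arange(2), np.arange(2), c, c)


class TestICP:
    def test_identical_clouds_converge_immediately(self, rng):
        c = random_cloud(rng, 100)
        res = rp.icp(c, c)
        assert res.converged and res.iterations == 1
        assert res.final_d < 1e-12

    def test_full_overlap_recovers_inverse_motion(self, rng):
        # 50 random motions within (5 deg, 10 cm) on a structured cloud
        base = rng.uniform(-0.5, 0.5, (300, 3))
        cloud = rp.PointCloud(base)
        params = rp.ICPParams(max_corr_dist=0.3, d_threshold=1e-10,
                              stall_delta=1e-12, max_iterations=200)
        for _ in range(50):
            T0 = random_rigid(rng, 5.0, 0.10)
            moved = cloud.transformed(T0.R, T0.t)
            res = rp.icp(moved, cloud, params)
            err = res.transform.compose(T0)
            assert np.degrees(err.rotation_angle()) < 1e-4
            assert np.linalg.norm(err.t) < 1e-6

    def test_disjoint_clouds_do_not_converge(self, rng):
        a = random_cloud(rng, 30)
        b = a.translated([100, 0, 0])
        res = rp.icp(a, b)
        assert not res.converged

    def test_error_function_non_increasing_on_fixed_pairs(self, rng):
        # one Kabsch step can only decrease E(R, t) on its own pairs
        src = random_cloud(rng, 80)
        T0 = random_rigid(rng, 3.0, 0.02)
        tgt = src.transformed(T0.R, T0.t)
        i, j, d0 = rp.find_correspondences(src, tgt, 0.5)
        T = rp.estimate_transform(i, j, src, tgt)
        moved = T.apply(src.xyz)
        e_before = float((d0 ** 2).mean())
        e_after = float(((moved[j] - tgt.xyz[i]) ** 2).sum(axis=1).mean())
        assert e_after <= e_before + 1e-15


class TestMergeBlocks:
    def test_single_block_unchanged(self, rng):
        c = random_cloud(rng, 40)
        res = rp.merge_blocks([c])
        assert np.array_equal(res.cloud.xyz, c.xyz)

    def test_output_size_is_sum_of_blocks(self, small_noisy):
        scene, streams, truth = small_noisy
        rail = rp.RailConfig.from_speed("344 cm/min")
        blocks = [rp.stitch(s, rail) for s in streams]
        res = rp.merge_blocks(blocks)
        assert len(res.cloud) == sum(len(b) for b in blocks)

    def test_noiseless_blocks_align_to_submillimeter(self, small_noiseless):
        scene, streams, truth = small_noiseless
        rail = rp.RailConfig.from_speed("344 cm/min")
        blocks = [rp.stitch(s, rail) for s in streams]
        res = rp.merge_blocks(blocks)
        # block 2 coarse-shifted should already be exact; ICP must not break it
        shifted = blocks[1].translated(rp.coarse_offset(2))
        refined = res.cloud.xyz[len(blocks[0]):]
        rms = np.sqrt(((refined - shifted.xyz) ** 2).sum(axis=1).mean())
        assert rms < 1e-3

    def test_stop_error_reduced_by_icp(self, small_noisy):
        # blocks with injected stop error: post-ICP residual < coarse-only residual
        scene, streams, truth = small_noisy
        rail = rp.RailConfig.from_speed("344 cm/min")
        blocks = [rp.stitch(s, rail) for s in streams]
        res = rp.merge_blocks(blocks)
        rec = res.transforms[1]
        o = rp.coarse_offset(2)
        T0, T1 = truth.block_transforms
        ideal = T0.compose(rp.RigidTransform(np.eye(3), o).compose(T1.inverse()))
        coarse = rp.RigidTransform(np.eye(3), o)
        c = blocks[1].xyz.mean(axis=0) + o
        err_icp = np.linalg.norm(rec.compose(ideal.inverse()).apply(c) - c)
        err_coarse = np.linalg.norm(coarse.compose(ideal.inverse()).apply(c) - c)
        assert err_icp < err_coarse
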