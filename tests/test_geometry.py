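"""Superposition and structural-metric correctness."""

import numpy as np
import pytest

from pocketrepo.geometry import (
    RigidTransform,
    gdt_ts,
    kabsch_superpose,
    mcc_sets,
    rmsd_paired,
    tm_score,
)

from conftest import random_rotation


class TestKabsch:
    def test_recovers_planted_rigid_motion(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        rot = random_rotation(rng)
        moved = pts @ rot.T + np.array([1.0, 2.0, 3.0])
        result = kabsch_superpose(moved, pts)
        assert result.rmsd < 1e-9
        assert result.n_points == 10

    def test_rotation_90deg_translation(self):
        pts = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float)
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        moved = pts @ rot.T + np.array([1, 2, 3])
        assert kabsch_superpose(moved, pts).rmsd < 1e-9

    def test_identity_on_identical_coords(self, rng):
        pts = rng.normal(size=(6, 3))
        result = kabsch_superpose(pts, pts)
        assert result.rmsd < 1e-12
        assert np.allclose(result.transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(result.transform.translation, 0.0, atol=1e-9)

    def test_single_point_displacement_closed_form(self):
        # a symmetric square, one point pulled 1 Å out of plane: the optimal
        # rmsd is checked against a dense rotation-grid oracle and bounded by
        # the no-rotation value sqrt(1Å² / 4 points) = 0.5 Å
        fixed = np.array(
            [[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]], dtype=float
        )
        moving = fixed.copy()
        moving[0, 2] += 1.0  # displace perpendicular to the plane
        rmsd = kabsch_superpose(moving, fixed).rmsd
        oracle = _grid_min_rmsd(moving, fixed)
        assert rmsd == pytest.approx(oracle, abs=1e-3)
        assert rmsd <= 0.5 + 1e-9  # no worse than centroid-only fit

    def test_grid_oracle_random_small_sets(self, rng):
        for _ in range(2):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            kab = kabsch_superpose(a, b).rmsd
            grid = _grid_min_rmsd(a, b)
            assert kab <= grid + 1e-9  # Kabsch is the true minimum
            assert grid - kab < 1e-3  # and the 2° grid comes this close

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_warns_but_returns(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.warns(UserWarning, match="degenerate"):
            result = kabsch_superpose(line, line + np.array([0, 1, 0]))
        assert result.rmsd < 1e-9


def _grid_min_rmsd(moving, fixed, step_deg=2.0):
    """Brute-force oracle: dense ZYZ Euler grid + centroid translation."""
    mc, fc = moving - moving.mean(0), fixed - fixed.mean(0)
    a_grid = np.deg2rad(np.arange(0, 360, step_deg))
    b_grid = np.deg2rad(np.arange(0, 180 + step_deg, step_deg))
    c_grid = np.deg2rad(np.arange(0, 360, step_deg))
    cc, sc = np.cos(c_grid), np.sin(c_grid)
    rz2 = np.zeros((len(c_grid), 3, 3))
    rz2[:, 0, 0], rz2[:, 0, 1] = cc, -sc
    rz2[:, 1, 0], rz2[:, 1, 1] = sc, cc
    rz2[:, 2, 2] = 1.0
    best = np.inf
    for a in a_grid:
        ca, sa = np.cos(a), np.sin(a)
        rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        for b in b_grid:
            cb, sb = np.cos(b), np.sin(b)
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            r12 = ry @ rz1
            moved = np.einsum("kij,jn->kin", rz2 @ r12, mc.T)  # (k, 3, N)
            diff = moved - fc.T[None]
            rmsds = np.sqrt(np.mean(np.sum(diff**2, axis=1), axis=1))
            best = min(best, float(rmsds.min()))
    return best


class TestRmsdPaired:
    def test_identical_zero(self, rng):
        pts = rng.normal(size=(8, 3))
        assert rmsd_paired(pts, pts) == 0.0

    def test_translation_magnitude_without_superposition(self, rng):
        pts = rng.normal(size=(8, 3))
        shifted = pts + np.array([3.0, 4.0, 0.0])
        assert rmsd_paired(pts, shifted) == pytest.approx(5.0)
        assert rmsd_paired(pts, shifted, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            rmsd_paired(np.zeros((4, 3)), np.zeros((5, 3)))


class TestTMScore:
    def test_identity_is_one(self, rng):
        pts = rng.normal(size=(30, 3)) * 10
        assert tm_score(pts, pts) == pytest.approx(1.0, abs=1e-6)

    def test_rigid_motion_invariance(self, rng):
        pts = np.cumsum(rng.normal(size=(40, 3)), axis=0) * 2
        rot = random_rotation(rng)
        moved = pts @ rot.T + np.array([5.0, -3.0, 8.0])
        assert tm_score(moved, pts) == pytest.approx(1.0, abs=1e-6)

    def test_random_chains_score_low(self, rng):
        scores = [
            tm_score(
                np.cumsum(rng.normal(size=(100, 3)), axis=0) * 2.5,
                np.cumsum(rng.normal(size=(100, 3)), axis=0) * 2.5,
            )
            for _ in range(5)
        ]
        assert np.mean(scores) < 0.3

    def test_distance_monotonicity(self, rng):
        # doubling every deviation lowers per-pair terms, hence the score
        ref = np.cumsum(rng.normal(size=(30, 3)), axis=0) * 2
        noise = rng.normal(size=(30, 3))
        near = tm_score(ref + 0.5 * noise, ref)
        far = tm_score(ref + 2.0 * noise, ref)
        assert far < near

    def test_short_norm_length_rejected(self, rng):
        pts = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            tm_score(pts, pts, norm_length=15)


class TestGDT:
    def test_identity_is_one(self, rng):
        pts = rng.normal(size=(25, 3)) * 8
        assert gdt_ts(pts, pts) == pytest.approx(1.0)

    def test_uniform_3A_displacement_scores_half(self):
        # all residues exactly 3 Å off after best fit: fails 1 and 2, passes 4 and 8
        ref = np.array([[float(i), 0.0, 0.0] for i in range(20)])
        model = ref + np.array([0.0, 0.0, 3.0])
        # direct threshold counting oracle on the raw (translation-removed) fit
        assert gdt_ts(model, ref) == pytest.approx(1.0)  # translation removed by fit
        # break the fit: alternate +3/-3 so no rigid motion can help
        model2 = ref.copy()
        model2[::2, 2] += 3.0
        model2[1::2, 2] -= 3.0
        score = gdt_ts(model2, ref)
        assert 0.5 <= score <= 0.75  # 4 and 8 Å thresholds pass fully

    def test_all_beyond_8A_is_zero(self):
        ref = np.array([[float(i) * 3, 0.0, 0.0] for i in range(10)])
        model = ref.copy()
        model[:, 2] = np.where(np.arange(10) % 2 == 0, 50.0, -50.0)
        assert gdt_ts(model, ref) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = np.cumsum(rng.normal(size=(20, 3)), axis=0) * 2
        noisy = pts + rng.normal(scale=1.0, size=pts.shape)
        rot = random_rotation(rng)
        assert gdt_ts(noisy @ rot.T + 7.0, pts) == pytest.approx(
            gdt_ts(noisy, pts), abs=1e-9
        )


class TestMCC:
    def test_perfect_prediction(self):
        u = set(range(20))
        a = set(range(5))
        assert mcc_sets(a, a, u) == pytest.approx(1.0)

    def test_complement_prediction(self):
        u = set(range(10))
        a = set(range(4))
        assert mcc_sets(u - a, a, u) == pytest.approx(-1.0)

    def test_hand_computed_confusion_matrix(self):
        # TP=6, FP=2, FN=2, TN=10 -> (60-4)/sqrt(8*8*12*12) = 56/96
        u = set(range(20))
        actual = set(range(8))
        predicted = set(range(6)) | {8, 9}
        assert mcc_sets(predicted, actual, u) == pytest.approx(56 / 96, abs=1e-9)
        assert mcc_sets(predicted, actual, u) == pytest.approx(0.583, abs=1e-3)

    def test_symmetry(self, rng):
        u = set(range(30))
        a = set(rng.choice(30, size=10, replace=False).tolist())
        b = set(rng.choice(30, size=12, replace=False).tolist())
        assert mcc_sets(a, b, u) == pytest.approx(mcc_sets(b, a, u))

    def test_empty_marginal_returns_zero(self):
        u = set(range(5))
        assert mcc_sets(set(), set(range(2)), u) == 0.0

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            mcc_sets({99}, {1}, set(range(5)))


class TestRigidTransform:
    def test_reflection_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]), translation=np.zeros(3))

    def test_compose_matches_sequential_application(self, rng):
        r1, r2 = random_rotation(rng), random_rotation(rng)
        t1 = RigidTransform(rotation=r1, translation=rng.normal(size=3))
        t2 = RigidTransform(rotation=r2, translation=rng.normal(size=3))
        pts = rng.normal(size=(5, 3))
        assert np.allclose(t1.compose(t2).apply(pts), t1.apply(t2.apply(pts)))
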