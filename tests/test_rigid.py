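import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from bsfinder.alignment import SegmentAlignment
from bsfinder.candidates import CandidateSite
from bsfinder.rigid import (
    DegenerateGeometryError,
    MatchParameters,
    RigidTransform,
    bottleneck_under_transform,
    find_matching_subsegments,
    kabsch_superpose,
    refine_transform,
)


def random_transform(rng):
    return RigidTransform(
        Rotation.random(random_state=int(rng.integers(2**31))).as_matrix(),
        rng.uniform(-10, 10, 3),
    )


def candidate_from_pairs(n):
    cols = [(i, i) for i in range(n)]
    seg = SegmentAlignment(columns=cols, score=n, gap_before=[0] * (n + 1))
    return CandidateSite(segment=seg, surface_fraction_a=1.0, surface_fraction_b=1.0,
                         n_pairs=n, span=(0, n))


def rmsd(A, B, tr):
    return float(np.sqrt(np.mean(np.sum((A - tr.apply(B)) ** 2, axis=1))))


class TestKabsch:
    def test_identity(self):
        A = np.random.default_rng(0).normal(size=(5, 3))
        tr = kabsch_superpose(A, A)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-9)

    def test_recovers_exact_congruence(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 3)) * 4
        true = random_transform(rng)
        B = true.inverse().apply(A)  # so that true maps B back onto A
        tr = kabsch_superpose(A, B)
        np.testing.assert_allclose(tr.apply(B), A, atol=1e-8)

    def test_matches_numeric_least_squares(self):
        # independent oracle: direct minimisation over a quaternion
        A = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        B = np.array([[0.0, 0, 0], [1.1, 0, 0], [0, 1, 0]])
        tr = kabsch_superpose(A, B)

        def objective(x):
            q = x[:4] / np.linalg.norm(x[:4])
            R = Rotation.from_quat(q).as_matrix()
            return np.sum((A - B @ R.T - x[4:]) ** 2)

        best = min(
            (minimize(objective, np.concatenate([q0, [0, 0, 0]]), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
             for q0 in (np.array([0, 0, 0, 1.0]), np.array([0.5, 0.5, 0.5, 0.5]))),
            key=lambda r: r.fun,
        )
        got = np.sum((A - tr.apply(B)) ** 2)
        assert got == pytest.approx(best.fun, abs=1e-6)

    def test_degenerate_inputs(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_beats_random_transforms(self):
        rng = np.random.default_rng(6)
        A = rng.normal(size=(10, 3)) * 5
        B = rng.normal(size=(10, 3)) * 5
        tr = kabsch_superpose(A, B)
        base = rmsd(A, B, tr)
        for _ in range(1000):
            assert base <= rmsd(A, B, random_transform(rng)) + 1e-12


class TestBottleneck:
    def test_trivials(self):
        A = np.random.default_rng(0).normal(size=(4, 3))
        ident = RigidTransform.identity()
        assert bottleneck_under_transform(ident, A, A) == 0.0
        B = A.copy()
        B[2] += [0, 0, 2.0]
        assert bottleneck_under_transform(ident, A, B) == pytest.approx(2.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = rng.normal(size=(5, 3)) * 3
            B = rng.normal(size=(5, 3)) * 3
            tr = random_transform(rng)
            expected = max(np.linalg.norm(a - tr.apply(b[None])[0]) for a, b in zip(A, B))
            assert bottleneck_under_transform(tr, A, B) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bottleneck_under_transform(RigidTransform.identity(), np.zeros((2, 3)), np.zeros((3, 3)))


class TestRigidTransformInvariants:
    def test_rejects_improper_rotation(self):
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(refl, np.zeros(3))

    def test_preserves_distances(self):
        rng = np.random.default_rng(3)
        tr = random_transform(rng)
        P = rng.normal(size=(6, 3)) * 4
        Q = tr.apply(P)
        np.testing.assert_allclose(
            np.linalg.norm(P[:, None] - P[None], axis=2),
            np.linalg.norm(Q[:, None] - Q[None], axis=2),
            atol=1e-9,
        )

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(4)
        tr = random_transform(rng)
        P = rng.normal(size=(5, 3))
        np.testing.assert_allclose(tr.inverse().apply(tr.apply(P)), P, atol=1e-9)


class TestRefine:
    def test_zero_bottleneck_returned_unchanged(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 3)) * 3
        tr = kabsch_superpose(A, A)
        out = refine_transform(tr, A, A, MatchParameters())
        assert bottleneck_under_transform(out, A, A) < 1e-12

    def test_never_worse_than_seed(self):
        rng = np.random.default_rng(8)
        params = MatchParameters()
        for _ in range(10):
            A = rng.normal(size=(6, 3)) * 4
            B = A + rng.normal(0, 0.5, size=A.shape)
            seed = kabsch_superpose(A, B)
            out = refine_transform(seed, A, B, params)
            assert bottleneck_under_transform(out, A, B) <= bottleneck_under_transform(seed, A, B) + 1e-9

    def test_translation_refinement_two_pairs(self):
        # least-squares translation is the centroid shift; the bottleneck
        # optimum is the midpoint of the two residuals -- refinement must
        # get within eps*d of it
        params = MatchParameters(d=1.5, eps=0.1, min_pairs=2)
        A = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        B = np.array([[0.0, 0.8, 0], [10.0, -0.4, 0]])
        seed = RigidTransform.identity()
        out = refine_transform(seed, A, B, params)
        best_b = 0.6  # optimal: shift y by 0.2 -> residuals +/-0.6
        assert bottleneck_under_transform(out, A, B) <= best_b + params.eps * params.d + 1e-6


class TestFindMatchingSubsegments:
    def test_congruent_copy_full_window(self):
        rng = np.random.default_rng(10)
        A = rng.normal(size=(20, 3)) * 5
        tr = random_transform(rng)
        B = tr.inverse().apply(A)
        res = find_matching_subsegments(candidate_from_pairs(20), A, B, MatchParameters())
        assert len(res) == 1
        assert res[0].subsegment == (0, 20)
        assert res[0].bottleneck < 1e-6

    def test_displaced_tail_is_excluded(self):
        rng = np.random.default_rng(12)
        A = rng.normal(size=(20, 3)) * 5
        B = A.copy()
        B[15:] += 10.0  # last 5 pairs displaced far away
        res = find_matching_subsegments(candidate_from_pairs(20), A, B, MatchParameters())
        assert len(res) == 1
        assert res[0].subsegment == (0, 15)

    def test_jittered_copy_accepted(self):
        rng = np.random.default_rng(13)
        A = rng.normal(size=(20, 3)) * 5
        tr = random_transform(rng)
        B = tr.inverse().apply(A) + rng.normal(0, 0.2, size=(20, 3))
        res = find_matching_subsegments(candidate_from_pairs(20), A, B, MatchParameters())
        assert len(res) == 1
        assert res[0].n_pairs == 20
        assert res[0].bottleneck <= 1.65

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(14)
        A = rng.normal(size=(8, 3)) * 4
        B = A + rng.normal(0, 0.3, size=A.shape)
        tr_ab = kabsch_superpose(A, B)
        tr_ba = kabsch_superpose(B, A)
        np.testing.assert_allclose(tr_ab.rotation, tr_ba.inverse().rotation, atol=1e-6)
        b_ab = bottleneck_under_transform(tr_ab, A, B)
        b_ba = bottleneck_under_transform(tr_ba, B, A)
        assert b_ab == pytest.approx(b_ba, abs=1e-6)

    def test_contract_on_planted_instances(self):
        # scaled-down version of the acceptance check: planted transform
        # achieves bottleneck <= d, so a window must be accepted at
        # bottleneck <= (1+eps) d
        rng = np.random.default_rng(15)
        params = MatchParameters(d=1.5, eps=0.1, min_pairs=5)
        for _ in range(50):
            n = int(rng.integers(5, 9))
            A = rng.uniform(-5, 5, size=(n, 3))
            tr = random_transform(rng)
            noise = rng.normal(size=(n, 3))
            noise *= (rng.uniform(0, params.d, n) / np.linalg.norm(noise, axis=1))[:, None]
            B = tr.inverse().apply(A + noise)  # planted bottleneck <= d
            res = find_matching_subsegments(
                candidate_from_pairs(n), A, B,
                MatchParameters(d=params.d, eps=params.eps, min_pairs=n),
            )
            assert res, "window admitting bottleneck <= d was not matched"
            assert res[0].bottleneck <= (1 + params.eps) * params.d + 1e-9
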