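"""Approximate bottleneck rigid matching of candidate windows.

Given a candidate window of matched atom pairs, the question is whether one
proper rigid transformation brings every pair within a distance threshold
``d``.  Deciding this exactly is expensive, so the accepted contract is the
usual (1+eps) relaxation: whenever some transform achieves bottleneck
(maximum per-pair) distance <= d, a transform with bottleneck <= (1+eps)d
is returned, with eps = 0.1 by default.

The search is seeded with the Kabsch least-squares superposition.  If the
seed's bottleneck already meets (1+eps)d the window is accepted outright.
Otherwise rotations are sampled on an axis-angle grid around the seed with
angular step eps*d / r_max (r_max = largest pair radius about the centroid,
so one step changes no point by more than eps*d), and for every sampled
rotation the bottleneck-optimal translation is computed exactly: it is the
center of the minimal enclosing ball of the residual vectors a_i - R b_i.
The gate for entering refinement is sound: bottleneck(opt) <= d implies
RMSD(opt) <= d and hence RMSD(Kabsch) <= d, so windows skipped for having
Kabsch RMSD > d can never violate the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .candidates import CandidateSite
from .structures import ProteinStructure

__all__ = [
    "RigidTransform",
    "MatchParameters",
    "MatchResult",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "bottleneck_under_transform",
    "refine_transform",
    "find_matching_subsegments",
]


class DegenerateGeometryError(ValueError):
    """Point sets too degenerate (coincident/collinear) for superposition."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation: x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix_3x4(self) -> list[list[float]]:
        """Row-major (rotation | translation), for report serialisation."""
        m = np.hstack([self.rotation, self.translation[:, None]])
        return [[round(float(v), 6) for v in row] for row in m]


@dataclass(frozen=True)
class MatchParameters:
    """Distance threshold d (A), relaxation eps and minimum window size."""

    d: float = 1.5
    eps: float = 0.1
    min_pairs: int = 15

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        if not 0 < self.eps < 1:
            raise ValueError("eps must lie in (0, 1)")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")

    @property
    def accept(self) -> float:
        return (1.0 + self.eps) * self.d


@dataclass
class MatchResult:
    """An accepted window: contiguous candidate columns plus the transform."""

    subsegment: tuple[int, int]  # [start, stop) in the candidate's columns
    transform: RigidTransform
    pair_distances: np.ndarray
    n_pairs: int
    bottleneck: float = field(init=False)

    def __post_init__(self) -> None:
        self.bottleneck = float(np.max(self.pair_distances)) if len(self.pair_distances) else 0.0


def kabsch_superpose(pointsA: np.ndarray, pointsB: np.ndarray) -> RigidTransform:
    """Least-squares proper-rotation superposition of B onto A.

    Classic Kabsch: the rotation comes from the SVD of the cross-covariance
    of the centred point sets with the reflection branch suppressed.
    """
    A = np.asarray(pointsA, dtype=float)
    B = np.asarray(pointsB, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(A) < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    cA, cB = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - cA, B - cB
    if np.linalg.matrix_rank(np.vstack([A0, B0]), tol=1e-8) < 2:
        raise DegenerateGeometryError("points are coincident or collinear")
    rot, _ = Rotation.align_vectors(A0, B0)
    R = rot.as_matrix()
    return RigidTransform(R, cA - R @ cB)


def bottleneck_under_transform(
    transform: RigidTransform, pairsA: np.ndarray, pairsB: np.ndarray
) -> float:
    """max_i |A_i - T(B_i)|."""
    A = np.asarray(pairsA, dtype=float)
    B = np.asarray(pairsB, dtype=float)
    if A.shape != B.shape:
        raise ValueError("paired point sets must have equal shapes")
    if len(A) == 0:
        raise ValueError("need at least one pair")
    return float(np.max(np.linalg.norm(A - transform.apply(B), axis=1)))


def _min_enclosing_ball_center(points: np.ndarray, iters: int = 150) -> np.ndarray:
    """Badoiu-Clarkson iteration; center error shrinks as radius/k.

    150 iterations put the center within ~1% of the ball radius of the
    optimum — well inside the eps*d slack the caller works with.
    """
    c = points.mean(axis=0)
    for k in range(1, iters + 1):
        far = points[int(np.argmax(np.einsum("ij,ij->i", points - c, points - c)))]
        c = c + (far - c) / (k + 1)
    return c


def _meb_centers_batch(res: np.ndarray, iters: int = 150) -> np.ndarray:
    """Badoiu-Clarkson centers for a batch of residual sets, shape (m, n, 3)."""
    m = res.shape[0]
    rows = np.arange(m)
    c = res.mean(axis=1)
    for k in range(1, iters + 1):
        d2 = np.einsum("mnk,mnk->mn", res - c[:, None, :], res - c[:, None, :])
        far = res[rows, np.argmax(d2, axis=1)]
        c = c + (far - c) / (k + 1)
    return c


def _kabsch_raw(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kabsch rotation/translation without object construction (hot path).

    Direct 3x3 SVD with the reflection branch suppressed.
    """
    cA, cB = A.mean(axis=0), B.mean(axis=0)
    H = (B - cB).T @ (A - cA)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cA - R @ cB


def _rotation_samples(seed_R: np.ndarray, step: float, n_axes: int, max_steps: int) -> np.ndarray:
    """Axis-angle grid around a seed rotation, shape (m, 3, 3); seed first."""
    # Fibonacci-sphere axes: roughly uniform directions, deterministic
    k = np.arange(n_axes)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_axes
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    axes = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    steps = step * np.arange(1, max_steps + 1)
    rotvecs = (axes[:, None, :] * steps[None, :, None]).reshape(-1, 3)
    perturbed = Rotation.from_rotvec(rotvecs).as_matrix() @ seed_R
    return np.concatenate([seed_R[None], perturbed], axis=0)


def _refine_raw(
    seed_R: np.ndarray,
    seed_t: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    params: MatchParameters,
    n_axes: int = 12,
    max_steps: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch rotation sampling + exact bottleneck translations; returns
    (R, t, per-pair distances) of the best transform found (never worse
    than the seed)."""
    seed_d = np.linalg.norm(A - B @ seed_R.T - seed_t, axis=1)
    best = (seed_R, seed_t, seed_d)
    best_b = float(seed_d.max())
    if best_b == 0.0:
        return best
    r_max = float(np.max(np.linalg.norm(B - B.mean(axis=0), axis=1)))
    step = params.eps * params.d / max(r_max, 1e-6)
    Rs = _rotation_samples(seed_R, step, n_axes, max_steps)
    res = A[None, :, :] - np.einsum("mij,nj->mni", Rs, B)
    centers = _meb_centers_batch(res)
    dists = np.linalg.norm(res - centers[:, None, :], axis=2)
    bott = dists.max(axis=1)
    i = int(np.argmin(bott))
    if bott[i] < best_b:
        best = (Rs[i], centers[i], dists[i])
    return best


def refine_transform(
    seed: RigidTransform,
    pairsA: np.ndarray,
    pairsB: np.ndarray,
    params: MatchParameters,
    n_axes: int = 12,
    max_steps: int = 3,
) -> RigidTransform:
    """Bottleneck refinement around a seed transform.

    Samples rotations around the seed (angular step eps*d / r_max) and pairs
    each with its exact bottleneck-optimal translation (minimal-enclosing-
    ball center of the residuals).  Returns the best transform found; never
    worse than the seed.
    """
    A = np.asarray(pairsA, dtype=float)
    B = np.asarray(pairsB, dtype=float)
    R, t, _ = _refine_raw(seed.rotation, seed.translation, A, B, params, n_axes, max_steps)
    return RigidTransform(R, t)


def _window_test_raw(
    A: np.ndarray, B: np.ndarray, params: MatchParameters
) -> tuple[bool, tuple[np.ndarray, np.ndarray] | None, np.ndarray | None]:
    """Accept a window iff a transform with bottleneck <= (1+eps)d is found.

    Returns raw (R, t) arrays; callers wrap accepted ones in RigidTransform.
    """
    try:
        R, t = _kabsch_raw(A, B)
    except Exception:
        return False, None, None
    dists = np.linalg.norm(A - B @ R.T - t, axis=1)
    if float(dists.max()) <= params.accept + 1e-12:
        return True, (R, t), dists
    rmsd = float(np.sqrt(np.mean(dists**2)))
    if rmsd <= params.d:  # optimal bottleneck <= d forces this, so the gate is safe
        R2, t2, dists2 = _refine_raw(R, t, A, B, params)
        if float(dists2.max()) <= params.accept + 1e-12:
            return True, (R2, t2), dists2
    return False, None, None


def _window_test(
    A: np.ndarray, B: np.ndarray, params: MatchParameters
) -> tuple[bool, RigidTransform | None, np.ndarray | None]:
    ok, rt, dists = _window_test_raw(A, B, params)
    if not ok:
        return False, None, None
    return True, RigidTransform(*rt), dists


def find_matching_subsegments(
    candidate: CandidateSite,
    structA: ProteinStructure | np.ndarray,
    structB: ProteinStructure | np.ndarray,
    params: MatchParameters = MatchParameters(),
) -> list[MatchResult]:
    """Maximal contiguous windows of a candidate matchable by one transform.

    Grow-and-slide search: every window of exactly ``min_pairs`` columns is
    tested; an accepted seed window is greedily extended right then left
    while the (1+eps)d guarantee holds.  Overlapping accepted windows are
    merged when their union also passes the test.
    """
    coordsA = structA if isinstance(structA, np.ndarray) else structA.coords()
    coordsB = structB if isinstance(structB, np.ndarray) else structB.coords()
    cols = candidate.segment.columns
    n = len(cols)
    if n < params.min_pairs:
        return []
    A = coordsA[[a for a, _ in cols]]
    B = coordsB[[b for _, b in cols]]

    # rigid transforms preserve distances, so a window can only qualify if
    # its endpoint span agrees between the two sides within 2(1+eps)d —
    # a cheap vectorised filter that rejects most decoy seeds outright
    w = params.min_pairs
    spanA = np.linalg.norm(A[w - 1 :] - A[: n - w + 1], axis=1)
    spanB = np.linalg.norm(B[w - 1 :] - B[: n - w + 1], axis=1)
    seed_ok = np.abs(spanA - spanB) <= 2.0 * params.accept
    h = w // 2
    midA = np.linalg.norm(A[h : h + n - w + 1] - A[: n - w + 1], axis=1)
    midB = np.linalg.norm(B[h : h + n - w + 1] - B[: n - w + 1], axis=1)
    seed_ok &= np.abs(midA - midB) <= 2.0 * params.accept

    windows: list[tuple[int, int]] = []
    s = 0
    while s + w <= n:
        e = s + w
        if not seed_ok[s]:
            s += 1
            continue
        ok, _, _ = _window_test_raw(A[s:e], B[s:e], params)
        if not ok:
            s += 1
            continue
        while e < n and _window_test_raw(A[s : e + 1], B[s : e + 1], params)[0]:
            e += 1
        s2 = s
        while s2 > 0 and _window_test_raw(A[s2 - 1 : e], B[s2 - 1 : e], params)[0]:
            s2 -= 1
        windows.append((s2, e))
        # resume at the first seed able to reach past the accepted window
        s = max(s + 1, e - w + 1)

    # drop windows contained in another; merge overlapping ones when the
    # union still satisfies the guarantee
    windows = sorted(set(windows))
    kept: list[tuple[int, int]] = []
    for w in windows:
        if any(o[0] <= w[0] and w[1] <= o[1] and o != w for o in windows):
            continue
        kept.append(w)
    merged: list[tuple[int, int]] = []
    for win in kept:
        if merged and win[0] < merged[-1][1]:
            u = (merged[-1][0], max(merged[-1][1], win[1]))
            if _window_test_raw(A[u[0] : u[1]], B[u[0] : u[1]], params)[0]:
                merged[-1] = u
                continue
        merged.append(win)

    out: list[MatchResult] = []
    for s, e in merged:
        ok, tr, dists = _window_test(A[s:e], B[s:e], params)
        if not ok:  # pragma: no cover - merged windows were just verified
            continue
        out.append(MatchResult(subsegment=(s, e), transform=tr, pair_distances=dists, n_pairs=e - s))
    return out
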