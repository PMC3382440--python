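"""Steric-overlap veto for matching transforms.

A transform that superposes two candidate sites may also drive the bodies
of the two proteins into each other; such transforms are rejected.  Both
structures (the second one transformed) are labelled on ONE shared lattice
with the same rules as surface detection.  With X the lattice points
interior to both proteins and X1, X2 the interior counts of each protein
alone, the pair is declared non-overlapping iff X <= 0.05 * min(X1, X2);
the comparison is non-strict, so X exactly at the bound is not a veto.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rigid import RigidTransform
from .structures import ProteinStructure
from .surface import INTERIOR, VoxelGrid, build_labeled_grid

__all__ = ["OverlapResult", "check_overlap", "check_overlap_fast"]


@dataclass(frozen=True)
class OverlapResult:
    """Interior-point counts and the veto verdict."""

    X: int
    X1: int
    X2: int
    ratio_threshold: float = 0.05

    @property
    def overlapping(self) -> bool:
        return self.X > self.ratio_threshold * min(self.X1, self.X2)


def check_overlap_fast(
    gridA: VoxelGrid,
    coordsB_transformed: np.ndarray,
    X2: int,
    step: float = 1.0,
    protein_radius: float = 2.0,
    ratio_threshold: float = 0.05,
) -> OverlapResult:
    """Veto check against a precomputed grid of protein A.

    Labels B only on the intersection of the two padded bounding boxes
    (shared interior points can exist nowhere else), reads A's interior
    labels from ``gridA`` and takes X2 from B's own grid, computed once by
    the caller.  Lattices anchored at integer coordinates make A's labels
    directly reusable; X2 shifts by at most voxel-discretisation noise
    relative to the shared-lattice value, far below the 5% criterion.
    """
    X1 = gridA.n_interior
    loA = gridA.origin
    hiA = gridA.origin + (np.array(gridA.labels.shape) - 1) * step
    loB = np.floor(coordsB_transformed.min(axis=0) / step) * step - 2 * step
    hiB = np.ceil(coordsB_transformed.max(axis=0) / step) * step + 2 * step
    lo = np.maximum(loA, loB)
    hi = np.minimum(hiA, hiB)
    if np.any(lo > hi):
        return OverlapResult(X=0, X1=X1, X2=X2, ratio_threshold=ratio_threshold)
    # B's interior labels on the intersection window (one-voxel margin so
    # the six-neighbour rule is evaluated exactly)
    shape = tuple(int(round((hi[k] - lo[k]) / step)) + 3 for k in range(3))
    origin = lo - step
    gridB = build_labeled_grid(
        coordsB_transformed, step, protein_radius, pad=protein_radius + step,
        origin=origin, shape=shape,
    )
    intB = gridB.labels == INTERIOR
    idx = np.argwhere(intB)
    if len(idx) == 0:
        return OverlapResult(X=0, X1=X1, X2=X2, ratio_threshold=ratio_threshold)
    pts = origin + idx * step
    ai = np.rint((pts - gridA.origin) / step).astype(int)
    inside = np.all((ai >= 0) & (ai < np.array(gridA.labels.shape)), axis=1)
    ai = ai[inside]
    X = int(np.count_nonzero(gridA.labels[ai[:, 0], ai[:, 1], ai[:, 2]] == INTERIOR))
    return OverlapResult(X=X, X1=X1, X2=X2, ratio_threshold=ratio_threshold)


def check_overlap(
    structA: ProteinStructure | np.ndarray,
    structB: ProteinStructure | np.ndarray,
    transform: RigidTransform,
    step: float = 1.0,
    protein_radius: float = 2.0,
    pad: float = 4.0,
    ratio_threshold: float = 0.05,
) -> OverlapResult:
    """Label both proteins on a shared lattice and apply the overlap rule.

    The lattice is anchored to the union bounding box of A and transformed
    B, so "interior for both proteins" refers to one common set of points.
    """
    coordsA = structA if isinstance(structA, np.ndarray) else structA.coords()
    coordsB = structB if isinstance(structB, np.ndarray) else structB.coords()
    coordsBT = transform.apply(coordsB)

    both = np.vstack([coordsA, coordsBT])
    origin = np.floor(both.min(axis=0) / step) * step - pad
    span = both.max(axis=0) + pad - origin
    shape = tuple(int(np.ceil(s / step)) + 1 for s in span)

    gridA = build_labeled_grid(coordsA, step, protein_radius, pad, origin=origin, shape=shape)
    gridB = build_labeled_grid(coordsBT, step, protein_radius, pad, origin=origin, shape=shape)

    intA = gridA.labels == INTERIOR
    intB = gridB.labels == INTERIOR
    return OverlapResult(
        X=int(np.count_nonzero(intA & intB)),
        X1=int(np.count_nonzero(intA)),
        X2=int(np.count_nonzero(intB)),
        ratio_threshold=ratio_threshold,
    )
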