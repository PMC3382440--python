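"""Surface-exposure filtering of conserved segments.

A window of a conserved segment qualifies as a candidate binding site when
it has at least 15 matched atom pairs and, on each protein separately, at
least 2/3 of the window's matched atoms are surface atoms.  Only maximal
qualifying windows are emitted: any qualifying window is contained in some
reported candidate, and the rigid-matching stage performs its own
subsegment search inside each candidate, so no final output is lost to this
de-duplication.

Gap columns recorded by ``matched_columns`` do not count toward the pair
count or the surface-fraction denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import SegmentAlignment, window_gap_count
from .surface import SurfaceAnnotation

__all__ = ["CandidateSite", "enumerate_candidates"]


@dataclass
class CandidateSite:
    """A maximal surface-exposed window of a conserved segment."""

    segment: SegmentAlignment  # matched columns of the window, gap annotations kept
    surface_fraction_a: float
    surface_fraction_b: float
    n_pairs: int
    span: tuple[int, int]  # window [start, stop) in the parent matched segment


def _qualifying_spans(
    okA: np.ndarray, okB: np.ndarray, min_pairs: int, min_fraction: float
) -> list[tuple[int, int]]:
    """Maximal windows [s, e) with e-s >= min_pairs and both fractions >= min_fraction."""
    n = len(okA)
    if n < min_pairs:
        return []
    ca = np.concatenate([[0], np.cumsum(okA)])
    cb = np.concatenate([[0], np.cumsum(okB)])
    spans: list[tuple[int, int]] = []
    # small tolerance so e.g. 10/15 against 2/3 compares exactly
    eps = 1e-12
    for s in range(n - min_pairs + 1):
        lengths = np.arange(min_pairs, n - s + 1)
        ends = s + lengths
        fa = (ca[ends] - ca[s]) / lengths
        fb = (cb[ends] - cb[s]) / lengths
        ok = (fa >= min_fraction - eps) & (fb >= min_fraction - eps)
        if not ok.any():
            continue
        e = int(ends[np.flatnonzero(ok)[-1]])  # longest qualifying end for this start
        spans.append((s, e))
    # drop windows contained in an earlier (smaller-start) qualifying window
    maximal: list[tuple[int, int]] = []
    best_e = -1
    for s, e in spans:
        if e > best_e:
            maximal.append((s, e))
            best_e = e
    return maximal


def enumerate_candidates(
    segment: SegmentAlignment,
    surfA: SurfaceAnnotation | None,
    surfB: SurfaceAnnotation | None,
    min_pairs: int = 15,
    min_fraction: float = 2.0 / 3.0,
) -> list[CandidateSite]:
    """Maximal candidate windows of a matched-columns segment.

    ``surfA`` / ``surfB`` may be ``None`` to exempt that side from the
    surface test (used in site-search mode, where the query is a binding
    site and surface-exposed by construction).
    """
    if any(a is None or b is None for a, b in segment.columns):
        raise ValueError("enumerate_candidates expects a matched-columns segment")
    n = len(segment.columns)
    if n == 0:
        return []
    posA = np.array([a for a, _ in segment.columns], dtype=int)
    posB = np.array([b for _, b in segment.columns], dtype=int)
    okA = surfA.is_surface_atom[posA] if surfA is not None else np.ones(n, dtype=bool)
    okB = surfB.is_surface_atom[posB] if surfB is not None else np.ones(n, dtype=bool)

    out: list[CandidateSite] = []
    for s, e in _qualifying_spans(okA, okB, min_pairs, min_fraction):
        sub_gaps = None
        if segment.gap_before is not None:
            # interior gap structure of the window; flanking gaps excluded
            sub_gaps = [0] + segment.gap_before[s + 1 : e] + [0]
        sub = SegmentAlignment(
            columns=segment.columns[s:e],
            score=(e - s) - 2 * window_gap_count(segment, s, e),
            tokens_a=segment.tokens_a,
            tokens_b=segment.tokens_b,
            gap_before=sub_gaps,
        )
        out.append(
            CandidateSite(
                segment=sub,
                surface_fraction_a=float(np.mean(okA[s:e])),
                surface_fraction_b=float(np.mean(okB[s:e])),
                n_pairs=e - s,
                span=(s, e),
            )
        )
    return out
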