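"""Local alignment of atom-name sequences.

Binding sites tend to be conserved at the atom level: aligning the two
chains' atom-name sequences (N, CA, C, O, CB, ...) with Smith-Waterman
recovers them as high-scoring local segments.  The scoring is deliberately
rigid: a pair of identical atom names scores +1, a pair of different names
is forbidden outright (it acts as -infinity, so mismatched columns never
occur), and aligning an atom against a space costs -2.  Suboptimal,
mutually non-overlapping segments are enumerated Waterman-Eggert style by
zeroing out the matched cells of each reported alignment and realigning.

The dynamic program is vectorised row by row; with linear gap costs the
within-row dependency collapses to a running maximum, so each row is a few
numpy operations and the full matrix is kept only for traceback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import AtomSequence

__all__ = [
    "ScoringScheme",
    "SegmentAlignment",
    "smith_waterman",
    "suboptimal_alignments",
    "matched_columns",
]

_NEG = -1e18  # stands in for the forbidden-mismatch -infinity


@dataclass(frozen=True)
class ScoringScheme:
    """Match +1, mismatch forbidden, gap -2.

    The mismatch penalty is not a number here: mismatched columns are an
    disallowed transition in the DP, which avoids any overflow or precision
    questions a large negative constant would raise.
    """

    match_score: int = 1
    gap_score: int = -2

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.gap_score >= 0:
            raise ValueError("gap_score must be negative")


@dataclass
class SegmentAlignment:
    """A conserved segment: ordered columns pairing sequence positions.

    Matched columns carry both positions (with identical tokens); gap
    columns carry exactly one.  ``gap_before`` is populated by
    :func:`matched_columns`: entry k counts the gap columns of the original
    segment that precede matched column k (entry ``n`` counts trailing
    gaps), so any contiguous window of matched columns can recover its
    interior gap count.
    """

    columns: list[tuple[int | None, int | None]]
    score: int
    tokens_a: list[str] = field(default_factory=list)
    tokens_b: list[str] = field(default_factory=list)
    gap_before: list[int] | None = None

    @property
    def n_matched(self) -> int:
        return sum(1 for a, b in self.columns if a is not None and b is not None)

    @property
    def n_gaps(self) -> int:
        return sum(1 for a, b in self.columns if a is None or b is None)

    @property
    def gap_count(self) -> int:
        """Total gap columns: direct for raw segments, from annotations after
        :func:`matched_columns` has dropped the gap columns themselves."""
        if self.gap_before is not None:
            return int(sum(self.gap_before))
        return self.n_gaps

    def matched_pairs(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b in self.columns if a is not None and b is not None]

    def recomputed_score(self, scoring: ScoringScheme = ScoringScheme()) -> int:
        return self.n_matched * scoring.match_score + self.n_gaps * scoring.gap_score

    def validate(self) -> None:
        pa = [a for a, _ in self.columns if a is not None]
        pb = [b for _, b in self.columns if b is not None]
        if pa != sorted(set(pa)) or pb != sorted(set(pb)):
            raise ValueError("column positions must be strictly increasing")
        for a, b in self.columns:
            if a is None and b is None:
                raise ValueError("empty column")


def _encode(seqA: AtomSequence, seqB: AtomSequence) -> tuple[np.ndarray, np.ndarray]:
    vocab: dict[str, int] = {}
    for t in seqA.tokens:
        vocab.setdefault(t, len(vocab))
    for t in seqB.tokens:
        vocab.setdefault(t, len(vocab))
    ta = np.array([vocab[t] for t in seqA.tokens], dtype=np.int32)
    tb = np.array([vocab[t] for t in seqB.tokens], dtype=np.int32)
    return ta, tb


def _fill_matrix(
    ta: np.ndarray,
    tb: np.ndarray,
    scoring: ScoringScheme,
    forbidden: np.ndarray | None,
) -> np.ndarray:
    """Score matrix H of shape (n+1, m+1); H[i, j] ends at A[i-1], B[j-1]."""
    n, m = len(ta), len(tb)
    g = float(-scoring.gap_score)  # positive gap cost
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    jj = g * np.arange(1, m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        diag = np.where(tb == ta[i - 1], H[i - 1, :-1] + scoring.match_score, _NEG)
        if forbidden is not None:
            diag = np.where(forbidden[i - 1], _NEG, diag)
        up = H[i - 1, 1:] - g
        tmp = np.maximum(np.maximum(diag, up), 0.0)
        # left-gap chain H[i,j] = max(tmp[j], H[i,j-1] - g) via running max
        H[i, 1:] = np.maximum.accumulate(tmp + jj) - jj
    return H


def _traceback(
    H: np.ndarray,
    ta: np.ndarray,
    tb: np.ndarray,
    scoring: ScoringScheme,
    forbidden: np.ndarray | None,
    start: tuple[int, int],
) -> list[tuple[int | None, int | None]]:
    """Walk back from ``start``; preference diagonal > gap-in-B > gap-in-A."""
    g = float(-scoring.gap_score)
    i, j = start
    cols: list[tuple[int | None, int | None]] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        ok_diag = (
            ta[i - 1] == tb[j - 1]
            and (forbidden is None or not forbidden[i - 1, j - 1])
            and H[i, j] == H[i - 1, j - 1] + scoring.match_score
        )
        if ok_diag:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] - g:
            cols.append((i - 1, None))
            i -= 1
        elif H[i, j] == H[i, j - 1] - g:
            cols.append((None, j - 1))
            j -= 1
        else:  # pragma: no cover - would indicate a DP inconsistency
            raise AssertionError("traceback found no consistent predecessor")
    cols.reverse()
    # strip any leading/trailing gap columns (never part of an optimal local
    # alignment, but the preference order can pick them up on ties)
    while cols and (cols[0][0] is None or cols[0][1] is None):
        cols.pop(0)
    while cols and (cols[-1][0] is None or cols[-1][1] is None):
        cols.pop()
    return cols


def _best_alignment(
    seqA: AtomSequence,
    seqB: AtomSequence,
    scoring: ScoringScheme,
    ta: np.ndarray,
    tb: np.ndarray,
    forbidden: np.ndarray | None,
) -> SegmentAlignment:
    H = _fill_matrix(ta, tb, scoring, forbidden)
    flat = int(np.argmax(H))  # row-major: smallest (i, j) among ties
    i, j = divmod(flat, H.shape[1])
    if H[i, j] <= 0:
        return SegmentAlignment(columns=[], score=0,
                                tokens_a=seqA.tokens, tokens_b=seqB.tokens)
    cols = _traceback(H, ta, tb, scoring, forbidden, (i, j))
    seg = SegmentAlignment(
        columns=cols,
        score=int(round(H[i, j])),
        tokens_a=seqA.tokens,
        tokens_b=seqB.tokens,
    )
    assert seg.recomputed_score(scoring) == seg.score
    for a, b in seg.matched_pairs():
        assert seqA.tokens[a] == seqB.tokens[b]
    return seg


def smith_waterman(
    seqA: AtomSequence,
    seqB: AtomSequence,
    scoring: ScoringScheme = ScoringScheme(),
) -> SegmentAlignment:
    """Highest-scoring local alignment of two atom-name sequences.

    Returns an empty segment with score 0 when no legal column exists
    (mismatches being forbidden, two disjoint alphabets cannot align).
    """
    if len(seqA) == 0 or len(seqB) == 0:
        raise ValueError("cannot align an empty atom sequence")
    ta, tb = _encode(seqA, seqB)
    return _best_alignment(seqA, seqB, scoring, ta, tb, None)


def suboptimal_alignments(
    seqA: AtomSequence,
    seqB: AtomSequence,
    scoring: ScoringScheme = ScoringScheme(),
    min_matches: int = 15,
    max_segments: int = 100,
) -> list[SegmentAlignment]:
    """Enumerate mutually non-overlapping conserved segments.

    Waterman-Eggert iteration: report the best alignment, forbid its matched
    cells, realign; stop when the next alignment has fewer than
    ``min_matches`` matched columns or ``max_segments`` is reached.  Output
    is sorted by score descending (the iteration order guarantees this).
    """
    if min_matches < 1:
        raise ValueError("min_matches must be >= 1")
    if len(seqA) == 0 or len(seqB) == 0:
        raise ValueError("cannot align an empty atom sequence")
    ta, tb = _encode(seqA, seqB)
    forbidden = np.zeros((len(ta), len(tb)), dtype=bool)
    out: list[SegmentAlignment] = []
    for _ in range(max_segments):
        seg = _best_alignment(seqA, seqB, scoring, ta, tb, forbidden)
        if seg.n_matched < min_matches:
            break
        out.append(seg)
        for a, b in seg.matched_pairs():
            forbidden[a, b] = True
    return out


def matched_columns(segment: SegmentAlignment) -> SegmentAlignment:
    """Restrict a segment to its matched columns.

    Gap columns are dropped from ``columns`` but recorded in ``gap_before``
    so later stages can count the gaps interior to any window of matched
    columns.
    """
    cols: list[tuple[int | None, int | None]] = []
    gap_before: list[int] = []
    pending = 0
    for a, b in segment.columns:
        if a is None or b is None:
            pending += 1
        else:
            gap_before.append(pending)
            pending = 0
            cols.append((a, b))
    gap_before.append(pending)  # trailing gaps
    return SegmentAlignment(
        columns=cols,
        score=segment.score,
        tokens_a=segment.tokens_a,
        tokens_b=segment.tokens_b,
        gap_before=gap_before,
    )


def window_gap_count(segment: SegmentAlignment, start: int, stop: int) -> int:
    """Gap columns of the original segment interior to matched window [start, stop)."""
    if segment.gap_before is None:
        return 0
    return int(sum(segment.gap_before[start + 1 : stop]))
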