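import functools
import random

import numpy as np
import pytest

from bsfinder.alignment import (
    ScoringScheme,
    matched_columns,
    smith_waterman,
    suboptimal_alignments,
    window_gap_count,
)
from bsfinder.structures import AtomSequence

TOKENS = ["N", "CA", "C", "O", "CB", "CG1", "OG"]


def seq(tokens):
    return AtomSequence(tokens=list(tokens), atom_index=list(range(len(tokens))))


def brute_local_score(a, b, match=1, gap=-2):
    """Independent oracle: plain recursive local-alignment DP.

    Mismatches are simply never taken (the -infinity rule); written
    without the vectorised running-max trick used by the implementation.
    """

    @functools.lru_cache(maxsize=None)
    def h(i, j):
        if i == 0 or j == 0:
            return 0
        best = 0
        if a[i - 1] == b[j - 1]:
            best = max(best, h(i - 1, j - 1) + match)
        best = max(best, h(i - 1, j) + gap, h(i, j - 1) + gap)
        return best

    return max(h(i, j) for i in range(len(a) + 1) for j in range(len(b) + 1))


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (["N", "CA", "C", "O", "CB"], ["N", "CA", "C", "O", "CB"], 5),
        (["CA"], ["CB"], 0),
        (["N", "CA", "C", "O", "CB", "CG", "CD"], ["N", "CA", "C", "CB", "CG", "CD"], 4),
    ],
)
def test_smith_waterman_examples(a, b, expected):
    seg = smith_waterman(seq(a), seq(b))
    assert seg.score == expected
    assert brute_local_score(tuple(a), tuple(b)) == expected
    for pa, pb in seg.matched_pairs():
        assert a[pa] == b[pb]


def test_oracle_agreement_random_sequences():
    rng = random.Random(7)
    for _ in range(100):
        a = tuple(rng.choice(TOKENS) for _ in range(rng.randint(1, 12)))
        b = tuple(rng.choice(TOKENS) for _ in range(rng.randint(1, 12)))
        assert smith_waterman(seq(a), seq(b)).score == brute_local_score(a, b)


def test_score_recomputes_from_columns():
    rng = random.Random(3)
    for _ in range(50):
        a = [rng.choice(TOKENS) for _ in range(rng.randint(2, 15))]
        b = [rng.choice(TOKENS) for _ in range(rng.randint(2, 15))]
        sg = smith_waterman(seq(a), seq(b))
        assert sg.recomputed_score() == sg.score
        sg.validate()


def test_monotone_in_extension():
    rng = random.Random(11)
    for _ in range(30):
        a = [rng.choice(TOKENS) for _ in range(rng.randint(1, 10))]
        b = [rng.choice(TOKENS) for _ in range(rng.randint(1, 10))]
        base = smith_waterman(seq(a), seq(b)).score
        extra = [rng.choice(TOKENS) for _ in range(3)]
        assert smith_waterman(seq(a + extra), seq(b + extra)).score >= base


def test_suboptimal_finds_disjoint_repeats():
    rng = random.Random(5)
    motif1 = [rng.choice(TOKENS) for _ in range(20)]
    motif2 = [rng.choice(TOKENS) for _ in range(20)]
    # spacers from a disjoint alphabet so no accidental long matches occur
    spacer_a = ["XA"] * 10
    spacer_b = ["XB"] * 10
    a = spacer_a + motif1 + spacer_a + motif2 + spacer_a
    b = spacer_b + motif1 + spacer_b + motif2 + spacer_b
    segs = suboptimal_alignments(seq(a), seq(b), min_matches=15)
    assert len(segs) == 2
    assert all(s.n_matched == 20 for s in segs)
    assert segs[0].score >= segs[1].score
    cells = [set(s.matched_pairs()) for s in segs]
    assert not (cells[0] & cells[1])


def test_suboptimal_threshold_excludes_all():
    a = ["N", "CA", "C", "O"] * 3
    assert suboptimal_alignments(seq(a), seq(a), min_matches=13) == []


def test_single_shared_motif():
    rng = random.Random(9)
    motif = [rng.choice(TOKENS) for _ in range(15)]
    a = ["XA"] * 8 + motif + ["XA"] * 8
    b = ["XB"] * 8 + motif + ["XB"] * 8
    segs = suboptimal_alignments(seq(a), seq(b), min_matches=15)
    assert len(segs) == 1
    assert segs[0].n_matched == 15


def test_matched_columns_annotations():
    a = ["N", "CA", "C", "O", "CB", "CG", "CD"]
    b = ["N", "CA", "C", "CB", "CG", "CD"]
    sg = smith_waterman(seq(a), seq(b))
    m = matched_columns(sg)
    assert len(m.columns) == 6
    assert m.gap_count == 1
    assert sum(m.gap_before) == 1
    # the gap sits between matched columns 2 (C) and 3 (CB)
    assert window_gap_count(m, 0, 6) == 1
    assert window_gap_count(m, 3, 6) == 0

    all_match = smith_waterman(seq(a), seq(a))
    m2 = matched_columns(all_match)
    assert len(m2.columns) == 7 and m2.gap_count == 0


try:
    from hypothesis import given, settings, strategies as st

    token_lists = st.lists(st.sampled_from(TOKENS), min_size=1, max_size=10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=token_lists, b=token_lists)
    def test_property_score_matches_oracle(a, b):
        assert smith_waterman(seq(a), seq(b)).score == brute_local_score(tuple(a), tuple(b))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=token_lists, b=token_lists)
    def test_property_matched_columns_have_equal_tokens(a, b):
        sg = smith_waterman(seq(a), seq(b))
        assert all(a[i] == b[j] for i, j in sg.matched_pairs())
        assert sg.score >= 0
        assert sg.recomputed_score() == sg.score
except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass


def test_scoring_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(match_score=0)
    with pytest.raises(ValueError):
        ScoringScheme(gap_score=1)
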