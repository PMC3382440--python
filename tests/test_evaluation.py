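import warnings

import pytest

from bsfinder.evaluation import (
    EvalSummary,
    ReferenceSite,
    confirm_site,
    gap_histogram,
    precision_recall,
    read_reference_tsv,
)


class FakeReport:
    """Minimal stand-in carrying the fields evaluation consumes."""

    def __init__(self, pid_a, pid_b, res_a, res_b, gaps=0):
        self.protein_a_id = pid_a
        self.protein_b_id = pid_b
        self._res_a = set(res_a)
        self._res_b = set(res_b)
        self.gap_count = gaps

    def residues_a(self):
        return self._res_a

    def residues_b(self):
        return self._res_b


def ref(pid, residues):
    return ReferenceSite(protein_id=pid, chain="A", residues=frozenset(residues))


def test_confirmation_rule():
    pred = FakeReport("4VHBA", "1CQXA", {84, 85, 86}, {84, 85, 86})
    assert confirm_site(pred, ref("4VHBA", {84, 85, 86, 87}))  # 3 shared >= 2
    assert not confirm_site(FakeReport("P", "Q", {1}, set()), ref("P", {1, 2, 3}))
    # one shared residue confirms only under the laxer single-residue rule
    one_shared = FakeReport("P", "Q", {1, 50}, set())
    assert not confirm_site(one_shared, ref("P", {1, 2, 3}), min_shared_residues=2)
    assert confirm_site(one_shared, ref("P", {1, 2, 3}), min_shared_residues=1)
    # empty intersection never confirms
    assert not confirm_site(FakeReport("P", "Q", {7, 8}, set()), ref("P", {1, 2, 3}), 1)


def test_protein_id_mismatch_raises():
    with pytest.raises(ValueError):
        confirm_site(FakeReport("P", "Q", {1}, {2}), ref("Z", {1, 2, 3}))


def test_perfect_agreement():
    preds = [FakeReport("P", "Q", {1, 2, 3}, set())]
    refs = [ref("P", {1, 2, 3})]
    s = precision_recall(preds, refs)
    assert s.precision == 1.0 and s.recall == 1.0


def test_mixed_precision_recall():
    preds = [
        FakeReport("P", "Q", {1, 2}, set()),      # confirms refs 0 and 1
        FakeReport("P", "Q", {10, 11}, set()),    # confirms refs 2 and 3
        FakeReport("P", "Q", {90, 91}, set()),    # confirms nothing
    ]
    refs = [
        ref("P", {1, 2, 3}), ref("P", {1, 2, 4}),
        ref("P", {10, 11, 12}), ref("P", {10, 11, 13}),
    ]
    s = precision_recall(preds, refs)
    assert s.n_output == 3 and s.n_confirmed == 2
    assert s.precision == pytest.approx(2 / 3)
    assert s.recall == 1.0  # all four reference sites recalled by two preds


def test_zero_predictions_warns():
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        s = precision_recall([], [ref("P", {1, 2, 3})])
    assert s.precision == 0.0 and s.recall == 0.0
    assert any("no predictions" in str(x.message) for x in w)


def test_reference_size_filter():
    preds = [FakeReport("P", "Q", {1, 2}, set())]
    refs = [ref("P", {1, 2}), ref("P", {1, 2, 3})]  # first one has only 2 residues
    s = precision_recall(preds, refs)
    assert s.n_reference == 1  # "more than two complete residues"


def test_monotone_in_shared_residue_threshold():
    preds = [FakeReport("P", "Q", {1, 2, 3}, set()), FakeReport("P", "Q", {3, 4}, set())]
    refs = [ref("P", {1, 2, 3}), ref("P", {3, 4, 5})]
    prev_p, prev_r = 1.1, 1.1
    for k in (1, 2, 3):
        s = precision_recall(preds, refs, min_shared_residues=k)
        assert s.precision <= prev_p and s.recall <= prev_r
        prev_p, prev_r = s.precision, s.recall


def test_gap_histogram_buckets():
    preds = [FakeReport("P", "Q", set(), set(), gaps=g) for g in (0, 0, 7)]
    h = gap_histogram(preds)
    assert h == {"0": 2, "1": 0, "2": 0, "3": 0, "4": 0, "5": 0, ">5": 1}
    assert sum(h.values()) == len(preds)
    assert gap_histogram([]) == {b: 0 for b in ("0", "1", "2", "3", "4", "5", ">5")}


def test_histogram_matches_planted_distribution():
    rng_counts = [0, 1, 2, 3, 4, 5, 6, 9, 0, 1] * 10
    preds = [FakeReport("P", "Q", set(), set(), gaps=g) for g in rng_counts]
    h = gap_histogram(preds)
    assert sum(h.values()) == 100
    assert h["0"] == 20 and h["1"] == 20 and h[">5"] == 20


def test_reference_tsv_round_trip(tmp_path):
    path = tmp_path / "ref.tsv"
    path.write_text(
        "protein_id\tchain\tresidue_numbers\n"
        "4VHBA\tA\t84,85,86\n"
        "# comment line\n"
        "1CQXA\tA\t95,96,97,98,99,100\n"
    )
    refs = read_reference_tsv(path)
    assert len(refs) == 2
    assert refs[0].protein_id == "4VHBA" and refs[0].residues == frozenset({84, 85, 86})
    assert len(refs[1].residues) == 6


def test_eval_summary_json():
    s = EvalSummary(3, 2, 4, 2 / 3, 1.0, {"0": 3})
    d = s.to_dict()
    assert d["precision"] == pytest.approx(0.666667)
    assert "gap_histogram" in d
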