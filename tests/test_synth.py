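import json

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from bsfinder.alignment import matched_columns, suboptimal_alignments
from bsfinder.rigid import kabsch_superpose, bottleneck_under_transform
from bsfinder.structures import extract_atom_sequence, read_pdb
from bsfinder.surface import annotate_surface_atoms, build_labeled_grid
from bsfinder.synth import (
    PALETTE_B,
    RESIDUE_TEMPLATES,
    SynthSpec,
    generate_protein,
    plant_shared_site,
    write_ground_truth,
    write_pdb,
)


def test_generation_is_deterministic():
    a = generate_protein(SynthSpec(n_residues=25, seed=42))
    b = generate_protein(SynthSpec(n_residues=25, seed=42))
    assert [x.name for x in a.atoms] == [x.name for x in b.atoms]
    np.testing.assert_array_equal(a.coords(), b.coords())


def test_minimum_atom_separation():
    s = generate_protein(SynthSpec(n_residues=30, seed=7))
    assert pdist(s.coords()).min() >= 2.5 - 1e-9


def test_all_ala_atom_count():
    s = generate_protein(SynthSpec(n_residues=30, seed=1, residue_palette=["ALA"]))
    assert len(s) == 150  # 5 atoms per residue
    assert [a.name for a in s.atoms[:5]] == RESIDUE_TEMPLATES["ALA"]


def test_templates_follow_standard_order():
    for names in RESIDUE_TEMPLATES.values():
        assert names[:4] == ["N", "CA", "C", "O"]


def test_plant_exact_copy_without_jitter():
    A, B, truth = plant_shared_site(
        SynthSpec(n_residues=40, seed=5, jitter_sigma=0.0),
        SynthSpec(n_residues=40, seed=6, residue_palette=list(PALETTE_B)),
        site=SynthSpec(n_residues=40, seed=5, jitter_sigma=0.0),
    )
    pa = A.coords()[[i for i, _ in truth.pairs]]
    pb = B.coords()[[j for _, j in truth.pairs]]
    assert bottleneck_under_transform(truth.transform, pb, pa) < 1e-9


def test_plant_jitter_within_matching_threshold():
    hits = 0
    n = 15
    for s in range(n):
        A, B, truth = plant_shared_site(
            SynthSpec(n_residues=40, seed=100 + s),
            SynthSpec(n_residues=40, seed=200 + s, residue_palette=list(PALETTE_B)),
        )
        pa = A.coords()[[i for i, _ in truth.pairs]]
        pb = B.coords()[[j for _, j in truth.pairs]]
        tr = kabsch_superpose(pb, pa)
        hits += bottleneck_under_transform(tr, pb, pa) < 1.5
    assert hits >= 0.9 * n


def test_gap_edits_become_alignment_gaps():
    A, B, truth = plant_shared_site(
        SynthSpec(n_residues=40, seed=8, gap_edits=2),
        SynthSpec(n_residues=40, seed=9, residue_palette=list(PALETTE_B)),
        site=SynthSpec(n_residues=40, seed=8, gap_edits=2),
    )
    assert len(truth.deleted_atoms_b) == 2
    segs = suboptimal_alignments(
        extract_atom_sequence(A), extract_atom_sequence(B), min_matches=15
    )
    truth_pairs = set(truth.pairs)
    best = max(segs, key=lambda sg: len(set(matched_columns(sg).matched_pairs()) & truth_pairs))
    m = matched_columns(best)
    covered = set(m.matched_pairs()) & truth_pairs
    assert len(covered) == len(truth.pairs)
    # the two deleted atoms appear as gap columns inside the planted span
    positions = sorted(i for i, c in enumerate(m.columns) if c in truth_pairs)
    lo, hi = positions[0], positions[-1] + 1
    interior_gaps = sum(m.gap_before[lo + 1 : hi])
    assert interior_gaps == 2


def test_surface_placement_exposes_site_on_both_sides():
    A, B, truth = plant_shared_site(
        SynthSpec(seed=31), SynthSpec(seed=32, residue_palette=list(PALETTE_B))
    )
    for struct, side in ((A, 0), (B, 1)):
        grid = build_labeled_grid(struct)
        ann = annotate_surface_atoms(struct, grid)
        idx = [p[side] for p in truth.pairs]
        assert np.mean(ann.is_surface_atom[idx]) >= 2 / 3


def test_buried_placement_occludes_every_window():
    A, B, truth = plant_shared_site(
        SynthSpec(seed=33, n_residues=160),
        SynthSpec(seed=34, residue_palette=list(PALETTE_B)),
        site=SynthSpec(seed=33, placement="buried"),
    )
    grid = build_labeled_grid(B)
    ann = annotate_surface_atoms(B, grid)
    flags = ann.is_surface_atom[[j for _, j in truth.pairs]].astype(float)
    c = np.concatenate([[0.0], np.cumsum(flags)])
    w = 15
    worst = max((c[i + w] - c[i]) / w for i in range(len(flags) - w + 1))
    assert worst < 2 / 3


def test_no_long_shared_decoy_runs():
    A, B, truth = plant_shared_site(
        SynthSpec(seed=35), SynthSpec(seed=36, residue_palette=list(PALETTE_B))
    )
    ta = [a.name for a in A.atoms]
    tb = [b.name for b in B.atoms]
    in_site_a = {i for i, _ in truth.pairs}
    in_site_b = {j for _, j in truth.pairs}
    grams_a = {
        tuple(ta[i : i + 15])
        for i in range(len(ta) - 14)
        if not any(k in in_site_a for k in range(i, i + 15))
    }
    grams_b = {
        tuple(tb[i : i + 15])
        for i in range(len(tb) - 14)
        if not any(k in in_site_b for k in range(i, i + 15))
    }
    assert not (grams_a & grams_b)


def test_pdb_format_edge_cases(tmp_path):
    from bsfinder.structures import AtomRecord, ProteinStructure

    atoms = [
        AtomRecord(1, "N", "N", "GLY", 9999, "", "A", (-99.999, 0.0, 1.5)),
        AtomRecord(2, "CA", "C", "GLY", 9999, "", "A", (3.25, -45.5, 99.125)),
        AtomRecord(3, "C", "C", "GLY", 9999, "", "A", (0.0, 2.5, -7.75)),
        AtomRecord(4, "O", "O", "GLY", 9999, "", "A", (1.0, 1.0, 1.0)),
    ]
    s = ProteinStructure(id="EDGE", atoms=atoms)
    path = write_pdb(s, tmp_path / "edge.pdb")
    s2 = read_pdb(path)
    assert s2.atoms[0].residue_number == 9999
    np.testing.assert_allclose(s2.coords(), s.coords(), atol=1.5e-3)


def test_ground_truth_serialisation(tmp_path):
    A, B, truth = plant_shared_site(
        SynthSpec(n_residues=40, seed=37),
        SynthSpec(n_residues=40, seed=38, residue_palette=list(PALETTE_B)),
    )
    path = write_ground_truth(truth, tmp_path / "truth.json")
    data = json.loads(open(path).read())
    assert len(data["pairs"]) == len(truth.pairs)
    assert data["placement"] == "surface"
    assert len(data["transform"]) == 3 and len(data["transform"][0]) == 4
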