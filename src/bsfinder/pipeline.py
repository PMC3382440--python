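"""End-to-end binding-site comparison pipeline.

``compare_pair`` chains the three stages — atom-level local alignment,
surface filtering of conserved segments, approximate bottleneck rigid
matching — and applies the steric-overlap veto to every matching
transform.  Reports carry matched atoms, residue ranges, the transform,
per-pair distances, the gap count of the source segment and the overlap
counts.  Windows whose transforms agree within a small tolerance are
grouped: distinct sequence segments matched by one rigid transformation
belong to one structural correspondence and share a ``transform_group``.

``search_site`` compares an extracted binding site (a residue selection of
a parent structure) against whole target structures; the surface test is
applied to the targets only, a site being surface-exposed by construction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .alignment import (
    ScoringScheme,
    matched_columns,
    suboptimal_alignments,
    window_gap_count,
)
from .candidates import CandidateSite, enumerate_candidates
from .overlap import OverlapResult, check_overlap, check_overlap_fast
from .rigid import MatchParameters, MatchResult, RigidTransform, find_matching_subsegments
from .structures import ProteinStructure, extract_atom_sequence, read_pdb
from .surface import annotate_surface_atoms, build_labeled_grid

__all__ = ["RunConfig", "SitePairReport", "compare_pair", "compare_structures", "search_site"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds in one place.

    Defaults are the method's operating point: d = 1.5 A with eps = 0.1,
    at least 15 matched atoms per site, 2/3 surface fraction, 1 A grid
    with a 2 A protein radius and 1.5 A surface-atom radius, and an
    overlap veto at 5% of the smaller interior count.
    """

    d: float = 1.5
    eps: float = 0.1
    min_pairs: int = 15
    min_surface_fraction: float = 2.0 / 3.0
    overlap_ratio: float = 0.05
    grid_step: float = 1.0
    protein_radius: float = 2.0
    atom_surface_radius: float = 1.5
    skip_surface_step: bool = False
    exact_overlap: bool = False  # per-transform shared-lattice veto (slower)
    max_segments: int = 100
    chain_a: str | None = None
    chain_b: str | None = None

    def __post_init__(self) -> None:
        for name in ("d", "eps", "grid_step", "protein_radius", "atom_surface_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_surface_fraction", "overlap_ratio"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")

    @property
    def match_params(self) -> MatchParameters:
        return MatchParameters(d=self.d, eps=self.eps, min_pairs=self.min_pairs)


@dataclass
class SitePairReport:
    """One predicted binding-site pair (post-veto)."""

    protein_a_id: str
    protein_b_id: str
    residue_ranges_a: list[tuple[str, int, int]]
    residue_ranges_b: list[tuple[str, int, int]]
    matched_atoms: list[tuple[str, int, int]]  # (atom name, resnum A, resnum B)
    atom_pairs: list[tuple[int, int]]  # atom indices into the two structures
    transform: RigidTransform
    bottleneck: float
    n_pairs: int
    gap_count: int
    overlap: OverlapResult | None
    transform_group: int = -1

    def residues_a(self) -> set[int]:
        return {ra for _, ra, _ in self.matched_atoms}

    def residues_b(self) -> set[int]:
        return {rb for _, _, rb in self.matched_atoms}

    def to_dict(self) -> dict:
        return {
            "protein_a": self.protein_a_id,
            "protein_b": self.protein_b_id,
            "residue_ranges_a": [list(r) for r in self.residue_ranges_a],
            "residue_ranges_b": [list(r) for r in self.residue_ranges_b],
            "matched_atoms": [list(m) for m in self.matched_atoms],
            "transform": self.transform.as_matrix_3x4(),
            "bottleneck": round(self.bottleneck, 6),
            "n_pairs": self.n_pairs,
            "gap_count": self.gap_count,
            "overlap": None
            if self.overlap is None
            else {
                "X": self.overlap.X,
                "X1": self.overlap.X1,
                "X2": self.overlap.X2,
                "overlapping": self.overlap.overlapping,
            },
            "transform_group": self.transform_group,
        }


def _residue_ranges(struct: ProteinStructure, atom_idx: list[int]) -> list[tuple[str, int, int]]:
    """Contiguous residue-number ranges covered by the given atoms."""
    nums = sorted({struct.atoms[i].residue_number for i in atom_idx})
    if not nums:
        return []
    chain = struct.atoms[atom_idx[0]].chain_id
    ranges = []
    start = prev = nums[0]
    for n in nums[1:]:
        if n == prev + 1:
            prev = n
            continue
        ranges.append((chain, start, prev))
        start = prev = n
    ranges.append((chain, start, prev))
    return ranges


def _rotation_angle(Ra: np.ndarray, Rb: np.ndarray) -> float:
    cosang = (np.trace(Ra.T @ Rb) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _group_transforms(
    reports: list[SitePairReport], angle_tol: float = 5.0, trans_tol: float = 0.5
) -> None:
    """Assign transform_group ids: transforms equal within tolerance share one.

    This reproduces the behaviour where several separate sequence segments
    are matched by one rigid transformation simultaneously and therefore
    constitute a single structural correspondence.
    """
    groups: list[RigidTransform] = []
    for rep in reports:
        for gid, ref in enumerate(groups):
            if (
                _rotation_angle(rep.transform.rotation, ref.rotation) <= angle_tol
                and float(np.linalg.norm(rep.transform.translation - ref.translation)) <= trans_tol
            ):
                rep.transform_group = gid
                break
        else:
            rep.transform_group = len(groups)
            groups.append(rep.transform)


def compare_structures(
    structA: ProteinStructure,
    structB: ProteinStructure,
    config: RunConfig = RunConfig(),
    *,
    surface_exempt_a: bool = False,
    skip_overlap_veto: bool = False,
) -> list[SitePairReport]:
    """Run the full pipeline on two in-memory structures.

    ``surface_exempt_a`` and ``skip_overlap_veto`` support site-search
    mode: an extracted binding site is surface-exposed by construction and
    necessarily coincides with its match, so neither the surface test on
    its side nor the whole-body steric veto applies.
    """
    seqA = extract_atom_sequence(structA)
    seqB = extract_atom_sequence(structB)
    segments = suboptimal_alignments(
        seqA, seqB, ScoringScheme(), min_matches=config.min_pairs, max_segments=config.max_segments
    )

    surfA = surfB = None
    gridA = gridB = None
    if not config.skip_surface_step:
        if not surface_exempt_a:
            gridA = build_labeled_grid(structA, config.grid_step, config.protein_radius)
            surfA = annotate_surface_atoms(structA, gridA, config.atom_surface_radius)
        gridB = build_labeled_grid(structB, config.grid_step, config.protein_radius)
        surfB = annotate_surface_atoms(structB, gridB, config.atom_surface_radius)

    coordsA = structA.coords()
    coordsB = structB.coords()
    reports: list[SitePairReport] = []
    for segment in segments:
        matched = matched_columns(segment)
        if config.skip_surface_step:
            if len(matched.columns) < config.min_pairs:
                continue
            candidates = [
                CandidateSite(
                    segment=matched,
                    surface_fraction_a=1.0,
                    surface_fraction_b=1.0,
                    n_pairs=len(matched.columns),
                    span=(0, len(matched.columns)),
                )
            ]
        else:
            candidates = enumerate_candidates(
                matched, surfA, surfB, config.min_pairs, config.min_surface_fraction
            )
        for cand in candidates:
            for result in find_matching_subsegments(cand, coordsA, coordsB, config.match_params):
                s, e = result.subsegment
                cols = cand.segment.columns[s:e]
                pairs = [(a, b) for a, b in cols]
                reports.append(
                    SitePairReport(
                        protein_a_id=structA.id,
                        protein_b_id=structB.id,
                        residue_ranges_a=_residue_ranges(structA, [a for a, _ in pairs]),
                        residue_ranges_b=_residue_ranges(structB, [b for _, b in pairs]),
                        matched_atoms=[
                            (
                                structA.atoms[a].name,
                                structA.atoms[a].residue_number,
                                structB.atoms[b].residue_number,
                            )
                            for a, b in pairs
                        ],
                        atom_pairs=pairs,
                        transform=result.transform,
                        bottleneck=result.bottleneck,
                        n_pairs=result.n_pairs,
                        gap_count=window_gap_count(cand.segment, s, e),
                        overlap=None,
                    )
                )

    reports.sort(key=lambda r: (-r.n_pairs, r.bottleneck))
    _group_transforms(reports)

    # steric veto, evaluated once per transform group (members agree within
    # 5 degrees / 0.5 A, far inside the voxel resolution of the test)
    if skip_overlap_veto:
        return reports
    if reports and not config.exact_overlap:
        if gridA is None:
            gridA = build_labeled_grid(structA, config.grid_step, config.protein_radius)
        if gridB is None:
            gridB = build_labeled_grid(structB, config.grid_step, config.protein_radius)
        X2_own = gridB.n_interior
    verdicts: dict[int, OverlapResult] = {}
    for rep in reports:
        if rep.transform_group not in verdicts:
            if config.exact_overlap:
                verdicts[rep.transform_group] = check_overlap(
                    coordsA,
                    coordsB,
                    rep.transform,  # maps B's coordinates into A's frame
                    config.grid_step,
                    config.protein_radius,
                    ratio_threshold=config.overlap_ratio,
                )
            else:
                verdicts[rep.transform_group] = check_overlap_fast(
                    gridA,
                    rep.transform.apply(coordsB),
                    X2_own,
                    config.grid_step,
                    config.protein_radius,
                    ratio_threshold=config.overlap_ratio,
                )
        rep.overlap = verdicts[rep.transform_group]
    reports = [r for r in reports if not r.overlap.overlapping]

    # compact group ids after the veto
    remap: dict[int, int] = {}
    for rep in reports:
        rep.transform_group = remap.setdefault(rep.transform_group, len(remap))
    return reports


def compare_pair(
    pdbA: str | os.PathLike,
    pdbB: str | os.PathLike,
    config: RunConfig = RunConfig(),
) -> list[SitePairReport]:
    """Compare two PDB files; see :func:`compare_structures`."""
    structA = read_pdb(pdbA, chain=config.chain_a)
    structB = read_pdb(pdbB, chain=config.chain_b)
    return compare_structures(structA, structB, config)


def load_site_query(path: str | os.PathLike) -> ProteinStructure:
    """Load a site query: JSON {"pdb": path, "chain": id, "residues": [...]}.

    Returns the site as a small structure (the selected residues' atoms in
    file order).  Relative PDB paths resolve against the JSON file's
    directory.
    """
    path = os.fspath(path)
    with open(path) as fh:
        spec = json.load(fh)
    pdb_path = spec["pdb"]
    if not os.path.isabs(pdb_path):
        pdb_path = os.path.join(os.path.dirname(path), pdb_path)
    parent = read_pdb(pdb_path, chain=spec.get("chain"))
    wanted = set(spec["residues"])
    atoms = [a for a in parent.atoms if a.residue_number in wanted]
    if not atoms:
        raise ValueError(f"site query selects no atoms ({path})")
    return ProteinStructure(
        id=parent.id + ":site", atoms=atoms, provenance={"query": path, "parent": parent.id}
    )


def search_site(
    query_site: ProteinStructure | str | os.PathLike,
    targets: list[str | os.PathLike],
    config: RunConfig = RunConfig(),
) -> list[SitePairReport]:
    """Search a binding site against a list of target structures.

    The query plays protein A with the surface test waived on its side.
    """
    if not isinstance(query_site, ProteinStructure):
        query_site = load_site_query(query_site)
    if len(query_site) < config.min_pairs:
        raise ValueError(
            f"site query holds {len(query_site)} atoms; at least {config.min_pairs} required"
        )
    if not targets:
        raise ValueError("no target structures given")
    all_reports: list[SitePairReport] = []
    for tpath in targets:
        target = read_pdb(tpath, chain=config.chain_b)
        all_reports.extend(
            compare_structures(
                query_site, target, config, surface_exempt_a=True, skip_overlap_veto=True
            )
        )
    all_reports.sort(key=lambda r: (-r.n_pairs, r.bottleneck))
    return all_reports


def reports_to_json(reports: list[SitePairReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=1, sort_keys=True)


def reports_to_tsv(reports: list[SitePairReport]) -> str:
    header = (
        "protein_a\tprotein_b\tn_pairs\tbottleneck\tgap_count\t"
        "residues_a\tresidues_b\ttransform_group"
    )
    rows = [header]
    for r in reports:
        ra = ",".join(f"{c}:{s}-{e}" for c, s, e in r.residue_ranges_a)
        rb = ",".join(f"{c}:{s}-{e}" for c, s, e in r.residue_ranges_b)
        rows.append(
            f"{r.protein_a_id}\t{r.protein_b_id}\t{r.n_pairs}\t{r.bottleneck:.6f}\t"
            f"{r.gap_count}\t{ra}\t{rb}\t{r.transform_group}"
        )
    return "\n".join(rows) + "\n"
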