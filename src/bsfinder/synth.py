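"""Synthetic protein-like structures with planted shared sites.

The generator emits single-chain structures whose residues follow the
standard PDB atom order (N, CA, C, O, then side chain) over a small palette
of residue templates.  The backbone is a self-avoiding random walk of CA
positions with ~3.8 A steps; every atom keeps at least 2.5 A from every
other atom, so the voxel-grid stage sees a connected, protein-sized body.
Geometry is idealized (template offsets, no rotamers, no Ramachandran
constraints): the pipeline only ever consumes atom names and coordinates,
which is exactly what these fixtures control.

``plant_shared_site`` copies a contiguous residue stretch of one structure
into a second one under a random rigid transform with optional per-atom
Gaussian jitter and optional atom deletions (which become alignment gaps),
and returns the planted ground truth.  Surface placement keeps both copies
exposed; buried placement wraps the second structure's chain around its
copy until the copy fails the surface-atom test.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .rigid import RigidTransform
from .structures import AtomRecord, ProteinStructure
from .surface import annotate_surface_atoms, build_labeled_grid

__all__ = [
    "RESIDUE_TEMPLATES",
    "SynthSpec",
    "PlantedTruth",
    "PlacementError",
    "generate_protein",
    "plant_shared_site",
    "write_pdb",
]

_MIN_ATOM_DIST = 2.5
_CA_STEP = 3.8
_CA_EXCLUSION = 6.0  # non-adjacent CA pairs keep at least this distance
_CA_EXCLUSION_WRAP = 3.2  # tighter packing while wrapping a buried site
_SIDE_RADIUS = 2.6

# icosahedron vertex directions: 12 units, min pairwise angle 63.43 deg, so
# atoms at radius 2.6 along distinct vertices sit >= 2.73 A apart (2.6 from
# CA).  The last vertex (and its antipode, second-to-last) are never
# assigned to atoms: at placement time the free vertex is aligned with the
# direction back along the chain, which would otherwise always clash.
def _icosahedron() -> np.ndarray:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = []
    for a, b in ((0, 1), (1, 2), (2, 0)):
        for s1 in (-1, 1):
            for s2 in (-1, 1):
                p = [0.0, 0.0, 0.0]
                p[a] = s1 * 1.0
                p[b] = s2 * phi
                v.append(p)
    v = np.array(v) / np.sqrt(1.0 + phi * phi)
    # order so the final two entries are an antipodal pair
    last = v[-1]
    anti = int(np.argmin(np.linalg.norm(v + last, axis=1)))
    order = [i for i in range(len(v)) if i not in (anti, len(v) - 1)] + [anti, len(v) - 1]
    return v[order]


_DIRECTIONS = _icosahedron()

# name -> ordered atom names (N, CA, C, O, then side chain).  Side chains
# are truncated after their second atom — as in partially disordered
# crystallographic models — which keeps every residue within six heavy
# atoms; bulkier templates cannot honour the 2.5 A exclusion at a 3.8 A
# CA step.  Each template has a distinct side-chain token set, so the two
# decoy palettes below share no residue-boundary-crossing atom-name runs.
RESIDUE_TEMPLATES: dict[str, list[str]] = {
    "GLY": ["N", "CA", "C", "O"],
    "ALA": ["N", "CA", "C", "O", "CB"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG"],
}

# disjoint decoy palettes for the two proteins of a planted pair
PALETTE_A = ["GLY", "ALA", "SER", "VAL"]
PALETTE_B = ["CYS", "THR", "ASP"]


class PlacementError(RuntimeError):
    """The walk or the plant could not satisfy its geometric constraints."""


@dataclass
class SynthSpec:
    """Parameters of one synthetic structure / planted site.

    ``compactness`` in [0, 1] biases the CA walk toward its running
    centroid (0 = extended coil, 1 = tight globule).
    """

    n_residues: int = 100
    residue_palette: list[str] = field(default_factory=lambda: list(PALETTE_A))
    seed: int = 0
    site_length_atoms: int = 20
    jitter_sigma: float = 0.2
    placement: str = "surface"  # or "buried"
    gap_edits: int = 0
    compactness: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.placement not in ("surface", "buried"):
            raise ValueError("placement must be 'surface' or 'buried'")
        unknown = set(self.residue_palette) - set(RESIDUE_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown residue templates: {sorted(unknown)}")


@dataclass
class PlantedTruth:
    """Ground truth of a planted shared site."""

    pairs: list[tuple[int, int]]  # (atom index in A, atom index in B)
    transform: RigidTransform  # maps A's planted atoms onto B's (pre-jitter)
    residues_a: tuple[int, int]  # inclusive residue-number range in A
    residues_b: tuple[int, int]
    seed: int
    jitter_sigma: float
    placement: str
    deleted_atoms_b: list[int] = field(default_factory=list)  # A-side indices of edited-out atoms


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _walk_step(
    rng: np.random.Generator,
    current: np.ndarray,
    previous_cas: list[np.ndarray],
    compactness: float,
    attract: np.ndarray | None = None,
) -> np.ndarray:
    """One self-avoiding CA step.

    With an ``attract`` point the step is biased to stay in a 3-6 A band
    around it (approach from outside, orbit inside the band), which is how
    buried placements wrap a chain around the planted site.  Plain
    ``compactness`` instead pulls toward the walk's running centroid.
    """
    for trial in range(300):
        relax = max(0.0, 1.0 - trial / 150.0)  # shed the bias if boxed in
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        bias = None
        if attract is not None:
            pull = attract - current
            r = np.linalg.norm(pull)
            if r > 1e-9:
                radial = pull / r
                if r > 6.0:
                    bias = radial
                elif r < 3.0:
                    bias = -radial
                else:  # orbit: strip the radial component off a random direction
                    tang = direction - np.dot(direction, radial) * radial
                    if np.linalg.norm(tang) > 1e-9:
                        bias = tang / np.linalg.norm(tang)
            mix = 0.7
        elif compactness > 0 and previous_cas:
            pull = np.mean(previous_cas, axis=0) - current
            if np.linalg.norm(pull) > 1e-9:
                bias = pull / np.linalg.norm(pull)
            mix = compactness
        if bias is not None:
            m = mix * relax
            direction = (1 - m) * direction + m * bias
            direction /= np.linalg.norm(direction)
        nxt = current + _CA_STEP * direction
        if len(previous_cas) > 1:
            excl = _CA_EXCLUSION_WRAP if attract is not None else _CA_EXCLUSION
            d = np.linalg.norm(np.array(previous_cas[:-1]) - nxt, axis=1)
            if d.min() < excl:
                continue
        return nxt
    raise PlacementError("self-avoiding walk failed to advance")


def _align_to(direction: np.ndarray) -> np.ndarray:
    """Rotation taking the reserved backward vertex onto ``direction``."""
    a = _DIRECTIONS[-1]
    b = direction / np.linalg.norm(direction)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _spin(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _place_residue(
    rng: np.random.Generator,
    ca: np.ndarray,
    atom_names: list[str],
    existing: np.ndarray,
    back_dir: np.ndarray | None = None,
    avoid: np.ndarray | None = None,
    avoid_dist: float = 4.5,
) -> np.ndarray | None:
    """Template atoms at ``ca``; the reserved free vertex faces ``back_dir``.

    The spin about the backward axis is random and retried on clashes.
    Returns None if no clash-free orientation was found.
    """
    others = [n for n in atom_names if n != "CA"]
    if back_dir is None or np.linalg.norm(back_dir) < 1e-9:
        back_dir = rng.normal(size=3)
    align = _align_to(back_dir)
    for _ in range(60):
        R = _spin(back_dir, rng.uniform(0, 2 * np.pi)) @ align
        offsets = _SIDE_RADIUS * (_DIRECTIONS[: len(others)] @ R.T)
        all_coords = []
        k = 0
        for n in atom_names:
            if n == "CA":
                all_coords.append(ca)
            else:
                all_coords.append(ca + offsets[k])
                k += 1
        all_coords = np.array(all_coords)
        if existing.size:
            dmin = np.min(
                np.linalg.norm(existing[:, None, :] - all_coords[None, :, :], axis=2)
            )
            if dmin < _MIN_ATOM_DIST:
                continue
        if avoid is not None and len(avoid):
            dmin = np.min(np.linalg.norm(avoid[:, None, :] - all_coords[None, :, :], axis=2))
            if dmin < avoid_dist:
                continue
        return all_coords
    return None


def _build_structure(
    struct_id: str,
    residue_names: list[str],
    residue_coords: list[np.ndarray],
    seed: int,
    first_residue_number: int = 1,
) -> ProteinStructure:
    atoms: list[AtomRecord] = []
    serial = 0
    for i, (rname, coords) in enumerate(zip(residue_names, residue_coords)):
        names = RESIDUE_TEMPLATES[rname]
        for n, c in zip(names, coords):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=n,
                    element=n[0],
                    residue_name=rname,
                    residue_number=first_residue_number + i,
                    insertion_code="",
                    chain_id="A",
                    coord=(float(c[0]), float(c[1]), float(c[2])),
                )
            )
    return ProteinStructure(id=struct_id, atoms=atoms, provenance={"synthetic_seed": seed})


def _grow_chain(
    rng: np.random.Generator,
    residue_names: list[str],
    start_ca: np.ndarray,
    start_dir_cas: list[np.ndarray],
    existing_atoms: list[np.ndarray],
    compactness: float,
    attract_points: np.ndarray | None = None,
    avoid: np.ndarray | None = None,
    avoid_dist: float = 4.5,
) -> list[np.ndarray]:
    """Grow residues one by one; returns per-residue atom coordinate blocks.

    ``attract_points``: optional (k, 3) array; each residue steps toward a
    randomly drawn row (buried-site wrapping).
    """
    blocks: list[np.ndarray] = []
    cas = list(start_dir_cas)
    current = start_ca
    backtracks = 0
    i = 0
    while i < len(residue_names):
        rname = residue_names[i]
        placed = None
        attract = None
        if attract_points is not None:
            attract = attract_points[int(rng.integers(len(attract_points)))]
        existing = np.vstack(existing_atoms) if existing_atoms else np.empty((0, 3))
        # gather candidate CA positions (biased first, free later), then try
        # to place starting from the least crowded one — a caged walk end
        # escapes along the most open corridor instead of stalling
        cands: list[np.ndarray] = []
        for trial in range(60):
            try:
                cands.append(_walk_step(rng, current, cas, compactness, attract if trial < 30 else None))
            except PlacementError:
                continue
        if not cands:
            raise PlacementError(f"walk cornered before residue {rname}")
        if existing.size:
            room = np.array([float(np.min(np.linalg.norm(existing - c, axis=1))) for c in cands])
            # biased candidates with enough elbow room first (keeps the wrap
            # tight), then everything else from most to least open
            biased = [i for i in range(min(30, len(cands))) if room[i] >= 3.2]
            rest = [int(i) for i in np.argsort(room)[::-1] if i not in set(biased)]
            order = biased + rest
        else:
            order = list(range(len(cands)))
        for oi in order[:30]:
            ca = cands[int(oi)]
            placed = _place_residue(
                rng, ca, RESIDUE_TEMPLATES[rname], existing, current - ca, avoid, avoid_dist
            )
            if placed is not None:
                break
        if placed is None:
            # caged: undo a few residues and regrow along a different path
            if backtracks >= 40 or len(blocks) < 2:
                raise PlacementError(f"could not place residue {rname} (seed-bound retries exhausted)")
            backtracks += 1
            n_undo = min(3, len(blocks) - 1)
            for _ in range(n_undo):
                blocks.pop()
                existing_atoms.pop()
                cas.pop()
                i -= 1
            current = cas[-1] if cas else start_ca
            continue
        blocks.append(placed)
        existing_atoms.append(placed)
        cas.append(ca)
        current = ca
        i += 1
    return blocks


def generate_protein(spec: SynthSpec, struct_id: str | None = None) -> ProteinStructure:
    """A self-avoiding protein-like chain; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    names = [spec.residue_palette[int(rng.integers(len(spec.residue_palette)))] for _ in range(spec.n_residues)]
    last_err: PlacementError | None = None
    for _ in range(20):  # dead-end walks restart with the same rng stream
        try:
            blocks = _grow_chain(rng, names, np.zeros(3), [], [], spec.compactness)
            break
        except PlacementError as err:
            last_err = err
    else:
        raise PlacementError(f"generation failed for seed {spec.seed}: {last_err}")
    sid = struct_id or f"SYN{spec.seed:04d}A"
    return _build_structure(sid, names, blocks, spec.seed)


def _site_window(names: list[str], blocks: list[np.ndarray], min_atoms: int, rng: np.random.Generator) -> tuple[int, int]:
    """A contiguous residue window with at least ``min_atoms`` atoms, mid-chain."""
    n = len(names)
    sizes = [len(b) for b in blocks]
    # prefer a window starting in the middle third of the chain
    starts = list(range(n // 3, n)) + list(range(0, n // 3))
    for s in starts:
        total = 0
        for e in range(s, n):
            total += sizes[e]
            if total >= min_atoms:
                return s, e + 1
    raise PlacementError("protein too small for the requested site length")


def _token_kgrams(tokens: list[str], k: int, exclude: tuple[int, int] | None) -> set[tuple[str, ...]]:
    out = set()
    for i in range(len(tokens) - k + 1):
        if exclude is not None and i + k > exclude[0] and i < exclude[1]:
            continue
        out.add(tuple(tokens[i : i + k]))
    return out


def plant_shared_site(
    specA: SynthSpec,
    specB: SynthSpec,
    site: SynthSpec | None = None,
) -> tuple[ProteinStructure, ProteinStructure, PlantedTruth]:
    """Two structures sharing one rigidly-copied site, plus ground truth.

    The site parameters (length, jitter, placement, gap edits) are taken
    from ``site`` when given, else from ``specA``.  The copy is planted in
    the second structure under a random proper rigid transform; with
    surface placement both copies stay exposed (verified a posteriori with
    the package's own surface stage), with buried placement the second
    chain is wrapped compactly around its copy until the copy fails the
    surface test.
    """
    site = site or specA
    rng = np.random.default_rng(np.random.SeedSequence([specA.seed, specB.seed, 7]))

    for attempt in range(8):
        try:
            A, B, truth = _plant_once(specA, specB, site, rng)
        except PlacementError:
            continue
        if site.placement == "surface":
            if _site_surface_ok(A, truth, side="a") and _site_surface_ok(B, truth, side="b"):
                return A, B, truth
        else:
            # every 15-atom window of the copy must fail the 2/3 surface
            # test (with margin), otherwise the candidate filter could
            # still admit a window of the site
            if _worst_window_fraction(B, truth, side="b") <= 0.6:
                return A, B, truth
    raise PlacementError(
        f"could not satisfy {site.placement!r} placement after retries "
        f"(seeds {specA.seed}/{specB.seed})"
    )


def _site_surface_ok(struct: ProteinStructure, truth: PlantedTruth, side: str) -> bool:
    grid = build_labeled_grid(struct)
    ann = annotate_surface_atoms(struct, grid)
    idx = [pa if side == "a" else pb for pa, pb in truth.pairs]
    return float(np.mean(ann.is_surface_atom[idx])) >= 2.0 / 3.0


def _worst_window_fraction(
    struct: ProteinStructure, truth: PlantedTruth, side: str, window: int = 15
) -> float:
    """Largest surface fraction over any ``window`` consecutive site atoms."""
    grid = build_labeled_grid(struct)
    ann = annotate_surface_atoms(struct, grid)
    idx = [pa if side == "a" else pb for pa, pb in truth.pairs]
    flags = ann.is_surface_atom[idx].astype(float)
    if len(flags) < window:
        return float(flags.mean())
    c = np.concatenate([[0.0], np.cumsum(flags)])
    return float(max((c[i + window] - c[i]) / window for i in range(len(flags) - window + 1)))


def _occlusion_shell(
    site_coords: np.ndarray,
    rng: np.random.Generator,
    avoid: np.ndarray | None = None,
    targets: np.ndarray | None = None,
    context: np.ndarray | None = None,
) -> np.ndarray:
    """Dense decoy-atom shell that buries ``site_coords`` under the voxel rules.

    A site atom stays a surface atom as long as any lattice point within
    ~2.5 A of it has an empty neighbour, so burial needs every lattice
    point near the site covered by some atom's 2 A sphere.  A BCC packing
    (3 A cube) seeds the shell and a hole-filling pass plants extra atoms
    at remaining empty lattice points.  Shell atoms keep >= 2.1 A from the
    site and >= 2.35 A from each other — van-der-Waals-contact distances,
    tighter than the walk's own 2.5 A exclusion, because a looser shell
    provably cannot close the coverage holes.
    """
    if targets is None:
        targets = site_coords
    a = 3.0
    lo = targets.min(axis=0) - 8.0
    hi = targets.max(axis=0) + 8.0
    axes = [np.arange(lo[k], hi[k], a) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    cub = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    bcc = np.vstack([cub, cub + a / 2.0])
    from scipy.spatial import cKDTree

    ts = cKDTree(site_coords)
    tt = cKDTree(targets)
    d, _ = ts.query(bcc)
    dt, _ = tt.query(bcc)
    keep = (d >= 2.1) & (dt <= 6.0)
    tav = cKDTree(avoid) if avoid is not None and len(avoid) else None
    if tav is not None:
        dav, _ = tav.query(bcc)
        keep &= dav >= 5.0
    tctx = cKDTree(context) if context is not None and len(context) else None
    if tctx is not None:
        dctx, _ = tctx.query(bcc)
        keep &= dctx >= 2.35
    fills = list(bcc[keep])

    # integer lattice points near the targeted atoms (the final grid is
    # anchored at integer coordinates, so these are the points that matter)
    vaxes = [np.arange(np.floor(lo[k]), hi[k] + 1.0) for k in range(3)]
    vx, vy, vz = np.meshgrid(*vaxes, indexing="ij")
    vox = np.column_stack([vx.ravel(), vy.ravel(), vz.ravel()])
    dv, _ = tt.query(vox)
    vox = vox[dv <= 3.6]

    ctx_stack = [context] if tctx is not None else []
    for _ in range(4):  # hole-filling passes
        atoms = np.vstack([site_coords, *ctx_stack, np.array(fills)])
        ta = cKDTree(atoms)
        dd, _ = ta.query(vox)
        empties = vox[dd > 2.0]
        if len(empties) == 0:
            break
        for v in empties:
            tf = cKDTree(np.array(fills))
            cands = v + rng.uniform(-1.3, 1.3, size=(300, 3))
            cands = cands[np.linalg.norm(cands - v, axis=1) <= 2.0]
            ds, _ = ts.query(cands)
            df, _ = tf.query(cands)
            good = (ds >= 2.1) & (df >= 2.35)
            if tctx is not None and good.any():
                dctx, _ = tctx.query(cands)
                good &= dctx >= 2.35
            if tav is not None and good.any():
                dav, _ = tav.query(cands)
                good &= dav >= 5.0
            ok = np.flatnonzero(good)
            if len(ok):
                fills.append(cands[ok[0]])
    return np.array(fills)


def _shell_to_residues(
    fills: np.ndarray, rng: np.random.Generator
) -> tuple[list[str], list[np.ndarray], list[str], list[np.ndarray]]:
    """Thread shell atoms into decoy residues (pre-site and post-site halves).

    Atoms are ordered along a greedy nearest-neighbour path and chunked
    into residue-sized groups; the atom-name sequence follows the decoy
    palette so the shell cannot align against the partner protein.
    """
    remaining = list(range(len(fills)))
    order = [remaining.pop(0)]
    while remaining:
        last = fills[order[-1]]
        dists = np.linalg.norm(fills[remaining] - last, axis=1)
        order.append(remaining.pop(int(np.argmin(dists))))
    pts = fills[order]

    # whole six-atom residues only: a lone GLY/ALA leftover in the shell
    # would hand decoy alignments a positive-scoring island, which drags
    # the zero-net backbone plateau (and surface spillover) into the
    # planted segment; the few dropped atoms sit at the path's end, on the
    # shell periphery
    n = len(pts) - len(pts) % 6
    sizes = [6] * (n // 6)
    names: list[str] = []
    blocks: list[np.ndarray] = []
    k = 0
    for s in sizes:
        names.append(PALETTE_B[int(rng.integers(len(PALETTE_B)))])
        blocks.append(pts[k : k + s])
        k += s
    half = len(names) // 2
    return names[:half], blocks[:half], names[half:], blocks[half:]


def _plant_once(
    specA: SynthSpec, specB: SynthSpec, site: SynthSpec, rng: np.random.Generator
) -> tuple[ProteinStructure, ProteinStructure, PlantedTruth]:
    sub = np.random.default_rng(rng.integers(2**31))
    buried = site.placement == "buried"

    if buried:
        # protein A with the site as an excursion: the flanks keep >= 6 A
        # from the site atoms, so A contributes few interior lattice points
        # near the site and the overlap test stays clear of its 5% bound
        # under the recovered transform
        # Buried fixtures use an ALA-only site in a GLY-only first chain.
        # Two reasons: the thin site tube carries few interior lattice
        # points (the self-overlap of the two site copies must stay under
        # the 5% veto bound for the ablation run), and aligning a GLY
        # against any 6-atom decoy residue scores exactly 0 (+4 backbone,
        # -4 side-chain gaps), so conserved segments stop at the site
        # boundary instead of diluting the buried copy with surface
        # spillover columns that would defeat the 2/3 filter.
        site_names = []
        total = 0
        while total < site.site_length_atoms:
            site_names.append("ALA")
            total += len(RESIDUE_TEMPLATES["ALA"])
        existingA: list[np.ndarray] = []
        site_blocks = _grow_chain(sub, site_names, np.zeros(3), [], existingA, 0.0)
        site_flat_a = np.vstack(site_blocks)
        site_cas_a = [b[1] for b in site_blocks]  # CA is the second template atom
        n_flank_a = max(specA.n_residues - len(site_names), 2)
        namesApre = ["GLY"] * (n_flank_a // 2)
        namesApost = ["GLY"] * (n_flank_a - n_flank_a // 2)
        # each flank's exclusion zone exempts the two site residues at its
        # own junction — the chain has to pass through that neighbourhood
        blocksApost = _grow_chain(
            sub, namesApost, site_cas_a[-1], list(site_cas_a), existingA, specA.compactness,
            avoid=np.vstack(site_blocks[:-2]) if len(site_blocks) > 2 else np.empty((0, 3)),
            avoid_dist=7.5,
        )
        blocksApreRev = _grow_chain(
            sub, namesApre[::-1], site_cas_a[0], list(site_cas_a[::-1]), existingA, specA.compactness,
            avoid=np.vstack(site_blocks[2:]) if len(site_blocks) > 2 else np.empty((0, 3)),
            avoid_dist=7.5,
        )
        namesA = namesApre + site_names + namesApost
        blocksA = blocksApreRev[::-1] + site_blocks + blocksApost
        sA = len(namesApre)
        eA = sA + len(site_names)
    else:
        # --- protein A: plain generation, pick the site window -------------
        namesA = [specA.residue_palette[int(sub.integers(len(specA.residue_palette)))] for _ in range(specA.n_residues)]
        existingA = []
        blocksA = _grow_chain(sub, namesA, np.zeros(3), [], existingA, specA.compactness)
        sA, eA = _site_window(namesA, blocksA, site.site_length_atoms, sub)
        site_names = namesA[sA:eA]
        site_blocks = [blocksA[i] for i in range(sA, eA)]

    # --- transform the site copy into B's frame ----------------------------
    R = _random_rotation(sub)
    t = sub.uniform(-5, 5, size=3)
    transform = RigidTransform(R, t)
    planted_blocks = [b @ R.T + t for b in site_blocks]
    jittered = [b + sub.normal(0.0, site.jitter_sigma, size=b.shape) for b in planted_blocks]

    # --- protein B: decoy flanks grown outwards from the planted stretch ---
    n_flank = max(specB.n_residues - len(site_names), 2)
    n_pre = n_flank // 2
    n_post = n_flank - n_pre
    paletteB = specB.residue_palette
    namesPre = [paletteB[int(sub.integers(len(paletteB)))] for _ in range(n_pre)]
    namesPost = [paletteB[int(sub.integers(len(paletteB)))] for _ in range(n_post)]

    site_cas = [b[RESIDUE_TEMPLATES[n].index("CA")] for n, b in zip(site_names, jittered)]

    # phantom copy of A's body in B's frame: B's decoys keep well clear of it
    # so that, under the planting transform, the two bodies do not
    # interpenetrate (shared surface sites imply compatible approach
    # directions).  A two-residue junction buffer around the site window is
    # exempt — both chains must pass through that neighbourhood.
    buffer = 2 if not buried else 4  # excursion flanks hug the site junctions
    phantom_blocks = [
        blocksA[i] for i in range(len(blocksA)) if i < sA - buffer or i >= eA + buffer
    ]
    phantom = (
        np.vstack(phantom_blocks) @ R.T + t if phantom_blocks else np.empty((0, 3))
    )

    if buried:
        # a random-walk wrap cannot occlude a site under the voxel rules;
        # instead the central run of the copy is encased in a dense shell of
        # decoy residues (BCC seed + hole filling, see _occlusion_shell).
        # Occluding the central ~55% of site atoms drives every 15-atom
        # window below the 2/3 surface threshold while keeping the shell —
        # and hence the shared-interior volume under the planting transform —
        # as small as possible.
        site_flat = np.vstack(jittered)
        # ordinary flank walks first (they bulk B up so the site region
        # stays a small fraction of its interior volume), then the shell
        # fills whatever space around the central site run remains open
        existingB = [site_flat]
        blocksPost = _grow_chain(
            sub, namesPost, site_cas[-1], list(site_cas), existingB, specB.compactness,
            avoid=phantom, avoid_dist=5.5,
        )
        blocksPreRev = _grow_chain(
            sub, namesPre[::-1], site_cas[0], list(site_cas[::-1]), existingB, specB.compactness,
            avoid=phantom, avoid_dist=5.5,
        )
        k = len(site_flat)
        targets = site_flat[int(0.22 * k) : int(np.ceil(0.78 * k))]
        flank_atoms = np.vstack(blocksPost + blocksPreRev)
        fills = _occlusion_shell(
            site_flat, sub, avoid=phantom, targets=targets, context=flank_atoms
        )
        shellPreNames, shellPreBlocks, shellPostNames, shellPostBlocks = _shell_to_residues(fills, sub)
        namesB = shellPreNames + namesPre + site_names + namesPost + shellPostNames
        blocksB = (
            shellPreBlocks + blocksPreRev[::-1] + jittered + blocksPost + shellPostBlocks
        )
        n_pre = len(shellPreNames) + len(namesPre)
        n_post = len(namesPost) + len(shellPostNames)
    else:
        existingB: list[np.ndarray] = list(jittered)
        blocksPost = _grow_chain(
            sub, namesPost, site_cas[-1], list(site_cas), existingB, specB.compactness,
            avoid=phantom,
        )
        blocksPreRev = _grow_chain(
            sub, namesPre[::-1], site_cas[0], list(site_cas[::-1]), existingB, specB.compactness,
            avoid=phantom,
        )
        namesB = namesPre + site_names + namesPost
        blocksB = blocksPreRev[::-1] + jittered + blocksPost

    # --- gap edits: delete atoms from B's copy (never CA, spread out) ------
    deleted_a_indices: list[int] = []
    if site.gap_edits:
        flat: list[tuple[int, int]] = []  # (residue offset in site, atom offset)
        for ri, rname in enumerate(site_names):
            for ai, an in enumerate(RESIDUE_TEMPLATES[rname]):
                if an != "CA":
                    flat.append((ri, ai))
        chosen: list[tuple[int, int]] = []
        order = sub.permutation(len(flat))
        for oi in order:
            ri, ai = flat[oi]
            if all(abs(ri - rj) > 0 or abs(ai - aj) > 1 for rj, aj in chosen):
                chosen.append((ri, ai))
            if len(chosen) == site.gap_edits:
                break
        for ri, ai in sorted(chosen, reverse=True):
            blocksB[n_pre + ri] = np.delete(blocksB[n_pre + ri], ai, axis=0)
            deleted_a_indices.append((ri, ai))  # resolved to flat indices below

    # assemble B; edited residues need explicit atom-name lists
    atomsB: list[AtomRecord] = []
    namesB_atoms: list[list[str]] = []
    for i, rname in enumerate(namesB):
        full = list(RESIDUE_TEMPLATES[rname])
        if len(blocksB[i]) != len(full):
            # reconstruct which atoms survived the deletion for this residue
            ri = i - n_pre
            removed = sorted(ai for rj, ai in (deleted_a_indices if site.gap_edits else []) if rj == ri)
            for ai in removed[::-1]:
                full.pop(ai)
        namesB_atoms.append(full)
    serial = 0
    for i, rname in enumerate(namesB):
        for n, c in zip(namesB_atoms[i], blocksB[i]):
            serial += 1
            atomsB.append(
                AtomRecord(
                    serial=serial, name=n, element=n[0], residue_name=rname,
                    residue_number=i + 1, insertion_code="", chain_id="A",
                    coord=(float(c[0]), float(c[1]), float(c[2])),
                )
            )
    B = _build_structure_from_atoms(f"SYN{specB.seed:04d}B", atomsB, specB.seed)
    A = _build_structure(f"SYN{specA.seed:04d}A", namesA, blocksA, specA.seed)

    # --- ground-truth atom pairing -----------------------------------------
    offsetA = sum(len(b) for b in blocksA[:sA])
    offsetB = sum(len(namesB_atoms[i]) for i in range(n_pre))
    pairs: list[tuple[int, int]] = []
    deleted_flat: list[int] = []
    ia = offsetA
    ib = offsetB
    for ri, rname in enumerate(site_names):
        full = RESIDUE_TEMPLATES[rname]
        kept = namesB_atoms[n_pre + ri]
        kb = 0
        for ai, an in enumerate(full):
            if kb < len(kept) and kept[kb] == an:
                pairs.append((ia + ai, ib + kb))
                kb += 1
            else:
                deleted_flat.append(ia + ai)
        ia += len(full)
        ib += len(kept)

    # decoy-vocabulary audit: no exact >=15-token run shared outside the plant
    tokA = [a.name for a in A.atoms]
    tokB = [a.name for a in B.atoms]
    spanA = (offsetA, offsetA + sum(len(RESIDUE_TEMPLATES[n]) for n in site_names))
    spanB = (offsetB, offsetB + sum(len(namesB_atoms[n_pre + i]) for i in range(len(site_names))))
    gramsA = _token_kgrams(tokA, 15, spanA)
    gramsB = _token_kgrams(tokB, 15, spanB)
    if gramsA & gramsB:
        raise PlacementError("decoy regions share a long exact atom-token run")

    truth = PlantedTruth(
        pairs=pairs,
        transform=transform,
        residues_a=(sA + 1, eA),
        residues_b=(n_pre + 1, n_pre + len(site_names)),
        seed=specA.seed,
        jitter_sigma=site.jitter_sigma,
        placement=site.placement,
        deleted_atoms_b=deleted_flat,
    )
    return A, B, truth


def _build_structure_from_atoms(struct_id: str, atoms: list[AtomRecord], seed: int) -> ProteinStructure:
    return ProteinStructure(id=struct_id, atoms=atoms, provenance={"synthetic_seed": seed})


def write_pdb(structure: ProteinStructure, path: str | os.PathLike) -> str:
    """Write a structure as wwPDB-column ATOM records (via gemmi).

    The generator seed, when present in the provenance, is recorded in a
    REMARK 999 header line.  Round trip with ``read_pdb`` preserves names,
    numbering and coordinates to PDB precision (3 decimals).
    """
    path = os.fspath(path)
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    # group atoms into complete residues first: gemmi copies objects on
    # add_residue/add_chain, so containers must be filled bottom-up
    residues: list[tuple[str, gemmi.Residue]] = []
    current_key: tuple[str, int, str] | None = None
    for a in structure.atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code)
        if key != current_key:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "A"
            residues.append((a.chain_id, res))
            current_key = key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.coord)
        at.occ = 1.0
        residues[-1][1].add_atom(at)
    chains: dict[str, gemmi.Chain] = {}
    chain_order: list[str] = []
    for chain_id, res in residues:
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
            chain_order.append(chain_id)
        chains[chain_id].add_residue(res)
    for chain_id in chain_order:
        model.add_chain(chains[chain_id])
    st.add_model(model)
    seed = structure.provenance.get("synthetic_seed")
    if seed is not None:
        st.raw_remarks = [f"REMARK 999 SYNTHETIC SEED {seed}"]
    st.setup_entities()
    st.write_pdb(path)
    return path


def write_ground_truth(truth: PlantedTruth, path: str | os.PathLike) -> str:
    """Serialise planted ground truth as JSON."""
    path = os.fspath(path)
    payload = {
        "pairs": [list(p) for p in truth.pairs],
        "transform": truth.transform.as_matrix_3x4(),
        "residues_a": list(truth.residues_a),
        "residues_b": list(truth.residues_b),
        "seed": truth.seed,
        "jitter_sigma": truth.jitter_sigma,
        "placement": truth.placement,
        "deleted_atoms_b": truth.deleted_atoms_b,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return path
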