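# Methods

`bsfinder` predicts binding sites shared by two protein 3D structures by
chaining three stages, each of which is independently testable: local
sequence alignment at the atom level, voxel-grid surface detection, and
approximate bottleneck rigid matching with a steric-overlap veto.

## Stage 1 — atom-level local alignment

In a PDB chain every residue lists its atoms in a fixed order (N, CA, C,
O, then the side chain in order of increasing remoteness), so a chain
defines a sequence over the atom-name alphabet (`N`, `CA`, `CB`, `CG1`,
... — the full token, not the element, is the symbol). Binding sites tend
to be conserved at this level, and Smith–Waterman local alignment of the
two atom sequences recovers them as high-scoring segments.

Scoring: identical atom names +1, different names forbidden (an
impossible transition in the dynamic program, not a large negative
constant), atom-versus-space −2. Because mismatches are forbidden, every
matched column pairs identical atom names; unmatched atoms appear as gap
columns and are counted per segment (the gap statistics of reported sites
are part of the output).

Suboptimal segments are enumerated Waterman–Eggert style: report the best
local alignment, forbid its matched cells, realign; stop when the next
alignment has fewer than 15 matched columns (smaller segments can never
yield a site) or when a configurable cap (default 100 segments) is
reached. Tie-breaking in the traceback is fixed (diagonal, then gap in
the second sequence, then gap in the first; earliest cell in row-major
order among equal maxima) so runs are deterministic.

The DP is vectorised row by row; with linear gap costs the within-row
dependency reduces to a running maximum, so each row costs a handful of
numpy operations and the score matrix is kept only for traceback.

## Stage 2 — voxel-grid surface detection

Space is discretised on a 1 Å lattice anchored at
`floor(min coordinate) − pad` (so integer-lattice translations of a
structure leave all labels unchanged; the absolute sub-voxel phase of a
structure is otherwise arbitrary, which is inherent to the grid method).
A lattice point within 2 Å of any atom center is a *protein* point;
a protein point whose six axis neighbours are all protein is *interior*,
otherwise it is *surface*. An atom is a *surface atom* if some surface
lattice point lies within 1.5 Å of it. All three distance tests are
non-strict (boundary cases count), and points on the lattice boundary are
never interior (the default padding keeps protein points away from the
boundary anyway).

Conserved segments are then filtered: a candidate binding site is a
contiguous window of at least 15 matched columns in which, on each
protein separately, at least 2/3 of the window's matched atoms are
surface atoms. Gap columns count toward neither the window size nor the
fraction denominators. Only *maximal* qualifying windows are emitted —
every qualifying window is contained in a reported one, and stage 3
performs its own subsegment search inside each candidate, so the final
output is unchanged while the quadratic flood of nested windows is
avoided.

The grid build paints each atom's reachable lattice cube directly
(O(atoms · (2r)³) instead of a per-lattice-point nearest-neighbour
query); the painted labels are tested for exact equality against an
exhaustive point-by-point oracle.

## Stage 3 — approximate bottleneck rigid matching

A candidate window is accepted when one proper rigid transformation
brings every matched atom pair within a distance threshold `d`
(default 1.5 Å). Exact bottleneck matching is expensive, so the standard
(1+ε) relaxation is used with ε = 0.1: whenever some transform achieves
bottleneck ≤ d, the stage returns a transform with bottleneck ≤ (1+ε)d.

The search is seeded with the Kabsch least-squares superposition (3×3
SVD, reflection suppressed). If the seed's bottleneck meets (1+ε)d the
window is accepted outright. Otherwise rotations are sampled on an
axis–angle grid around the seed — Fibonacci-sphere axes, angular step
ε·d / r_max where r_max is the largest pair radius about the centroid, so
one step moves no point by more than ε·d — and each sampled rotation is
paired with its *exact* bottleneck-optimal translation: the center of the
minimal enclosing ball of the residual vectors a_i − R·b_i
(Bâdoiu–Clarkson iteration, 150 steps, center error ≈ 1% of the ball
radius). Sampling translations on a grid would give the same guarantee
strictly more slowly; replacing the translation grid with the exact
per-rotation optimum is the one deliberate departure from the textbook
scheme and is covered by the same contract tests.

The gate into refinement is conservative and provably safe: if the
optimal bottleneck is ≤ d then the optimal RMSD is ≤ d, hence the Kabsch
RMSD is ≤ d; windows skipped because their Kabsch RMSD exceeds d can
never violate the contract.

Window search is grow-and-slide: every contiguous window of exactly 15
columns is tested (after a cheap rigid-invariant prefilter — endpoint and
midpoint span differences beyond 2(1+ε)d cannot be matched), accepted
seeds are extended greedily right then left while the guarantee holds,
and overlapping accepted windows are merged when their union still
passes. Windows whose transforms agree within 5° / 0.5 Å are grouped:
separate sequence segments matched by one rigid transformation form a
single structural correspondence, and output counting is per transform
group.

## Steric-overlap veto

A transform that superposes two sites may also drive the protein bodies
into each other. Both structures (the second one transformed) are
labelled on one shared integer-anchored lattice with the stage-2 rules;
with X the points interior to both and X1, X2 the individual interior
counts, the transform is kept iff X ≤ 0.05 · min(X1, X2) (non-strict: the
boundary value is not a veto).

The pipeline's default veto path computes the first structure's interior
labels once per run, labels the second structure only on the padded
intersection box of the two bodies, takes X2 from the second structure's
own lattice (voxel-phase noise of 1–2%, far below the 5% criterion), and
evaluates one verdict per transform group. The literal shared-lattice
implementation remains available (`RunConfig(exact_overlap=True)`) and
the two are cross-checked in the tests.

In site-search mode (`search_site`) the query is an extracted binding
site rather than a whole protein: it is surface-exposed by construction
and necessarily coincides with its match, so the surface test on the
query side and the whole-body veto are waived there.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `d` | 1.5 Å | per-pair distance threshold of stage 3 |
| `eps` | 0.1 | relaxation factor; accepted bottleneck ≤ (1+eps)·d |
| `min_pairs` | 15 | minimum matched atoms per reported site |
| `min_surface_fraction` | 2/3 | surface-atom fraction required on each side |
| `overlap_ratio` | 0.05 | veto bound on X / min(X1, X2) |
| `grid_step` | 1.0 Å | lattice spacing |
| `protein_radius` | 2.0 Å | atom-to-lattice protein-point radius |
| `atom_surface_radius` | 1.5 Å | surface-atom distance to a surface point |
| `max_segments` | 100 | Waterman–Eggert enumeration cap |
| `skip_surface_step` | off | ablation switch: bypass stage 2 entirely |

`d` is the user-facing sensitivity knob; the remaining values are the
method's operating point and are exposed for experimentation only.

## Synthetic structures and what they do (not) show

The generator (`bsfinder.synth`) emits single-chain, protein-like
structures: a self-avoiding CA random walk (≈3.8 Å steps, 6 Å exclusion
between non-adjacent CAs) with residues instantiated from idealised
templates (atoms on icosahedral directions 2.6 Å from the CA, one
direction reserved to face back along the chain). Every atom keeps at
least 2.5 Å from every other atom so the voxel stage sees a connected,
protein-sized body. Residue templates are truncated to at most six heavy
atoms (as in partially disordered crystallographic models); bulkier
templates provably cannot satisfy the joint spacing constraints.
Defaults: 100 residues per structure, 20-atom planted sites, 0.2 Å
coordinate jitter — sized so that a planted site occupies a realistically
small fraction of the body's interior volume, which is what the 5% veto
bound implicitly assumes of real proteins.

`plant_shared_site` copies a contiguous residue stretch of structure A
into structure B under a random proper rigid transform with per-atom
Gaussian jitter and optional atom deletions (which become alignment
gaps). B's decoy flanks grow around a phantom copy of A's body so that
the two bodies are sterically compatible under the planting transform —
the geometry real shared surface sites imply. The two structures use
disjoint decoy residue palettes, so no exact ≥15-token atom-name run is
shared outside the plant (audited at generation time); gapped
backbone-level alignments between decoys still arise, exactly as in real
proteins, and are rejected by stage 3's geometry or the veto.

Buried placement encases the central ~55% of the copy in a dense
BCC-seeded, hole-filled shell of decoy residues (shell contact distances
2.1/2.35 Å — the one place the 2.5 Å exclusion is relaxed, since a looser
shell cannot close the voxel coverage holes). The site-carrying structure
holds the site on an excursion with GLY-only flanks and an ALA-only site:
the thin site tube keeps the irreducible self-overlap of the two copies
under the veto bound, and GLY-versus-six-atom-residue alignment columns
net exactly zero score, which stops conserved segments at the site
boundary instead of diluting the buried copy with surface spillover.

These fixtures control exactly what the pipeline consumes — atom names
and coordinates — and nothing else. Passing tests therefore demonstrate
the algorithmic contracts (alignment optimality, label correctness, the
(1+ε) guarantee, veto semantics, end-to-end recovery under jitter and the
surface-step ablation), not performance on real crystal structures:
synthetic chains have no rotamers, no Ramachandran statistics, no
B-factors, no heteroatoms, and their surface texture is coarser than a
real protein's.

## Numerical choices and degenerate inputs

* Mismatch "−∞" is a forbidden transition; scores stay small integers in
  float64 and tracebacks compare exactly.
* Kabsch requires ≥3 non-collinear pairs; degenerate windows raise
  (`DegenerateGeometryError`) or are skipped during window scans.
* Rotation outputs are validated orthonormal with det +1 at 1e−9.
* Altloc resolution keeps the highest-occupancy conformer (ties: first
  encountered); hydrogens and HETATM records are excluded by default;
  only the first model of multi-model files is read; insertion codes are
  part of residue identity and residues are never renumbered.
* All distance comparisons against thresholds are non-strict with a 1e−9
  guard so exact-boundary lattice geometry is reproducible.
* Empty inputs raise named errors (`EmptyStructureError`,
  `NoAtomRecordsError`, `ChainNotFoundError`); an empty report list is a
  valid result, not an error.

## Evaluation conventions

A prediction is *confirmed* against a reference site when they share at
least two residues (`min_shared_residues=1` reproduces the laxer
single-residue rule used for very short sites by some tools). Precision
is confirmed predictions over all predictions; recall is reference sites
hit by ≥1 prediction over all reference sites with more than two complete
residues (≥3). A prediction confirming several references counts once for
precision but can recall each of them. Gap counts are bucketed 0–5 and
">5" per reported site.

## Known limitations

* Only PDB input (no mmCIF), single chains, first model.
* Subsegments are contiguous alignment windows; non-contiguous atom
  subsets are out of scope.
* The voxel classification is phase-sensitive at the sub-Ångström level,
  as any fixed-grid method is; counts shift by a few percent under
  off-lattice translations.
* The Waterman–Eggert cap (100 segments) bounds runtime on large chains;
  extremely repetitive sequences could in principle push a true site
  below the cap.
* Whole-database searching is sequential; there is no index structure.
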