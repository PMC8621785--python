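# Methods

## Model and definitions

A chain is an ordered list of residues with CA coordinates.  A *bridge*
is a loop-closing inter-residue bond; the backbone span it closes,
together with the bridge itself, forms a closed space curve — the
*covalent loop*.  The chain portions before and after the loop are its
N- and C-terminal *tails*.  A *piercing* is a transversal crossing of a
tail through a surface spanned on the loop; its sign records the
crossing direction relative to the surface orientation.  The motif
classification (`L0`, `Ln`, `LSn`, `LLi,j`, `LLSi,j`, with minor labels
carrying signs and the piercing tail) depends only on the ordered signed
crossing sequences of the two tails, so the geometric pipeline's sole
job is to get those sequences right.

## Structure input and gap modelling

PDB and mmCIF files are parsed with gemmi; a plain `index x y z` text
dialect covers generic polymers.  Residues are renumbered 1-based and
sequential; author numbering is retained as metadata.  For alternate
conformations the highest-occupancy altLoc of each atom is kept;
insertion-coded residues are simply renumbered in file order.  Chains
with fewer than 4 CA atoms, and HETATM-only chains, are skipped.

Gaps (jumps in author numbering) are modelled as straight intervals:
*g* missing residues become *g* virtual residues equidistant on the
segment between the flanking CAs, in the working coordinates and in
every NMR model alike.  The operation is idempotent and the gap records
survive so the validity check can consult them.  Straight-interval
modelling is deliberately minimal: it restores chain contiguity without
inventing structure, and the validity rules below flag the cases where
it could change the topology.

## Bridge detection

Disulfides are detected geometrically: CYS SG–SG pairs within 2.5 Å
(covalent S–S is ≈ 2.05 Å; the margin tolerates poorly refined models;
configurable).  Non-disulfide bridges are accepted **only** from
explicit LINK/struct_conn records between two residues of the same
chain with at least one side-chain atom, because distance-inferred
non-disulfide bonds in deposited files are frequently artefactual.  The
chemistry is inferred from the element pair: N–C → amide, C–O → ester,
C–S → thioester, C–C → CC, S–S → disulfide.  Files rarely carry the
information needed to separate amide/amine, ester/ether or
thioester/thioether (keto-oxygen context), so the primary label of each
family is reported.  A `permissive` switch additionally infers bonds
from side-chain heavy-atom pairs ≤ 1.8 Å apart, for files without
connectivity records.  Sequence-adjacent residue pairs (peptide bonds)
are never bridges.  Bridges spanning fewer than 4 residues close no
usable loop and are dropped.

## Validity

A loop's lasso assignment is *certain* unless: a gap of more than 2
missing residues (configurable) lies inside the loop span; any gap lies
within 3 residues of a detected piercing segment; or a CYS carrying the
bridge lacks its SG atom.  These thresholds are this package's declared
defaults, chosen so that a short modelled gap far from the action cannot
flip a classification, while anything near a piercing — where a straight
interval could cross the surface differently than the real chain —
demotes the result to the *artifact* class.

## Spanning surface

The initial surface is a centroid fan over the loop's CA polygon, closed
across the bridge edge.  Triangles are wound so their normals follow the
right-hand rule of the loop traversed in increasing residue order;
every piercing sign is defined against these normals.  One refinement
round splits edges longer than `max_edge` (default: the mean boundary
edge length) at their midpoints.  Interior vertices are then relaxed
toward minimal total area by L-BFGS-B on the exact area objective with
its analytic gradient (for triangle *(v, p, q)*, ∂A/∂v = ½ n̂ × (q −
p)); the boundary stays bitwise fixed, the line search makes the area
monotone non-increasing, and iteration stops when the relative area
change falls below `rel_tol` (default 1e-4) or after `max_iter` sweeps
(default 200, then flagged unconverged).  Exact minimality is not the
goal — the piercing calculus needs the surface's topology, not its
geometry — so the scheme favours determinism and robustness.  Planar
loops are left exactly planar (the fan is already minimal), which is
what makes the synthetic fixtures exact oracles.

## Crossings and reduction

Each tail is walked outward from the loop; every CA–CA segment is tested
against every triangle with signed-volume orientation predicates.  A
crossing requires a strict sign change of the endpoint volumes plus a
barycentric containment test; crossings exactly through shared mesh
edges or vertices are accepted by every incident triangle and merged by
parametric position, so they count once.  A tail point lying exactly in
a triangle's plane (volume below 1e-12 of the cubed coordinate scale)
crosses nothing — this deterministic rule handles the tangential
contacts that arise systematically where a tail leaves the loop
boundary, without random jitter.  The sign is `+` when the chain
direction (increasing residue index) agrees with the local normal; for
the N-tail, whose outward walk opposes the chain direction, the
geometric sign is flipped accordingly.  A global `flip_signs` switch
mirrors the whole convention: the convention here is internally
consistent but, absent an external calibration structure, could be
globally mirrored relative to other lasso tools, so every "negative
piercing" statistic is convention-relative.

Reduction applies two rules until stable: adjacent opposite-sign
crossings whose intersection points lie within `cancel_eps` = 2 Å and
whose segments are within `cancel_sep` = 1 residue annihilate pairwise
(they are wobble of the discrete surface, not topology), and a crossing
with fewer than `min_tail_depth` = 3 residues of tail beyond it is too
shallow to be meaningful.  All three are configurable; the defaults are
small so that genuine shallow threading is kept wherever defensible.
Piercings by the loop's own span are not part of the nomenclature
(types attribute piercings to tails only) and the loop polygon coincides
with the surface boundary, where the tangential-contact rule applies.

## Nomenclature details

The sign shown in `Ln` and `LL` minor labels is that of the rank-1
(loop-proximal) piercing of the tail.  Supercoiled tails are written
with their full sign string (`LS3++-C`); in two-sided labels each tail
token is sign+count when alternating and count+signs when supercoiled
(`LLS2--,+2`), N-tail first.  Fingerprints compress only *consecutive*
runs of identical majors (`2L1`), leaving non-consecutive duplicates
expanded.  Fingerprint strings are inherently ambiguous as a grammar
(`L1L2L12L2`); the parser resolves them by backtracking recursive
descent that prefers single-digit counts and short multiplicities, which
reads composite strings the way they are conventionally written.  The
evolution-flower neighbourhood of a major type applies a move — append
or remove one terminal sign, or append an opposite-sign pair (a
slipknot threaded through the loop) — to every minor subtype of that
major and collects the resulting labels; a same-sign triple winding is
therefore never a slipknot product of a single piercing.

## Stabilisation scoring

Bulkiness is the windowed mean (window 5, odd, configurable) of
standard residue volumes (Zamyatnin-style consensus table, bundled);
unknown codes take the mean volume.  Windowed-mean profiles produce
plateaus, so extrema are strict-neighbour extrema with the plateau
midpoint rule.  Flexibility uses the CA B-factors (windowed mean) or,
for multi-model ensembles, the per-residue mean square deviation of CA
positions about their mean after least-squares (Kabsch) superposition of
every model onto the first — superposition removes the trivial rigid
drift between models that would otherwise masquerade as flexibility.
The reported statistic is the sequential distance from the piercing
residue (first residue of the piercing segment) to the nearest
bulkiness maximum / flexibility minimum; small distances indicate a
mechanically caged, likely functional piercing.

## Conservation

Alignments are consumed precomputed (FASTA or Clustal, via Biopython);
the module never aligns.  Near-duplicate rows are removed greedily at
≥ 95 % pairwise identity (matches over columns aligned in both rows).
Bridge conservation is the fraction of rows with `C` at each bridge
column, gaps counting against, with the full row count as denominator;
classes are high (> 0.80 both), poor (< 0.30 either), else medium, both
inequalities strict — (0.80, 0.80) is medium.

## Synthetic data

`make_lasso_fixture` realises any minor label as a deterministic chain:
the loop is a regular planar polygon (12 residues, 3.8 Å spacing by
default) closed by a synthetic disulfide whose SG atoms sit between the
terminal CAs; each prescribed crossing is a vertical pass through the
loop interior at laterally separated points (3 Å apart, ≥ 2 Å so the
wobble-cancellation radius cannot merge them), consecutive same-sign
crossings wrap around the outside of the loop, and every tail ends with
enough padding residues that no prescribed crossing is shallow.  Because
the loop is planar the minimal surface is the flat polygon and the
crossing sequence is known exactly — the fixtures are ground truth for
the whole pipeline, which the test suite exercises for every minor
label with up to three piercings.  Labels needing more crossings than
fit inside the polygon raise an error suggesting a larger loop.

`sample_ideal_chain` draws closed equilateral random loops (alternating
projection: remove the mean step, renormalise to unit length, iterate to
1e-13) with freely jointed unit-step tails — the standard
no-volume/no-interaction ideal-chain null model.  It is adequate for
property tests and Monte-Carlo trends (piercing probability grows with
tail length); it is not claimed to sample the exact uniform closed-
polygon measure.

What the fixtures do **not** emulate: side chains beyond the bridge SG,
excluded volume, real secondary structure, non-planar loops with
self-intersecting surfaces, or crystallographic noise.  Passing the
round-trip suite therefore certifies the sign/tail/reduction calculus
and the nomenclature, not the geometric robustness on every pathological
deposited structure.

## Numerical choices and limitations

- Orientation predicates use double precision with a relative tolerance,
  not exact arithmetic; contacts within 1e-12 of degeneracy are treated
  as tangential.  Coordinates from real files (3 decimal places, Å) are
  far from this regime.
- The surface is approximately minimal; a strongly non-minimal surface
  could in principle report cancelling crossing pairs, which is exactly
  what the wobble-cancellation rule absorbs.
- Multi-chain entanglement, bridge-through-loop piercing (the cysteine-
  knot bridge case), link/Hopf detection between loop pairs, and any
  formal topological invariant are out of scope; the fingerprint does
  not characterise chain topology unequivocally.
- Survey statistics are convention-relative in sign and make no attempt
  at redundancy reduction; representative-set construction is upstream
  of this package.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated
data: the exhaustive round-trip covers all 49 minor labels with ≤ 3
piercings (12-residue loops), the crossing oracle uses 200 random
planar loops of 6–12 vertices, the ideal-chain trend uses 150 samples
per tail length at loop length 10, and the surface checks use 16–24
vertex boundaries.  These sizes were chosen as the smallest at which
each property is unambiguous.
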