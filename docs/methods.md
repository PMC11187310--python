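# Methods

## Scope and model

`compknot` decides the knot type of open or closed 3D polylines
(protein Cα traces), localizes the minimal knotted cores along the
sequence, and flags composite chains (two disjoint cores whose
invariants multiply to the global ones) and slipknots (knotted subchain,
unknotted whole). Everything downstream — the domain-architecture
screen, the interface area, the gene-arrangement taxonomy — is ordinary
data analysis layered on that engine.

The package treats knot typing as a statistical measurement, not a
single topological fact: an open chain's knot type depends on how the
termini are joined, so the reported label is the majority over many
random closures together with its supporting fraction. This matches
standard practice for protein knot annotation.

## Knot engine

**KMT reduction.** A vertex is deleted when the triangle spanned with
its two neighbours is pierced by no other segment of the chain; deleting
it is then an ambient isotopy. Sweeps run until stable. The
implementation tests all vertices against all segments in one vectorized
Möller–Trumbore pass per sweep and removes a pairwise non-adjacent
subset; within a sweep each accepted removal's replacement chord is
checked against the other accepted triangles, so simultaneous removals
cannot interact. The piercing test is conservative (tolerance 10⁻⁹ on
the barycentric and segment parameters; near-boundary and near-parallel
hits count as piercing), so a vertex is removed only when clearly safe.
Endpoints of open chains are never removed; closed chains stop at 3
vertices. Exact duplicate points are cleaned with a warning.

**Closure.** Three strategies:

- `direct`: join last to first point (one deterministic closure).
- `sphere_random` (default): draw one uniformly random direction,
  translate both termini by twice the chain's bounding-sphere radius
  along it, and join the two far points. Their connecting chord is a
  translate of the first–last chord far outside the chain, so the join
  itself cannot thread the structure. Extending both termini along a
  *common* direction is deliberate: with independently chosen endpoint
  directions the closure arc re-threads trimmed subchains often enough
  to blur knotted-core boundaries by several residues.
- `two_ray`: extend each terminus along its terminal segment direction
  to the sphere, then join outside (deterministic).

Defaults: 100 closures, sphere radius factor 2.0, seed mandatory.

**Invariants.** Each closed curve is projected along a deterministic
seeded sequence of directions until a generic diagram is found (up to 25
attempts; rejections: crossings within 10⁻⁶ of each other or of segment
endpoints, ambiguous over/under depth, properly overlapping parallel
segments). From the crossings and arcs the Alexander matrix is built via
Fox calculus on the Wirtinger relations (rows (1−t, t, −1) or
(1−t, −1, t) by crossing sign); one row and column are deleted and the
determinant D(t) = ±t^k Δ(t) is evaluated at t = −1 and t = −2 with
fraction-free Bareiss elimination over Python integers — never floating
point, because the classification is a lookup of exact values. The
monomial unit t^k is stripped by exact Newton interpolation of D when
D(0) = 0. The label table covers 0₁, 3₁, 4₁, 5₁, 5₂, 6₁, 6₂, 6₃ and the
composite 3₁#3₁:

| pair | label | pair | label |
|------|-------|------|-------|
| (1,1) | 0₁ | (9,20) | 6₁ |
| (3,7) | 3₁ | (11,59) | 6₂ |
| (5,11) | 4₁ | (13,67) | 6₃ |
| (5,31) | 5₁ | (9,49) | 3₁#3₁ |
| (7,16) | 5₂ | | |

All pairs were derived from the tabulated Alexander polynomials cleared
of monomial units and are independently confirmed in the test suite by a
reduced-Burau oracle on braid-word closures. Any pair outside the table
is reported as `unresolved(det1,det2)`. The determinant is blind to
chirality, so the composite label never distinguishes granny from square
knots — consistent with surveying |Δ|-based annotations.

**Call threshold.** A majority label below `call_threshold` (default
0.5, strict majority) is demoted to unresolved.

## Core localization

The fingerprint evaluates the knot call on subchains over a grid of
(start, stop) positions at a stride (default 5 residues; spans below
3·stride are skipped; 20 closures per entry by default). Inside
`analyze_topology` the stride adapts as max(5, n/26) and entries use 10
closures, keeping the grid near a constant ~300 entries per chain —
chosen so a full analysis of a 200-residue chain runs in seconds on one
core. Region finding keeps grid entries whose call support reaches 0.7
(marginal calls just above the majority line usually come from closure
re-threading at a clipped boundary and under-cover the core), takes the
minimal such intervals, and keeps a smallest-first pairwise-disjoint
subset.

Each region is refined by bisection to single-residue resolution:
the left boundary is the largest start that keeps the subchain knotted
against a generously bracketed right end, and vice versa — each boundary
is measured with the opposite flank padded one stride outward, because
trimming both ends at once makes every call marginal and biases the
result outward. The bisection predicate additionally counts
near-majority unknot calls (knot fraction ≳ 0.42) as knotted: a single
finite-sample flip of a clearly knotted interval would otherwise lock
the search on a wrong boundary. Refined cores closer than 3 residues are
merged and re-called; if the located cores fail to account for the
global invariants (product rule), the flanks are rescanned once.

Composite and slipknot flags follow the definitions above; depth is the
residue distance from a core to its nearer terminus and is reported,
never thresholded. Knot cores measured this way are
closure-convention-dependent quantities; the package's planted-truth
generator defines them the same way (below), and the boundary agreement
achieved on synthetic chains (±5 residues) should not be read as a
guarantee for real proteins, whose cores can be shallower and noisier.

## Architecture screen

A registry entry per domain family carries its entanglement class
(knot/slipknot/both), the minimal knotted-core length (residues), and
`knots_per_domain` — 1.0 for self-contained knotted domains, 0.5 for
families whose domains pair up so that two copies form one knot (this is
what makes a four-copy tandem architecture a two-knot candidate while a
two-copy one is not). A protein passes when the expected knot count of
its registry domains of class knot/both reaches 2 and its length reaches
the sum of the minimal core lengths those knots require
(Σ min_core_length·knots_per_domain). The homology gate keeps candidates
whose best hit (lowest e-value) is strictly below the threshold
(default 10⁻³) *and* knotted; candidates with no hits are flagged
unknown rather than rejected, since the gate prioritizes modelling
effort rather than disproving a knot. Gene pairs are classified
fused / overlapping / adjacent / separated with a configurable adjacency
gap (default 50 nt — the exemplars in scope are 11 nt apart versus
thousands, so any cutoff in that wide gap behaves identically; 50 nt is
a typical operon-spacing scale).

## Interface area

SASA by Shrake–Rupley sampling: a deterministic Fibonacci lattice of
960 points per atom (probe 1.4 Å, NACCESS-style radii: C 1.87, N 1.65,
O 1.40, S 1.85, P 1.80, H 1.00, default 1.80 Å), neighbour search with a
k-d tree. The buried area is the exact arithmetic identity
B = SASA₁+SASA₂−SASA₁₂; totals use compensated summation so swapping the
partners is exactly symmetric. The fixed point set does not rotate with
the molecule; measured rigid-motion variation at 960 points is below
0.1%, and halving/doubling the sampling changes totals by <0.5% on a
50-atom cluster. Lee–Richards slicing would serve equally; any
consistent SASA satisfies the identity, and the analytic one- and
two-sphere closed forms bound the numerical error in the tests (1% and
2% respectively).

## Synthetic data

Knotted arcs are cut from the (2,q) torus-knot parametrization (ring
radius 10, tube 4 before scaling; q = 3 or 5). For p = 2 the planar
projection's crossings sit where cos(qt) = 0, so the generated arc spans
from the first to the last crossing plus a 0.1 rad margin; termini dive
below (or climb above) the knot body's z-range before escaping radially,
so tails and spacers cannot thread a core. The assembled body is scaled
so resampling to `n_points` gives Cα-like 3.8 Å spacing; helical tails
(default 20 residues per terminus) and Gaussian coordinate noise
(default σ = 0.2 Å) are added last. Above σ ≈ 1 Å the planted-label
guarantee degrades.

The **planted core interval** is computed geometrically (engine-free)
as the median, over 48 projection directions, of the outermost-crossing
residue bracket of the noiseless knotted arc. The median is the right
statistic because a stochastic closure can substitute for crossings
outside a trimmed subchain in roughly half of the directions: the
minimal subchain that stays knotted under *majority* closure is the
direction-median bracket, not the single-projection one (which
overstates the core by ~5 residues at each end).

Connected sums place two summands along an axis (rotated/mirrored so
entry and exit face each other) joined by a straight spacer of ≥ 10
points. The slipknot construction lays a complete trefoil arc, then
doubles back alongside itself (1.6 Å radial offset) past two of the
three crossings before escaping at the outer equator: the forward
subchain is a trefoil, the full chain is unknotted. Closed reference
curves come either from the torus parametrization or from geometric
braid closures (crossings as over/under bridges; return arcs layered far
below the braid body realize the trace closure); the braid words for
3₁ through 6₃ and the granny knot are frozen in `BRAID_WORDS` and
verified algebraically in the tests.

Annotation fixtures plant candidate architectures (adequate length,
significant knotted hit) among decoys that each fail exactly one gate —
no entangled domains, one only, too short, insignificant e-value, or an
unknotted best homolog. What the generator does *not* emulate: real
domain-boundary uncertainty, partially disordered termini, shallow
knots whose cores approach the chain ends, and correlated (non-Gaussian)
coordinate error of real predicted models — so green tests here validate
the machinery, not database-scale survey accuracy.

## Numerical choices and degenerate inputs

- All stochastic stages take an explicit integer seed; identical
  config + inputs give byte-identical outputs (closures, fingerprint
  entry seeds, and projection directions are all derived
  deterministically from it).
- Segment–triangle tolerance 10⁻⁹; diagram genericity tolerance 10⁻⁶;
  duplicate-point threshold 10⁻¹²; projection retry budget 25.
- Chains shorter than 3 residues are rejected; reduced open chains of
  < 3 points are unknots by definition.
- A chain whose residue numbering is not strictly increasing (insertion
  codes) is renumbered sequentially with a warning; altloc A/blank only;
  first model only.
- The pLDDT gate uses the chain *mean* against a default threshold of
  70 and can be overridden (`force`); a chain without B-factor-derived
  confidence passes with a warning.

## Problem sizes

Defaults were sized for interactive use on one core: single-knot
fixtures of ~120 residues and double-knot fixtures of ~210 residues
analyse in roughly 2 s and 4 s respectively; the bundled acceptance
script measures reduction invariance over 40 noisy curves and core
recovery over 30 fixtures, and the test suite runs the same checks at
100/100.

## Known limitations

- No nested knots ("knot inside a knot"), no links between chains, no
  θ-curves/lassos, no HOMFLY/Jones invariants, and no chirality calls —
  the determinant pair cannot make them.
- Knots outside the lookup table surface as `unresolved(d1,d2)` rather
  than a type.
- Slipknot detection is anchored on the fingerprint grid; a slipknot
  whose knotted subchain falls entirely between grid lines can be
  missed at coarse strides.
- The screen's length filter counts only knotted-core lengths, not
  inter-domain linkers; it is a necessary-condition filter, not a
  structure predictor.
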