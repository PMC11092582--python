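# Methods

cavscan quantifies the *shape* of protein–protein binding surfaces and
supports the downstream steps of a concave-binder optimization campaign.
This note documents the models, the parameters that matter, the synthetic
data the tests rely on, and the numerical choices made where the design was
genuinely open.

## Interface detection by dSASA

Solvent-accessible surface area (SASA) is computed per heavy atom with the
Shrake–Rupley method: each atom's van der Waals sphere is inflated by the
probe radius and covered with `n_points` test directions; a direction is
accessible if the test point lies outside every neighbour's inflated
sphere, and the accessible fraction times the inflated-sphere area is the
atomic SASA (Å²).

- **Probe radius**: 1.4 Å (water) by default.
- **Test points**: 960 by default, placed by a deterministic golden-spiral
  rule so a given input always yields bit-identical areas.  Convergence
  versus a 4000-point grid is under 2% on the test structures.  The fixed
  direction set makes areas exactly invariant under translation but only
  approximately invariant under rotation (quadrature-level changes, ~0.5%
  observed); interface *membership* is rotation-stable on all fixtures.
- **Radii**: a single heavy-atom vdW table (C 1.70, N 1.55, O 1.52, S 1.80,
  P 1.80 Å; 1.70 for anything else).  Different published radii sets shift
  absolute areas by a few percent, which is why area comparisons across
  tools need tolerance.
- **Neighbour search** uses a k-d tree over atom centers; the result is
  identical to the all-pairs computation (tested exactly).

An atom is *interfacial* when its SASA drops by at least a threshold on
complex formation: `dSASA = SASA(partner alone) − SASA(in complex)`, with
the threshold at **0.5 Å² per heavy atom**.  Because the test directions
are identical in the apo and holo evaluations, dSASA is non-negative by
construction (clamping is a no-op safeguard).  Buried surface area (BSA) is
the sum of dSASA over both partners — the *sum-both-partners* convention,
with a `half` option — decomposed into polar (N/O) and apolar (everything
else) contributions.  The identity
`BSA = SASA(apo A) + SASA(apo B) − SASA(complex)` holds to 1e-6 and is
asserted in the tests.

## Signed convexity from RANSAC sphere fits

The curvature of a binding surface is summarized by one number: the signed
reciprocal radius (1/Å) of a sphere fitted to the interfacial heavy atoms.

**Fitting.** Random 4-point samples propose exact spheres (linearized
3×3 system; quadruples with condition number above 1e8 are rejected as
near-coplanar).  The candidate with the most points within the **inlier
threshold (1.0 Å)** of its surface wins; ties break toward lower inlier
RMS.  Iteration stops at `min(100 000, adaptive bound)` where the adaptive
bound is the classic 99.9%-confidence formula from the best inlier ratio.
By default the consensus set is refit with the algebraic least-squares
sphere (solving `[2p | 1][c; k] = |p|²`), accepted only when it keeps at
least as many inliers; the result records whether refitting happened.
Identical seeds give bit-identical fits.

**Sign.** With g_int the centroid of the interfacial atoms, g_body the
centroid of all heavy atoms of the protein whose surface is assessed, and
c the fitted center, the sign of

    (g_body − g_int) · (c − g_int)

decides the class: positive means the sphere center lies behind the
surface, inside the body — a convex bulge, convexity `+1/R`; negative means
the center sits on the solvent side — a concave pocket, `−1/R`.  The body
defaults to the partner being assessed (a `complex` option uses all
chains).  Fits are classed **flat** (convexity 0) when `1/R < 1e-4 1/Å`
(equivalently R at or beyond the 10 000 Å cap — a reported curvature of
0.001 1/Å, R = 1000 Å, stays representable) or when the dot product is
angularly ambiguous (|dot| < 1e-3·‖v₁‖‖v₂‖).

The end-to-end entry point chains detection and fitting and requires at
least `min_interface_atoms` (default 10) interfacial atoms — four points
determine a sphere, but ten is the practical floor below which the
consensus is meaningless for a molecular surface patch.

## Scaffold concave-face screening

Candidate scaffolds for concave binders are five-helix bundles whose
helices 1, 3 and 5 (in chain order) form the binding face.  Helices are
detected from backbone dihedrals (φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°],
runs ≥ 5) when N/CA/C atoms are present, else from the Cα-distance
signature of an α-helix (d(i,i+2) ≈ 5.4 Å, d(i,i+3) ≈ 5.1 Å); runs are
additionally split at chain breaks (consecutive Cα > 4.5 Å apart), so
back-to-back helical segments count separately.

The face point set holds heavy atoms of the named helices that are
solvent exposed — atomic SASA over the isolated-atom area
`4π(r+probe)²` at least **0.25** — and that lie on the face side of their
*own helix's local axis* (smoothed Cα positions over a ±2-residue window),
where "face side" is the direction from the buttressing helices' centroid
toward the face helices' centroid.  The per-helix local-axis test selects
the face-side monolayer of each helix; a single plane through the whole
bundle would also admit atoms on the far sides of the flanking helices and
bias the fit flat.  The selected atoms are RANSAC-fitted and signed against
the whole scaffold; `is_concave` supports filtering (concave faces kept,
convex ones discarded).

## Survey: clustering and the partner-convexity relationship

To de-redundify many complexes, chain pairs are clustered greedily at a
**40% sequence-identity threshold applied to both chains** against a
cluster representative.  Identity comes from a global Needleman–Wunsch
alignment (match +1, mismatch 0, gap −1; deterministic diagonal-first
traceback; `X` never matches; terminal gap columns excluded from the
denominator).  Records are visited in (resolution, total length, input
order), which makes the clustering independent of input shuffling and
makes representatives the best-resolved, shortest members.  The survey then
computes both partners' convexities per complex and reports Pearson and
Spearman correlations; geometric complementarity makes the two signed
convexities strongly negatively correlated on matched interfaces.  This
module operates on any user-supplied structure list; it does not harvest
or mirror structure databases.

## SSM analysis and codon design

Deep-sequencing count tables (positions × 20 amino acids, selected vs
reference pool) are converted to log2 enrichments

    E(i, aa) = log2[ ((c_sel + pc) / N_sel) / ((c_ref + pc) / N_ref) ]

with pseudocount `pc = 1` and `N` the pseudocount-inclusive total over the
whole table.  Per-position conservation is the Shannon entropy (bits) of
the selected-pool frequencies, bounded by [0, log2 20 ≈ 4.32].  Both the
base and the pseudocount are configurable and recorded; computing entropy
from selected-pool frequencies (rather than from enrichment values) is a
documented choice, not a community standard.

Degenerate codons are chosen by exhaustive search over all 15³ = 3375
IUPAC triplets under a total order: covers the wish-list → fewest undesired
distinct amino acids → stop-free (when stops are forbidden) → smallest
expanded codon count → lexicographic.  Note the order puts *fewest extras*
ahead of *stop-free*: a triplet with two extras and a stop beats one with
three extras and no stop.  Some wish-lists have no exact encoding at all
({F,Y,W} forces a TAG stop because Y needs A and W needs G); the result is
then flagged inexact.  Library sizes use exact big-integer arithmetic.
Only the standard genetic code is supported.

## Synthetic fixtures: what they emulate and what they do not

All generators are seeded and embed their ground truth in the returned
object's metadata.

- **Ideal helices**: 1.5 Å rise, 100° twist, 2.3 Å Cα ring (≈3.8 Å Cα–Cα).
  The backbone mode builds N/CA/C/O from ideal internal coordinates
  (φ −57°, ψ −47°, ω 180°) so dihedral-based assignment sees real angles.
- **Concave bundles**: the three face helices are wound around great-circle
  arcs so their face-side atoms lie near a sphere of the requested radius
  (ground truth κ = −1/R, or +1/R for the mirrored convex construction);
  two buttressing helices sit 9 Å behind, helices packed antiparallel at
  10.5 Å spacing.  Radii are accepted in [10, 5000] Å.  Face-curvature
  recovery is accurate at design-relevant radii (3% at R = 15 Å, 1% at
  R = 30 Å) and degrades for shallow faces (R ≳ 60 Å) where the face
  sagitta falls below the 2.3 Å thickness of the Cα monolayer.
- **Cap clouds**: uniform samples over a spherical cap (default half-angle
  60°) with isotropic Gaussian noise plus uniform box outliers — the
  controlled testbed for RANSAC recovery (median curvature error < 1% at
  0.3 Å noise and 20% outliers, over radii 15–200 Å).
- **Toy dimers**: a convex knob cap (sphere R, default 12 Å) inside a
  complementary socket cap 4 Å + gap further out, each backed by body
  shells, with 0.3 Å coordinate noise by default.  Small gaps produce a
  genuine dSASA interface; 50 Å separations produce none.

Fixtures are Cα-only with carbon radii (one atom per residue).  They have
no side chains, no sequence diversity, no polar/apolar texture, no
B-factors or altlocs, and ideal secondary structure, so passing tests
demonstrate the geometric machinery — detection thresholds, fit recovery,
sign classification — not robustness to real crystallographic artifacts or
chemically realistic surface composition.  On real structures, absolute
BSA and convexity values additionally depend on radii set, probe, and
altloc/water handling, all of which are exposed as options and recorded in
the outputs.

## Problem sizes

The test suite and the reproduction script run on fixture-scale inputs:
toy dimers of ~310 atoms, 100-atom bundles, 300-point cap clouds, 50
seeded dimer instances for the sign-rate estimate and 20 for the
correlation summary, 200 random wish-lists against all 3375 triplets, and
100 random sequence pairs for the alignment checks.  These sizes give
stable statistics (the reported rates and medians move by well under their
test tolerances across seeds) while keeping a full run in minutes on one
core.

## Known limitations

- No molecular (Connolly) surface or mesh curvature; the sphere is the
  only shape model, by design.
- Structure input is PDB/mmCIF read through gemmi; output is PDB only.
  No symmetry expansion, no density handling.
- Secondary-structure assignment distinguishes helix from non-helix only.
- The greedy clustering is quadratic in the number of records; it targets
  curated sets, not database-scale redundancy removal.
- Altloc handling keeps the highest-occupancy conformer (ties toward 'A');
  waters and hetero groups are dropped unless kept explicitly.  How such
  choices were made in other tools' curvature pipelines is generally
  unstated, so cross-tool comparisons should use tolerant thresholds.
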