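# cavscan

Shape analysis of protein–protein interfaces for concave-binder design.

Most designed miniprotein binders engage flat or concave target sites;
binding a *convex* site — a knob, a protruding loop, the edge of a β-sheet —
requires a binder whose interface wraps around the target.  Deciding which
surfaces are convex, how concave a candidate scaffold's face is, and
whether a designed pair is shape-complementary all reduce to the same
measurement: the signed curvature of a binding surface.

cavscan measures it in three steps:

1. **Interface detection.**  Per-atom solvent-accessible surface area
   (Shrake–Rupley, 1.4 Å probe) is computed for each partner alone and in
   the complex; heavy atoms losing ≥ 0.5 Å² are interfacial
   (ΔSASA = SASA_apo − SASA_holo).  Buried surface area and its
   polar/apolar split come from the same bookkeeping.
2. **Sphere fitting.**  RANSAC fits a sphere to the interfacial atoms
   (1.0 Å inlier threshold, ≤ 100 000 iterations, seeded and
   reproducible), with a least-squares refit of the consensus set.
3. **Sign rule.**  The *convexity* is κ = ±1/R (1/Å): with g_int and
   g_body the centroids of the interfacial atoms and of the protein body,
   the sign of (g_body − g_int)·(c_sphere − g_int) is positive for a
   convex bulge (center inside the body) and negative for a concave
   pocket; near-flat fits (|κ| < 1e-4 1/Å) are classed flat.

Around this core the package provides: screening of five-helix scaffolds
for concave faces (keep concave, filter convex), a survey mode that
clusters chain pairs at 40% sequence identity and correlates partner
convexities, site-saturation-mutagenesis analytics (log2 enrichment
matrices, per-position Shannon entropy), degenerate-codon design by
exhaustive search over all 3375 IUPAC triplets, Kabsch superposition /
Cα RMSD, and seeded synthetic generators (helices, curved bundles, cap
clouds, knob–socket dimers) with embedded ground truth.

See `docs/methods.md` for the full model description and parameter
rationale.

## Worked example

```python
from cavscan import buried_surface_area, find_interface, interface_convexity
from cavscan.fixtures import make_toy_dimer

dimer = make_toy_dimer(contact_gap=0.5, radius=12.0, seed=1)  # knob A, socket B
iface = find_interface(dimer, {"A"}, {"B"})
bsa = buried_surface_area(iface)
knob = interface_convexity(dimer, ["A"], ["B"], seed=1)
sock = interface_convexity(dimer, ["B"], ["A"], seed=1)
print(len(iface.interface_atoms_a), len(iface.interface_atoms_b))
print(round(bsa.total, 1), round(knob.convexity, 4), round(sock.convexity, 4))
```

prints

```
38 71
1284.0 0.087 -0.0603
```

38 knob atoms and 71 socket atoms lose ≥ 0.5 Å² on binding; the interface
buries 1284 Å² in total (both partners summed).  The knob's surface is
convex with κ = +0.087 1/Å and the socket concave with κ = −0.060 1/Å —
close to the generating spheres (12.0 Å and 16.5 Å, i.e. +0.083 and
−0.061 1/Å) and opposite in sign, as shape complementarity requires.

The same analysis from the shell:

```bash
cavscan fixtures dimer --seed 1 -o dimer.pdb
cavscan convexity dimer.pdb --partners A:B --seed 1
cavscan fixtures bundle --face-radius 15 -o bundle.pdb
cavscan scaffold-face bundle.pdb          # -> {"verdict": "pass", ...}
```

`examples/` holds one short narrative script per capability (interface
shape, scaffold screening, sphere fitting, the convexity survey, SSM
analysis, codon design); each prints the numbers it computes and what they
mean.

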