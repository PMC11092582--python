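"""Site-saturation mutagenesis enrichment and conservation.

Simulates an SSM selection over an 8-residue stretch: two positions are
strongly constrained (the parent residue dominates the selected pool), the
rest tolerate substitutions.  Prints the log2 enrichment extremes and the
per-position Shannon entropy used to color conservation.
"""

import numpy as np

from cavscan.libtools import AA20, position_entropy, ssm_log_enrichment

rng = np.random.default_rng(0)
parent = "MKTAYIAK"
ref = rng.integers(80, 120, (len(parent), 20)).astype(float)  # even input library

sel = ref.copy()
for i, aa in enumerate(parent):
    if i in (2, 5):  # conserved hot-spot positions: selection keeps parent only
        sel[i, :] = 2.0
        sel[i, AA20.index(aa)] = 2000.0
    else:  # tolerant positions: mild noise around the input
        sel[i] = ref[i] * rng.uniform(0.5, 2.0, 20)

ssm = ssm_log_enrichment(sel, ref, pseudocount=1.0)
entropy = position_entropy(ssm)

print("pos parent  entropy(bits)  most-enriched  most-depleted")
for i, aa in enumerate(parent):
    row = ssm.enrichment[i]
    up, down = AA20[int(row.argmax())], AA20[int(row.argmin())]
    print(f"{i + 1:3d}   {aa}       {entropy[i]:5.2f}        "
          f"{up} ({row.max():+.2f})      {down} ({row.min():+.2f})")

print()
print("Low entropy (near 0 bits) marks positions the selection conserves —")
print("candidate hot spots; high entropy (up to log2 20 = 4.32 bits) marks")
print("positions free to vary in a combinatorial library.")
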