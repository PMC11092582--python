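"""Degenerate-codon design for a combinatorial binder library.

For each position's amino-acid wish-list, search all 3375 IUPAC triplets
for the codon that covers the wish-list with the fewest extra amino acids
(stop codons penalized) and the smallest codon count; then compute the
library size.  {F,Y,W} shows an inexact case: no triplet covers all three
aromatics without extras, because Y forces A and W forces G into the codon.
"""

from cavscan.libtools import design_degenerate_codon, library_size

wishlists = [
    {"M"},                 # fixed position
    {"D", "E"},            # conservative acidic swap
    {"D", "G", "N", "S"},  # small/polar set with an exact encoding
    {"F", "Y", "W"},       # aromatics: only approximable
    {"K", "R"},            # basic pair
]

print("wish-list        codon  encodes        codons  stop?  exact?")
for aas in wishlists:
    dc = design_degenerate_codon(aas)
    print(f"{'/'.join(sorted(aas)):15s}  {dc.iupac_triplet}    "
          f"{'/'.join(sorted(dc.encoded_aa_set)):13s}  {dc.codon_count:4d}    "
          f"{str(dc.contains_stop):5s}  {dc.is_exact}")

n_protein, n_dna = library_size(wishlists)
print()
print(f"library size: {n_protein} protein variants from {n_dna} DNA variants")
print("(exact encodings keep the DNA library no larger than the protein one,")
print("so transformation capacity ~1e7 is spent on wanted variants)")
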