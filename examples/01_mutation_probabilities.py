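"""Per-motif mutation probabilities under BLOSUM62.

P_m(M) = 1 - prod_i P(M[i]), where P(x) is the share of residue x's
strictly positive substitution scores held by its diagonal. A high P_m
means the motif readily mutates into substitutable variants; P_m = 0
means every residue's only positive score is staying itself.
"""

from ddsm import load_matrix, motif_mutation_prob, residue_conservation, truncate

matrix = load_matrix("BLOSUM62")

print("residue conservation probabilities:")
for residue in "LKGIV":
    print(f"  P({residue}) = {residue_conservation(matrix, residue):.4f}")

print("\nmotif mutation probabilities (printed at truncated 2-decimal precision):")
for motif in ["LLK", "IMK", "VMK", "GGP", "RI", "RV", "RA", "PP"]:
    pm = motif_mutation_prob(motif, matrix)
    print(f"  P_m({motif:<3}) = {pm:.5f}  -> prints {truncate(pm):.2f}")
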