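"""Clustering substitutable motifs into main-motif clusters.

Nine motifs collapse into five clusters at threshold T = 0.5 under
BLOSUM62: each motif is assigned to the substituting motif of highest
mutation probability, and filtering keeps one main motif per cluster.
Note RV: it is absorbed by RI's cluster yet heads the cluster holding RA,
so it appears in two clusters and is the main motif of one of them.
"""

from ddsm import cluster_motifs, filter_main_motifs, load_matrix

matrix = load_matrix("BLOSUM62")
motifs = ["LLK", "IMK", "VMK", "GGP", "RI", "RV", "RF", "RA", "PP"]

clustering = cluster_motifs(motifs, matrix, t=0.5)

print("motif -> main motif:")
for motif, main in clustering.main_of.items():
    print(f"  {motif:<4} -> {main}")

print(f"\n{len(clustering.clusters)} clusters:")
for main, members in clustering.clusters.items():
    print(f"  {main}: {{{', '.join(sorted(members))}}}")

retained = filter_main_motifs(clustering)
print(f"\nretained features after filtering: {retained}")
print(f"({len(motifs)} motifs reduced to {len(retained)} features)")
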