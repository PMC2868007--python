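"""Encoding labeled sequence families: DD vs DDSM feature tables.

A synthetic two-family set is generated with one implanted 6-residue
motif per family; half of the implants are replaced by substitutable
variants. The discriminative-descriptor (DD) encoder extracts both the
originals and the recurring variants as separate features; the
substitution-matrix encoder (DDSM) collapses each variant onto its main
motif, producing fewer features, and its substitute-aware context still
marks every sequence that carries a variant.
"""

from ddsm import (
    build_context,
    extract_dd,
    extract_ddsm,
    generate_fixture,
    load_matrix,
    write_arff,
)

matrix = load_matrix("BLOSUM62")
sequences, truth = generate_fixture(
    families=2, per_family=10, motif_length=6, variant_rate=0.5, t=0.8, seed=3
)
print("implanted motifs:", dict(truth.implanted))

dd = extract_dd(sequences, alpha=0.0, beta=0.0, min_length=6, max_length=6)
ddsm = extract_ddsm(sequences, alpha=0.0, beta=0.0, m=matrix, t=0.8,
                    min_length=6, max_length=6)
print(f"DD features   ({len(dd)}): {list(dd.features)}")
print(f"DDSM features ({len(ddsm)}): {list(ddsm.features)}")

context = build_context(sequences, ddsm, "substitute_aware", matrix, 0.8)
arff = write_arff(context, "synthetic_families")
print("\nfirst lines of the ARFF learning context:")
print("\n".join(arff.splitlines()[: len(ddsm) + 6]))
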