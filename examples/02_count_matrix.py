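"""From variant calls to the 96-category count matrix.

Builds a tiny in-memory cohort of single-nucleotide variants, classifies
each into its trinucleotide category against a toy reference, and prints
the resulting count matrix M.
"""

from sparsesig import MutationRecord, build_count_matrix, classify_mutation, filter_samples

reference = {"chr1": "AACGTACGTTACGGATCCA"}

print("single classifications (pyrimidine-centred, strand-collapsed):")
print("  C>T in A_G context :", classify_mutation("C", "T", "A", "G"))
print("  G>A in C_T context :", classify_mutation("G", "A", "C", "T"),
      " (reverse-complemented to the pyrimidine strand)\n")

records = [
    MutationRecord("tumor_A", "chr1", 3, "C", "T"),
    MutationRecord("tumor_A", "chr1", 7, "C", "G"),
    MutationRecord("tumor_A", "chr1", 5, "T", "A"),
    MutationRecord("tumor_B", "chr1", 9, "T", "C"),
    MutationRecord("tumor_B", "chr1", 13, "G", "A"),
]
matrix = build_count_matrix(records, reference)
frame = matrix.to_frame()
nonzero = frame.loc[:, (frame != 0).any()]
print("count matrix M (nonzero categories only):")
print(nonzero.to_string())
print("\nrow sums equal mutations per sample:", dict(zip(matrix.sample_ids, matrix.row_sums())))

kept, removed = filter_samples(matrix, min_mutations=3)
print(f"with a 3-mutation minimum, kept {kept.sample_ids}, removed {removed}")
print("(real cohorts use a 1000-mutation minimum per genome)")
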