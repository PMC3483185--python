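"""Internal correspondence analysis of tissue-labelled codon usage.

Builds a gene x 61-codon count table for seven tissues with a GC3
gradient, decomposes its chi-square inertia into the four
{between,within}-tissue x {between,within}-amino-acid components, and
tests the between-tissue within-amino-acid fraction (the share of
synonymous codon usage variability explained by tissue identity) against
a gene/tissue label-permutation null.
"""

from tissuecodon import (
    GeneticCode,
    build_usage_matrix,
    count_codons,
    decompose_inertia,
    default_config,
    elementary_ca,
    gen_codon_dataset,
    permutation_test,
    validate_cds,
)
from tissuecodon.ica_decomposition import blocked_from_usage

code = GeneticCode.standard()
records, labels = gen_codon_dataset(default_config(seed=11, n_genes_per_tissue=20))
vectors = [count_codons(validate_cds(r, code), code) for r in records]
table = blocked_from_usage(build_usage_matrix(vectors, labels, code), code)

decomp = decompose_inertia(table)
print(f"total inertia: {decomp.total_inertia:.4f}")
for key, frac in decomp.fractions.items():
    print(f"  {key[0]:>7}-tissue x {key[1]:>7}-AA : {100 * frac:6.2f} %")

perm = permutation_test(table, B=199, seed=3)
print(f"\nbetween-tissue within-AA fraction: {100 * perm.observed_fraction:.2f} %")
print(f"permutation null: {100 * perm.mean:.2f} +/- {100 * perm.sd:.2f} %  "
      f"(B = {perm.n_permutations}, p = {perm.p_value:.4f})")

panel_d = elementary_ca(table, "d")
print("\npanel-d Axis-1 tissue coordinates (ordered by the GC3 gradient):")
for tissue, coord in zip(panel_d.row_ids, panel_d.row_coords[:, 0]):
    print(f"  {tissue:>10}: {coord:+.4f}")
print("\nThe observed between-tissue synonymous fraction far exceeds the")
print("label-shuffle null, so codon usage genuinely depends on the tissue;")
print("Axis 1 orders tissues along the planted GC3 gradient.")
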