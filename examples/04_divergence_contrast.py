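"""NG86 dS/dN for ortholog pairs and the specific vs non-specific contrast.

Generates ortholog pairs in which the tissue-specific class carries more
synonymous and nonsynonymous substitutions than the non-specific class,
estimates per-pair dS and dN by Nei-Gojobori pathway counting with
Jukes-Cantor correction, and compares the two groups.
"""

from tissuecodon import (
    GeneticCode,
    align_proteins_global,
    default_config,
    gen_ortholog_pairs,
    group_contrast,
    ng86_pair,
    thread_codons,
    validate_cds,
)

code = GeneticCode.standard()
config = default_config(seed=5)
pairs, truth = gen_ortholog_pairs(config)
groups = dict(zip(truth["pair_id"], truth["class"]))

rates = []
for anc, der in pairs:
    a, b = validate_cds(anc, code), validate_cds(der, code)
    pid = a.gene_id[:-2]  # strip the _a suffix
    aln = align_proteins_global(a.translate(code), b.translate(code))
    rates.append(ng86_pair(thread_codons(aln, a, b, code, pair_id=pid), code))

contrast = group_contrast(rates, groups)
print(contrast.round(4).to_string(index=False))
print()
print("The tissue-specific class was generated with more substitutions,")
print("and the recovered group means preserve that ordering in both dS and")
print("dN; the rank-test p-value quantifies the separation.")
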