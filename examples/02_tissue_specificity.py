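"""SPM-based tissue-specificity classification on planted truth.

Generates an expression + detection matrix with planted tissue-specific
genes (high signal in one tissue) and broadly expressed genes, classifies
every gene with the two-rule criterion (SPM > 0.9 in exactly one tissue
AND transcript detected only there; non-specific = SPM < 0.4 everywhere),
and reports the confusion against the planted truth.
"""

import pandas as pd

from tissuecodon import classify_matrix, default_config, gen_expression_matrix

config = default_config(seed=7, n_genes_per_tissue=10)
expression, detection, truth = gen_expression_matrix(config)

pred = classify_matrix(expression, detection)
merged = truth.merge(pred, on="gene_id", suffixes=("_true", "_pred"))

print(pd.crosstab(merged["class_true"], merged["class_pred"]))
accuracy = (merged["class_true"] == merged["class_pred"]).mean()
print(f"\nrecovery of planted classes: {accuracy:.1%}")
print()
print("Each planted tissue-specific gene concentrates its expression in")
print("one tissue (SPM near 1 there), while broadly expressed genes sit")
print("near the uniform profile, whose SPM is 1/sqrt(7) ~ 0.378 < 0.4.")
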