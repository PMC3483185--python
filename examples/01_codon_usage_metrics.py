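"""Per-gene codon-usage metrics on a small synthetic tissue dataset.

Generates CDSs for two tissues with different GC3-ending codon
preferences, then prints ENC (codon-bias strength, 20 = maximal bias,
61 = uniform usage), CAI (similarity to a highly expressed reference
set), and positional GC content for a few genes.
"""

import numpy as np

from tissuecodon import (
    GeneticCode,
    SimulationConfig,
    TissueModel,
    build_usage_matrix,
    count_codons,
    gen_codon_dataset,
    metrics_table,
    reference_weights,
    validate_cds,
)
from tissuecodon.codon_core import CodonCountVector

code = GeneticCode.standard()
config = SimulationConfig(
    tissues=[
        TissueModel(name="root", n_genes=10, gc3_pref=0.73),
        TissueModel(name="seed", n_genes=10, gc3_pref=0.51),
    ],
    seed=42,
)
records, labels = gen_codon_dataset(config)
vectors = [count_codons(validate_cds(r, code), code) for r in records]
matrix = build_usage_matrix(vectors, labels, code)

pooled = CodonCountVector("pooled", np.sum([v.counts for v in vectors], axis=0))
weights = reference_weights(pooled, code)

metrics = metrics_table(matrix, weights, code)
print(metrics.head(6).round(3).to_string(index=False))
print()
print(metrics.groupby("tissue")[["ENC", "GC3"]].mean().round(3))
print()
print("High-GC3 'root' genes use G/C-ending codons more often, which the")
print("per-tissue mean GC3 shows directly; ENC stays well above 20 because")
print("both tissues still use several codons per amino acid.")
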