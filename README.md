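# tissuecodon

Analysis of tissue-specific synonymous codon usage in plant coding
sequences, built around the question: *does the choice among synonymous
codons depend on the tissue a gene is selectively expressed in, and if so,
how much of that variability is compositional (GC content) versus
selective?* The package targets rice-style datasets — a set of CDSs, a
gene × tissue expression matrix with transcript-detection evidence, and
ortholog pairs for divergence estimates — and ships a seeded synthetic-data
generator that emulates all of these inputs, so every analysis is testable
end to end without genome downloads.

## What it computes

**Codon-usage metrics** (`usage_metrics`): per gene, the effective number
of codons (Wright's ENC, in [20, 61]; 20 = one codon per amino acid),
the codon adaptation index CAI = (∏ᵢ wᵢ)^(1/L) over a gene's codons with
relative adaptiveness w from a highly expressed reference set, RSCU, and
GC1/GC2/GC3/GCall computed after excluding Met, Trp and stop codons.

**Tissue specificity** (`specificity`): the specificity measure
SPM_t = xₜ / ‖x‖₂ — the cosine between a gene's expression profile x and
the idealized single-tissue profile. A gene is *tissue-specific* when
SPM > 0.9 in exactly one tissue **and** its transcript is detected in only
that tissue; *non-specific* when SPM < 0.4 in every tissue.

**Internal correspondence analysis** (`ica_decomposition`): the gene × 61
sense-codon count table carries row blocks (tissues) and column blocks
(the 20 synonymous families). Its total chi-square inertia

&nbsp;&nbsp;&nbsp;&nbsp;Φ² = Σᵢⱼ (pᵢⱼ − rᵢcⱼ)² / (rᵢcⱼ)

splits additively into {between, within}-tissue × {between, within}-amino-
acid components via block condensation and Huygens subtraction. The
between-tissue × within-AA cell is the share of *synonymous* codon usage
variability attributable to tissue identity; a gene/tissue label
permutation test (default B = 1000, add-one p-value) provides its null.
Crossing {total, between, within} on both axes yields the nine elementary
correspondence analyses, each a weighted SVD with eigenvalues summing to
its inertia component.

**Divergence** (`evo_rates`): Nei–Gojobori (1986) counting for ortholog
pairs — synonymous/nonsynonymous site fractions per codon (stop changes
excluded from the denominator), pathway averaging over the d! orders of
d-position codon differences with stop-crossing pathways discarded, and
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) — plus the
tissue-specific vs non-specific group contrast (rank test). Protein-guided
codon alignment uses a global BLOSUM62 aligner.

**Statistics** (`stats_utils`): Spearman correlation with *exact*
enumeration p-values for tie-free n ≤ 9 (tissue-level correlations involve
only 7–8 points, where the t-approximation is unreliable).

## Worked example

```sh
python examples/03_inertia_decomposition.py
```

generates seven tissues of synthetic CDSs whose GC3-ending codon
preference spans 0.51–0.73 (the gradient observed across rice tissues) and
prints:

```
total inertia: 0.2863
  between-tissue x between-AA :   1.67 %
  between-tissue x  within-AA :  13.69 %
   within-tissue x between-AA :  33.77 %
   within-tissue x  within-AA :  50.86 %

between-tissue within-AA fraction: 13.69 %
permutation null: 2.75 +/- 0.42 %  (B = 199, p = 0.0050)
```

13.69 % of total codon-usage variability here is synonymous variation
*between* tissues; shuffling gene/tissue labels yields only ≈2.8 %, and no
permutation reaches the observed value (p = 1/(B+1)), so tissue identity
genuinely structures synonymous codon choice in this dataset. The panel-d
Axis-1 tissue coordinates printed afterwards order the tissues along the
planted GC3 gradient — the compositional driver of the effect.

Other examples: `01_codon_usage_metrics.py` (ENC/CAI/GC per gene),
`02_tissue_specificity.py` (SPM classification against planted truth),
`04_divergence_contrast.py` (dS/dN group contrast). A thin CLI wraps the
same library calls: `tissuecodon simulate|metrics|classify|ica|permtest|
rates|all` (see `tissuecodon --help`).

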