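# Methods

## The model and its assumptions

The package treats a gene's coding sequence as a bag of codons and asks
how synonymous codon choice co-varies with the tissue in which the gene is
selectively expressed. Three statistical layers implement this:

1. **Index layer.** Per-gene summaries of codon bias. ENC is Wright's
   estimator: for each amino acid *a* with nₐ ≥ 2 observed codons, the
   codon homozygosity Fₐ = (nₐ·Σpᵢ² − 1)/(nₐ − 1); class means F̄ₖ are
   taken over amino acids of equal degeneracy k ∈ {2, 3, 4, 6} (Fₐ ≤ 0 or
   nₐ < 2 excluded as uninformative), and ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
   3/F̄₆, capped into [20, 61]. A missing class mean is imputed with the
   unweighted mean of the available class means — a generalization of
   Wright's single-Ile rule that stays deterministic and testable. CAI is
   the Sharp–Li geometric mean of relative adaptiveness values
   w_c = count_c / max-family-count from a reference set of highly
   expressed genes; zero reference counts get a 0.5 pseudo-count before
   division so no weight is zero. Met, Trp and stop codons are excluded
   from CAI and from the positional GC fractions (they offer no synonymous
   choice); this exclusion is configurable for CAI since conventions vary.

2. **Specificity layer.** SPM_t = xₜ/‖x‖₂, the cosine between the
   expression profile and the ideal single-tissue profile, so Σ SPM² = 1
   and SPM is scale-invariant. The literature around this score does not
   pin down one formula, so the scorer is a pluggable argument to
   `classify_matrix`. Classification combines two independent rules —
   SPM > 0.9 in exactly one tissue, and transcript detection (EST-style
   presence/absence, default ≥ 1 hit) in exactly that tissue — because
   either rule alone admits genes the other rejects; the combination is
   deliberately stricter. Non-specific genes must satisfy SPM < 0.4 in
   every tissue, which a uniform profile meets only with ≥ 7 tissues
   (1/√7 ≈ 0.378).

3. **Decomposition layer.** Internal correspondence analysis of the gene ×
   61-codon table with tissues as row blocks and the 20 synonymous
   families as column blocks (Met and Trp are singleton blocks and thus
   contribute zero within-AA inertia by construction). Total inertia is
   the chi-square statistic over the grand total. The implementation
   computes the four components by condensation: inertia of the
   row-condensed (tissue × codon), column-condensed (gene × AA) and doubly
   condensed tables, combined by Huygens subtraction. This is
   algebraically identical to projecting the standardized residual matrix
   with mass-weighted between/within-block centering operators; the test
   suite carries that dense-projector computation as an independent oracle
   and checks agreement to 1e-10. Negative round-off in a component is
   clamped at zero below 1e-9 × Φ²; anything larger raises, because it
   can only be a bug. Elementary analyses are weighted SVDs of the
   condensed and/or within-centered residual; axis signs are fixed by
   making the largest-magnitude column loading positive.

## Row masses

Row masses are count-proportional (the classical CA convention), so longer
genes carry more weight. A uniform-gene-mass variant is available by
normalizing each row to unit total (`blocked_from_usage(...,
row_weight="uniform")`); the default is the mass convention because it is
what the standard CA lineage of codon-usage studies uses.

## Permutation null

The statistic is the between-tissue within-AA fraction of total inertia.
Labels are shuffled uniformly while preserving tissue sizes ("randomly
associating the genes and tissues"), which leaves the full table — hence
the total inertia — unchanged, so each permutation only recomputes the row
condensation (cheap: a B × I indicator product). The add-one p-value
(1 + #{permuted ≥ observed})/(B + 1) is exact under exchangeability and
never returns zero. Default B = 1000; tests use B = 39–199 to keep the
suite fast while preserving the attainable-p granularity each check needs.

## Divergence estimation

NG86 counting with Jukes–Cantor correction replaces likelihood-based
codon-model estimation deliberately: every ingredient (site fractions,
pathway averaging, the log correction) admits an exhaustive enumeration
oracle, which the tests run over all sense-codon pairs. Changes to stop
codons are excluded from site denominators; mutational pathways through
stops are discarded with renormalization; codon pairs whose every pathway
crosses a stop are dropped with a warning. Saturation (p ≥ 3/4) yields an
undefined distance, excluded from group means and counted. Absolute dS/dN
values from this estimator are not comparable to HKY-corrected ML values;
the reproducible claim in group contrasts is the *ordering* of group
means, not their magnitudes. The protein aligner behind codon threading is
a global affine-gap BLOSUM62 alignment (gap open 11, extend 1 — BLAST-like
defaults); alignment is not the scientific contribution here, only frame
bookkeeping.

## Exact Spearman p-values

Tissue-level correlations involve 7–8 points. For tie-free n ≤ 9 the
two-sided p is computed by enumerating all n! rank permutations of the
6Σd²/(n(n²−1)) statistic; with ties or larger n, midranks plus the
t-approximation are used and labelled as such in the result.

## What the generator emulates — and what it does not

`synthetic_data` draws, per tissue: gene lengths (normal around the tissue
mean, floor 30 codons), amino-acid compositions (per-gene Dirichlet,
symmetric α = 25 by default — mild between-gene amino-acid variation),
and a gene-level GC3-ending preference g ~ Beta with mean `gc3_pref` and
concentration `gene_dispersion` (default 60, giving a per-gene GC3 spread
comparable to real tissue boxplots). Each synonymous choice picks the
G/C-ending subset of the family with probability g, then uniformly within
the subset. The default seven tissues use GC3 preferences 0.733, 0.708,
0.573, 0.717, 0.696, 0.550, 0.511 — the tissue-level GC3 gradient
observed across rice root, shoot, leaf, anther, embryo, endosperm and
5-day seed — with 30 genes × ~300 codons per tissue as the desk-scale
default (the real corpus is 675 genes with very unequal tissue sizes;
inertia *fractions* at this reduced size are larger than corpus-scale
values and are not comparable to them).

Expression: tissue-specific genes get overdispersed counts with mean 5000
in their tissue and 50 elsewhere (a 100:1 signal ratio); non-specific
genes get exchangeable mean-5000 counts everywhere. The overdispersion
shape (default 10000, i.e. near-Poisson at these means, total CV ≈ 1.7 %)
reflects replicate-averaged, tissue-level intensities rather than
single-library noise — under the strict SPM < 0.4 everywhere rule, a
"non-specific" gene *is* a near-uniform profile, and the generator models
exactly that population. Detection counts are Poisson (mean 6 in the own
tissue for specific genes, 0 elsewhere; mean 3 per tissue for
non-specific genes). Ortholog pairs apply exactly k_syn synonymous and
k_non nonsynonymous one-step codon changes (rejection-sampled, never
creating stops) to a freshly drawn ancestor; defaults give the
tissue-specific class 30 + 12 changes and the non-specific class 12 + 4
on ~300-codon genes.

Not modelled: isochores and chromosomal gene order, introns, EST library
composition effects, alternative splicing, codon autocorrelation along a
gene, and amino-acid-conditional GC preferences. Passing tests therefore
demonstrate correctness of the estimators and the detectability of planted
tissue structure — not that real rice data would yield any particular
fraction.

## Numerical choices and degenerate inputs

* All randomness flows from one integer seed via independent
  `numpy` Generator streams per stage; identical seeds give byte-identical
  FASTA/TSV artifacts.
* ENC returns NaN (never raises) for genes too short to inform any
  degeneracy class; CAI and GC return NaN when no eligible codons exist.
* All-zero gene rows and unobserved codon columns are dropped (with a
  warning) before the chi-square machinery, which is undefined on zero
  margins; all-zero tissue columns are likewise dropped in classification.
* Ambiguous (N-containing) codons are skipped and tallied, never imputed.
* Terminal stop codons are stripped silently; internal stops are errors in
  strict mode (the default), retained with a warning in lenient mode.
* SVD ties are left to the deterministic LAPACK ordering; axis signs are
  fixed as described above, so coordinates are reproducible across runs.

## Problem sizes in the test suite

The suite runs at reduced sizes chosen for quick iteration: 100 null
datasets at B = 39 for calibration, B = 199 for the power check (minimum
attainable p = 1/200), 20 common-random-number replicates over a 5-point
GC3-spread grid for signal monotonicity, 1000 random tables for
additivity, and all 61 × 61 codon pairs for the NG86 oracle. The whole
suite completes in well under a minute on a laptop-class machine.

## Known limitations

* ENC missing-class imputation and the CAI Met/Trp exclusion are
  conventions; datasets analysed with other tools may differ slightly.
* The detection rule reduces EST evidence to presence/absence; count-aware
  rules (min_hits > 1) are supported but not the default.
* Group contrasts report a single rank test per statistic; no
  multiple-testing machinery is included.
* The pipeline analyses all labelled genes it is given; subsetting to
  classified tissue-specific genes before the ICA (as a corpus-scale study
  would) is the caller's choice.
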