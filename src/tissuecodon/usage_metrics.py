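"""Per-gene codon-usage statistics: RSCU, Wright's ENC, CAI, positional GC.

All operations work from a :class:`~tissuecodon.codon_core.CodonCountVector`
so that a gene is summarized once and every index is computed from the same
counts. ENC follows Wright's homozygosity estimator with class means over
degeneracy classes {2, 3, 4, 6}; CAI is the Sharp-Li geometric mean of
relative adaptiveness values from a reference gene set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_core import CodonCountVector, CodonUsageMatrix, GeneticCode

__all__ = [
    "UsageMetrics",
    "ReferenceWeights",
    "rscu",
    "enc",
    "reference_weights",
    "cai",
    "gc_by_position",
    "metrics_table",
]


@dataclass
class UsageMetrics:
    gene_id: str
    enc: float  # NaN when undefined
    cai: float
    gc1: float
    gc2: float
    gc3: float
    gc_all: float
    cds_length_nt: int


@dataclass
class ReferenceWeights:
    """Relative adaptiveness w per sense codon, max w = 1 in each family."""

    w: dict[str, float]
    source: str = ""

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tw\n")
            for codon in sorted(self.w):
                fh.write(f"{codon}\t{self.w[codon]:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "ReferenceWeights":
        w: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("codon", "#")):
                    continue
                codon, val = line.split("\t")
                w[codon] = float(val)
        return cls(w, source=str(path))


def rscu(counts: CodonCountVector, code: GeneticCode) -> dict[str, float]:
    """Relative synonymous codon usage: observed / (family total / family
    size). Families unobserved in the gene give NaN (not an error)."""
    cd = counts.as_dict(code)
    out: dict[str, float] = {}
    for aa, fam in code.families.items():
        total = sum(cd[c] for c in fam)
        k = len(fam)
        for c in fam:
            out[c] = math.nan if total == 0 else cd[c] * k / total
    return out


def enc(counts: CodonCountVector, code: GeneticCode) -> float:
    """Wright's effective number of codons, capped into [20, 61].

    Per amino acid a with n_a >= 2 observed codons, the homozygosity
    F_a = (n_a * sum p_i^2 - 1) / (n_a - 1); class means are taken over
    amino acids of equal degeneracy (F_a <= 0 excluded as uninformative).
    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, a missing class mean imputed by
    the unweighted mean of the available ones. Returns NaN when no class
    mean is computable (gene too short or degenerate).
    """
    cd = counts.as_dict(code)
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in code.families.items():
        k = len(fam)
        if k == 1:
            continue
        n = sum(cd[c] for c in fam)
        if n < 2:
            continue
        p2 = sum((cd[c] / n) ** 2 for c in fam)
        f = (n * p2 - 1) / (n - 1)
        if f > 0:
            f_by_class[k].append(f)
    means = {k: float(np.mean(v)) for k, v in f_by_class.items() if v}
    if not means:
        return math.nan
    impute = float(np.mean(list(means.values())))
    fbar = {k: means.get(k, impute) for k in (2, 3, 4, 6)}
    raw = 2.0 + 9.0 / fbar[2] + 1.0 / fbar[3] + 5.0 / fbar[4] + 3.0 / fbar[6]
    return float(min(61.0, max(20.0, raw)))


def reference_weights(
    ref_counts: CodonCountVector, code: GeneticCode
) -> ReferenceWeights:
    """Relative adaptiveness from aggregated reference-set counts.

    Within each family w_c = count_c / max family count, with zero counts
    replaced by a 0.5 pseudo-count before division so every w is positive.
    Single-codon families (Met, Trp) get w = 1.
    """
    cd = ref_counts.as_dict(code)
    w: dict[str, float] = {}
    for aa, fam in code.families.items():
        if len(fam) == 1:
            w[fam[0]] = 1.0
            continue
        repaired = {c: (cd[c] if cd[c] > 0 else 0.5) for c in fam}
        top = max(repaired.values())
        if all(cd[c] == 0 for c in fam):
            warnings.warn(
                f"reference set has no codons for {aa}; weights set to 1",
                stacklevel=2,
            )
        for c in fam:
            w[c] = repaired[c] / top
    return ReferenceWeights(w, source="reference_weights()")


def cai(
    counts: CodonCountVector,
    weights: ReferenceWeights,
    code: GeneticCode,
    exclude_single_codon_families: bool = True,
) -> float:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    Met and Trp (single-codon families, no synonymous choice) are excluded
    by default, as are stop codons (never in the counts). NaN when the gene
    has no eligible codons.
    """
    cd = counts.as_dict(code)
    log_sum = 0.0
    n = 0
    for aa, fam in code.families.items():
        if exclude_single_codon_families and len(fam) == 1:
            continue
        for c in fam:
            k = cd[c]
            if k:
                log_sum += k * math.log(weights.w[c])
                n += k
    if n == 0:
        return math.nan
    return float(math.exp(log_sum / n))


def gc_by_position(
    counts: CodonCountVector, code: GeneticCode
) -> tuple[float, float, float, float]:
    """(GC1, GC2, GC3, GCall) from codon counts, excluding ATG, TGG and
    stop codons; GCall is the mean of the three positional fractions."""
    cd = counts.as_dict(code)
    gc = np.zeros(3)
    total = 0
    for aa, fam in code.families.items():
        if len(fam) == 1:  # Met, Trp carry no degrees of freedom
            continue
        for c in fam:
            k = cd[c]
            if not k:
                continue
            total += k
            for pos in range(3):
                if c[pos] in "GC":
                    gc[pos] += k
    if total == 0:
        return (math.nan,) * 4
    g1, g2, g3 = (gc / total).tolist()
    return g1, g2, g3, (g1 + g2 + g3) / 3.0


def metrics_table(
    matrix: CodonUsageMatrix,
    weights: ReferenceWeights,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Per-gene metrics for every row of a usage matrix.

    Returns a DataFrame with columns gene_id, tissue, ENC, CAI, GC1, GC2,
    GC3, GCall, length_nt (the TSV export layout; NaN prints as NA).
    """
    code = code or GeneticCode.standard()
    rows = []
    # matrix columns may be a subset of sense codons after empty-col drop
    col_idx = {c: i for i, c in enumerate(matrix.codons)}
    full = np.zeros((len(matrix.gene_ids), len(code.sense_codons)), dtype=np.int64)
    for c, i in col_idx.items():
        full[:, code.codon_index[c]] = matrix.counts[:, i]
    for g, row in zip(matrix.gene_ids, full):
        vec = CodonCountVector(g, row)
        g1, g2, g3, gall = gc_by_position(vec, code)
        rows.append(
            {
                "gene_id": g,
                "tissue": matrix.tissue_of[g],
                "ENC": enc(vec, code),
                "CAI": cai(vec, weights, code),
                "GC1": g1,
                "GC2": g2,
                "GC3": g3,
                "GCall": gall,
                "length_nt": int(row.sum()) * 3,
            }
        )
    return pd.DataFrame(rows)
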