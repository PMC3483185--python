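"""Pairwise synonymous/nonsynonymous divergence for ortholog pairs.

Implements the Nei-Gojobori (1986) counting method with Jukes-Cantor
correction: synonymous/nonsynonymous site counts per codon (changes to stop
codons excluded from the denominator), pathway averaging over all orders of
multi-position codon differences (pathways through stop codons discarded
with renormalization), proportions pS = Sd/S and pN = Nd/N, and corrected
distances dX = -(3/4) ln(1 - 4 pX / 3), undefined at saturation
(pX >= 3/4). Protein-guided codon alignment keeps the two coding sequences
in frame; group contrasts compare tissue-specific against non-specific
ortholog pairs with a rank-based two-sample test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .codon_core import CodingSequence, GeneticCode

__all__ = [
    "CodonAlignment",
    "SubstitutionRates",
    "align_proteins_global",
    "thread_codons",
    "ng86_sites",
    "ng86_pair",
    "group_contrast",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
_BASES = "ACGT"


@dataclass
class CodonAlignment:
    pair_id: str
    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError(f"{self.pair_id}: unequal codon alignment lengths")

    def __len__(self) -> int:
        return len(self.codons_a)


@dataclass
class SubstitutionRates:
    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when saturated
    dN: float
    n_codons: int

    @property
    def saturated(self) -> bool:
        return math.isnan(self.dS) or math.isnan(self.dN)


def align_proteins_global(
    seq_a: str,
    seq_b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, affine gaps).

    Returns the two gapped strings of the optimal alignment; tie-breaking
    is deterministic (first alignment in the aligner's fixed enumeration
    order).
    """
    for name, s in (("first", seq_a), ("second", seq_b)):
        if not s:
            raise ValueError(f"{name} protein sequence is empty")
        bad = set(s) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{name} sequence has non-amino-acid symbols {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def thread_codons(
    aln: tuple[str, str],
    cds_a: CodingSequence,
    cds_b: CodingSequence,
    code: GeneticCode | None = None,
    pair_id: str | None = None,
) -> CodonAlignment:
    """Map an aligned protein pair back onto codons.

    Gap columns and columns where either codon contains an ambiguous base
    are dropped; retained codons must translate to the aligned residues.
    """
    code = code or GeneticCode.standard()
    ga, gb = aln
    if len(ga) != len(gb):
        raise ValueError("aligned strings differ in length")
    pa = ga.replace("-", "")
    pb = gb.replace("-", "")
    for p, cds in ((pa, cds_a), (pb, cds_b)):
        if len(p) * 3 != len(cds.nucleotides):
            raise ValueError(
                f"{cds.gene_id}: protein length {len(p)} does not match CDS "
                f"length {len(cds.nucleotides)} (expected {len(p) * 3})"
            )
    cod_a = cds_a.codons()
    cod_b = cds_b.codons()
    ia = ib = 0
    keep_a: list[str] = []
    keep_b: list[str] = []
    for ra, rb in zip(ga, gb):
        ca = cb = None
        if ra != "-":
            ca = cod_a[ia]
            ia += 1
        if rb != "-":
            cb = cod_b[ib]
            ib += 1
        if ca is None or cb is None:
            continue
        if "N" in ca or "N" in cb:
            continue
        if ca in code.stop_codons or cb in code.stop_codons:
            continue
        if code.codon_to_aa[ca] != ra or code.codon_to_aa[cb] != rb:
            raise ValueError(
                f"codon/residue mismatch at aligned column ({ca}->{ra}, {cb}->{rb})"
            )
        keep_a.append(ca)
        keep_b.append(cb)
    return CodonAlignment(
        pair_id=pair_id or f"{cds_a.gene_id}|{cds_b.gene_id}",
        codons_a=keep_a,
        codons_b=keep_b,
    )


def ng86_sites(codon: str, code: GeneticCode) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    At each of the three positions the fraction of one-step changes that
    are synonymous is accumulated; changes creating a stop codon are
    excluded from the denominator. s + n = 3 always.
    """
    aa = code.codon_to_aa.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"not a sense codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = code.codon_to_aa[alt]
            if alt_aa == "*":
                continue
            valid += 1
            if alt_aa == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _pathway_diffs(
    ca: str, cb: str, code: GeneticCode
) -> tuple[float, float] | None:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts for a
    codon pair; None when every mutational pathway passes through a stop."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd_tot = nd_tot = 0.0
    n_ok = 0
    for order in itertools.permutations(diff_pos):
        cur = ca
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if code.codon_to_aa[nxt] == "*":
                ok = False
                break
            if code.codon_to_aa[nxt] == code.codon_to_aa[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_tot += sd
            nd_tot += nd
            n_ok += 1
    if n_ok == 0:
        return None
    return sd_tot / n_ok, nd_tot / n_ok


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(aln: CodonAlignment, code: GeneticCode | None = None) -> SubstitutionRates:
    """NG86 rates for an aligned codon pair with Jukes-Cantor correction.

    Site counts S and N are averaged over the two sequences; difference
    counts average over all mutational pathways per differing codon pair,
    discarding pathways through stop codons. A codon pair whose every
    pathway hits a stop is dropped (with a warning) from sites and
    differences alike.
    """
    code = code or GeneticCode.standard()
    if len(aln) < 1:
        raise ValueError(f"{aln.pair_id}: empty codon alignment")
    S = N = Sd = Nd = 0.0
    n_used = 0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        d = _pathway_diffs(ca, cb, code)
        if d is None:
            warnings.warn(
                f"{aln.pair_id}: codon pair {ca}/{cb} has no stop-free "
                "pathway; column dropped",
                stacklevel=2,
            )
            continue
        sa, na = ng86_sites(ca, code)
        sb, nb = ng86_sites(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += d[0]
        Nd += d[1]
        n_used += 1
    if n_used == 0:
        raise ValueError(f"{aln.pair_id}: no usable codon columns")
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    return SubstitutionRates(
        pair_id=aln.pair_id,
        S=S,
        N=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=_jc(pS) if not math.isnan(pS) else math.nan,
        dN=_jc(pN) if not math.isnan(pN) else math.nan,
        n_codons=n_used,
    )


def group_contrast(
    rates: Sequence[SubstitutionRates],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Tissue-specific vs non-specific contrast of dS and dN.

    Saturated pairs (undefined distance) are excluded from group means and
    counted; the two-sided Mann-Whitney rank test compares groups when both
    have at least two usable pairs, otherwise p is NA.
    """
    from scipy.stats import mannwhitneyu

    by_group: dict[str, list[SubstitutionRates]] = {}
    for r in rates:
        g = groups.get(r.pair_id)
        if g is None:
            raise ValueError(f"pair {r.pair_id!r} has no group label")
        by_group.setdefault(g, []).append(r)
    if len(by_group) < 2:
        raise ValueError("need two non-empty groups")
    rows = []
    for stat in ("dS", "dN"):
        samples = {}
        for g, rs in sorted(by_group.items()):
            vals = np.array([getattr(r, stat) for r in rs])
            ok = ~np.isnan(vals)
            samples[g] = vals[ok]
            rows.append(
                {
                    "statistic": stat,
                    "group": g,
                    "n": int(ok.sum()),
                    "n_saturated": int((~ok).sum()),
                    "mean": float(vals[ok].mean()) if ok.any() else math.nan,
                    "sd": float(vals[ok].std(ddof=1)) if ok.sum() > 1 else math.nan,
                }
            )
        gs = sorted(samples)
        if all(samples[g].size >= 2 for g in gs[:2]) and all(
            np.ptp(np.concatenate([samples[g] for g in gs[:2]])) > 0 for _ in (0,)
        ):
            p = float(
                mannwhitneyu(samples[gs[0]], samples[gs[1]],
                             alternative="two-sided").pvalue
            )
        else:
            p = math.nan
        for row in rows[-len(gs):]:
            row["p_rank_test"] = p
    return pd.DataFrame(rows)
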