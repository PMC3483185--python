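"""Internal correspondence analysis of a blocked gene x codon table.

A codon usage table (genes as rows, the 61 sense codons as columns) carries
two natural partitions: rows group into tissues, columns group into
synonymous families (amino acids). Under the chi-square metric of
correspondence analysis the total inertia

    Phi^2 = sum_ij (p_ij - r_i c_j)^2 / (r_i c_j)

splits additively into four orthogonal components by crossing
{between-tissue, within-tissue} with {between-amino-acid, within-amino-acid}.
The between-tissue x within-amino-acid cell is the quantity of interest: the
share of synonymous codon usage variability attributable to the tissue a
gene is expressed in. Crossing {total, between, within} on both axes yields
nine elementary correspondence analyses, each a weighted SVD of an
appropriately condensed and/or within-block-centered residual matrix.

Row masses are count-proportional (the classical CA convention: longer
genes weigh more); a uniform-row-mass variant is available via
``row_weight="uniform"`` on :class:`BlockedTable` construction, which
reweights gene rows to equal mass before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .codon_core import CodonUsageMatrix, GeneticCode

__all__ = [
    "BlockedTable",
    "InertiaDecomposition",
    "ElementaryAnalysis",
    "PermutationResult",
    "PANELS",
    "blocked_from_usage",
    "total_inertia",
    "condense",
    "decompose_inertia",
    "elementary_ca",
    "permutation_test",
]

# Fig-style panel grid: rows cross {within, between, total} tissues,
# columns cross {within, between, total} amino acids.
PANELS: dict[str, tuple[str, str]] = {
    "a": ("within", "within"),
    "b": ("within", "between"),
    "c": ("within", "total"),
    "d": ("between", "within"),
    "e": ("between", "between"),
    "f": ("between", "total"),
    "g": ("total", "within"),
    "h": ("total", "between"),
    "i": ("total", "total"),
}


@dataclass
class BlockedTable:
    """Non-negative I x J table with a block label per row and per column."""

    counts: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    row_block: list[str]  # tissue per row
    col_block: list[str]  # amino acid per column
    row_block_names: list[str]
    col_block_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("negative cell in contingency table")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("zero row in contingency table")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("zero column in contingency table")
        if len(self.row_block) != self.counts.shape[0]:
            raise ValueError("row_block length mismatch")
        if len(self.col_block) != self.counts.shape[1]:
            raise ValueError("col_block length mismatch")

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())

    def row_masses(self) -> np.ndarray:
        return self.counts.sum(axis=1) / self.grand_total

    def col_masses(self) -> np.ndarray:
        return self.counts.sum(axis=0) / self.grand_total

    def row_block_indicator(self) -> np.ndarray:
        """B x I 0/1 matrix mapping rows into row blocks."""
        idx = {b: k for k, b in enumerate(self.row_block_names)}
        M = np.zeros((len(self.row_block_names), self.counts.shape[0]))
        for i, b in enumerate(self.row_block):
            M[idx[b], i] = 1.0
        return M

    def col_block_indicator(self) -> np.ndarray:
        idx = {b: k for k, b in enumerate(self.col_block_names)}
        M = np.zeros((len(self.col_block_names), self.counts.shape[1]))
        for j, b in enumerate(self.col_block):
            M[idx[b], j] = 1.0
        return M


def blocked_from_usage(
    matrix: CodonUsageMatrix,
    code: GeneticCode | None = None,
    row_weight: str = "mass",
) -> BlockedTable:
    """Build the tissue x amino-acid blocked table from a usage matrix.

    Column blocks are synonymous families (Met and Trp are singleton
    blocks, so they contribute zero within-amino-acid inertia by
    construction). ``row_weight="uniform"`` rescales each gene row to unit
    total so every gene carries equal mass.
    """
    code = code or GeneticCode.standard()
    counts = matrix.counts.astype(float)
    if row_weight == "uniform":
        counts = counts / counts.sum(axis=1, keepdims=True)
    elif row_weight != "mass":
        raise ValueError("row_weight must be 'mass' or 'uniform'")
    col_block = [code.codon_to_aa[c] for c in matrix.codons]
    aa_order = [a for a in code.amino_acids if a in set(col_block)]
    return BlockedTable(
        counts=counts,
        row_ids=list(matrix.gene_ids),
        col_ids=list(matrix.codons),
        row_block=matrix.tissue_labels,
        col_block=col_block,
        row_block_names=list(matrix.tissues),
        col_block_names=aa_order,
    )


def total_inertia(table: BlockedTable) -> float:
    """Chi-square statistic of the table divided by its grand total."""
    P = table.counts / table.grand_total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    return float(((P - E) ** 2 / E).sum())


def condense(table: BlockedTable, axis: str) -> BlockedTable:
    """Sum counts within blocks along ``axis`` ('rows' or 'columns').

    Margins on the other axis are conserved; the condensed axis gets one
    row/column per block, labelled by itself.
    """
    if axis == "rows":
        M = table.row_block_indicator()
        counts = M @ table.counts
        return BlockedTable(
            counts=counts,
            row_ids=list(table.row_block_names),
            col_ids=list(table.col_ids),
            row_block=list(table.row_block_names),
            col_block=list(table.col_block),
            row_block_names=list(table.row_block_names),
            col_block_names=list(table.col_block_names),
        )
    if axis == "columns":
        M = table.col_block_indicator()
        counts = table.counts @ M.T
        return BlockedTable(
            counts=counts,
            row_ids=list(table.row_ids),
            col_ids=list(table.col_block_names),
            row_block=list(table.row_block),
            col_block=list(table.col_block_names),
            row_block_names=list(table.row_block_names),
            col_block_names=list(table.col_block_names),
        )
    raise ValueError("axis must be 'rows' or 'columns'")


@dataclass
class InertiaDecomposition:
    total_inertia: float
    components: dict[tuple[str, str], float]  # (tissue-axis, aa-axis)
    fractions: dict[tuple[str, str], float]
    between_tissue_total: float
    within_tissue_total: float
    between_aa_total: float
    within_aa_total: float

    def to_frame(self):
        import pandas as pd

        rows = []
        for (tkey, akey), val in self.components.items():
            rows.append(
                {
                    "tissue_axis": tkey,
                    "aa_axis": akey,
                    "inertia": val,
                    "fraction": self.fractions[(tkey, akey)],
                }
            )
        return pd.DataFrame(rows)


def decompose_inertia(table: BlockedTable) -> InertiaDecomposition:
    """Four-way inertia split via block condensation and Huygens subtraction.

    With I_full the inertia of the raw table, I_rows of the row-condensed
    (tissue x codon) table, I_cols of the column-condensed (gene x amino
    acid) table, and I_both of the doubly condensed (tissue x amino acid)
    table:

        between x between = I_both
        between x within  = I_rows - I_both
        within  x between = I_cols - I_both
        within  x within  = I_full - I_rows - I_cols + I_both

    Each difference is non-negative (condensation can only lose inertia);
    small negative round-off is clamped at zero, larger negatives raise.
    """
    i_full = total_inertia(table)
    i_rows = total_inertia(condense(table, "rows"))
    i_cols = total_inertia(condense(table, "columns"))
    i_both = total_inertia(condense(condense(table, "rows"), "columns"))
    raw = {
        ("between", "between"): i_both,
        ("between", "within"): i_rows - i_both,
        ("within", "between"): i_cols - i_both,
        ("within", "within"): i_full - i_rows - i_cols + i_both,
    }
    tol = 1e-9 * max(i_full, 1e-300)
    comps: dict[tuple[str, str], float] = {}
    for key, val in raw.items():
        if val < -tol:
            raise ArithmeticError(
                f"negative inertia component {key}: {val} (internal error)"
            )
        comps[key] = max(val, 0.0)
    denom = i_full if i_full > 0 else 1.0
    fracs = {k: v / denom for k, v in comps.items()}
    return InertiaDecomposition(
        total_inertia=i_full,
        components=comps,
        fractions=fracs,
        between_tissue_total=comps[("between", "between")]
        + comps[("between", "within")],
        within_tissue_total=comps[("within", "between")]
        + comps[("within", "within")],
        between_aa_total=comps[("between", "between")]
        + comps[("within", "between")],
        within_aa_total=comps[("between", "within")]
        + comps[("within", "within")],
    )


@dataclass
class ElementaryAnalysis:
    which: str
    row_mode: str
    col_mode: str
    eigenvalues: np.ndarray  # non-increasing, positive
    row_coords: np.ndarray  # rows-of-analysis x axes, principal coords
    col_coords: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    component_inertia: float


def _deviation_matrix(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """X_ij = p_ij / (r_i c_j) - 1 plus the row and column masses."""
    P = counts / counts.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    X = P / np.outer(r, c) - 1.0
    return X, r, c


def _project_rows_between(X: np.ndarray, r: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Mass-weighted row-block averages, broadcast back to rows."""
    block_mass = M @ r
    block_avg = (M @ (r[:, None] * X)) / block_mass[:, None]
    return M.T @ block_avg


def elementary_ca(table: BlockedTable, which: str) -> ElementaryAnalysis:
    """One of the nine elementary correspondence analyses.

    ``which`` is a panel letter 'a'..'i' (see :data:`PANELS`) crossing
    {within, between, total} on the tissue axis with the same on the
    amino-acid axis. 'total'/'total' (panel i) is classical CA of the full
    table; 'between' condenses an axis to its blocks; 'within' centers
    profiles on their block means under the chi-square metric. Eigenvalues
    are the squared singular values of the weighted residual matrix and sum
    to the panel's inertia component. Axis signs are fixed by making the
    largest-magnitude column loading positive.
    """
    if which not in PANELS:
        raise ValueError(f"unknown panel {which!r}; expected one of a-i")
    row_mode, col_mode = PANELS[which]

    work = table
    if row_mode == "between":
        work = condense(work, "rows")
    if col_mode == "between":
        work = condense(work, "columns")

    X, r, c = _deviation_matrix(work.counts)
    if row_mode == "within":
        X = X - _project_rows_between(X, r, work.row_block_indicator())
    if col_mode == "within":
        Xt = X.T
        Xt = Xt - _project_rows_between(Xt, c, work.col_block_indicator())
        X = Xt.T

    Z = np.sqrt(r)[:, None] * X * np.sqrt(c)[None, :]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    keep = s**2 > 1e-12 * max(float((s**2).sum()), 1e-300)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # deterministic sign: largest-|v| column loading positive per axis
    for k in range(s.size):
        v = Vt[k]
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            Vt[k] = -v
            U[:, k] = -U[:, k]
    eigenvalues = s**2
    row_coords = (U / np.sqrt(r)[:, None]) * s[None, :]
    col_coords = (Vt.T / np.sqrt(c)[:, None]) * s[None, :]
    return ElementaryAnalysis(
        which=which,
        row_mode=row_mode,
        col_mode=col_mode,
        eigenvalues=eigenvalues,
        row_coords=row_coords,
        col_coords=col_coords,
        row_ids=list(work.row_ids),
        col_ids=list(work.col_ids),
        component_inertia=float(eigenvalues.sum()),
    )


@dataclass
class PermutationResult:
    observed_fraction: float
    permuted: np.ndarray
    mean: float
    sd: float
    p_value: float
    n_permutations: int


def _bt_wa_fraction(
    counts: np.ndarray, M_rows: np.ndarray, M_cols: np.ndarray, i_full: float
) -> float:
    """(between-tissue, within-AA) inertia fraction for given row blocks."""

    def inertia(tab: np.ndarray) -> float:
        P = tab / tab.sum()
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        E = np.outer(r, c)
        return float(((P - E) ** 2 / E).sum())

    rows = M_rows @ counts
    i_rows = inertia(rows)
    i_both = inertia(rows @ M_cols.T)
    return (i_rows - i_both) / i_full


def permutation_test(
    table: BlockedTable,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Label-permutation null for the between-tissue within-AA fraction.

    Gene-to-tissue assignments are shuffled uniformly, preserving tissue
    sizes; the full table (hence the total inertia) is unchanged, so only
    the row condensation is recomputed per permutation. The add-one
    p-value (1 + #{permuted >= observed}) / (B + 1) never returns zero and
    is exact under exchangeability.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sizes = {b: table.row_block.count(b) for b in table.row_block_names}
    if len(sizes) < 2 or min(sizes.values()) < 2:
        raise ValueError("need >= 2 tissues with >= 2 genes each")
    if rng is None:
        rng = np.random.default_rng(seed)
    M_rows = table.row_block_indicator()
    M_cols = table.col_block_indicator()
    i_full = total_inertia(table)
    observed = _bt_wa_fraction(table.counts, M_rows, M_cols, i_full)
    n = table.counts.shape[0]
    permuted = np.empty(B)
    for b in range(B):
        perm = rng.permutation(n)
        permuted[b] = _bt_wa_fraction(
            table.counts, M_rows[:, perm], M_cols, i_full
        )
    p = (1.0 + float((permuted >= observed).sum())) / (B + 1.0)
    return PermutationResult(
        observed_fraction=observed,
        permuted=permuted,
        mean=float(permuted.mean()),
        sd=float(permuted.std(ddof=1)) if B > 1 else float("nan"),
        p_value=p,
        n_permutations=B,
    )
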