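import numpy as np
import pytest

from tissuecodon.codon_core import GeneticCode
from tissuecodon.ica_decomposition import BlockedTable


@pytest.fixture(scope="session")
def code() -> GeneticCode:
    return GeneticCode.standard()


def make_blocked_table(rng, n_rows=None, n_cols=None, n_row_blocks=2,
                       n_col_blocks=3, max_count=30) -> BlockedTable:
    """Random strictly positive blocked table with every block non-empty."""
    I = n_rows if n_rows is not None else int(rng.integers(4, 9))
    J = n_cols if n_cols is not None else int(rng.integers(5, 11))
    counts = rng.integers(1, max_count, size=(I, J)).astype(float)
    rb = [f"t{k % n_row_blocks}" for k in range(I)]
    cb = [f"a{k % n_col_blocks}" for k in range(J)]
    return BlockedTable(
        counts=counts,
        row_ids=[f"g{i}" for i in range(I)],
        col_ids=[f"c{j}" for j in range(J)],
        row_block=rb,
        col_block=cb,
        row_block_names=sorted(set(rb)),
        col_block_names=sorted(set(cb)),
    )


def projector_decompose(table: BlockedTable) -> dict:
    """Independent inertia decomposition via explicit within/between
    centering operators under the chi-square metric (dense projectors).

    Deliberately written with dense matrices and no condensation so it
    shares no code path with the implementation it cross-checks.
    """
    counts = table.counts
    P = counts / counts.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    X = P / np.outer(r, c) - 1.0
    Mr = table.row_block_indicator()
    Mc = table.col_block_indicator()

    def between_rows(A):
        bm = Mr @ r
        return Mr.T @ ((Mr @ (r[:, None] * A)) / bm[:, None])

    def between_cols(A):
        bm = Mc @ c
        return (Mc.T @ ((Mc @ (c[:, None] * A.T)) / bm[:, None])).T

    def inertia(A):
        return float((r[:, None] * c[None, :] * A**2).sum())

    Xb = between_rows(X)
    Xw = X - Xb
    out = {}
    for rkey, Xr in (("between", Xb), ("within", Xw)):
        Xrb = between_cols(Xr)
        out[(rkey, "between")] = inertia(Xrb)
        out[(rkey, "within")] = inertia(Xr - Xrb)
    out["total"] = inertia(X)
    return out
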