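"""Spearman rank correlation with exact small-sample p-values, and simple
per-group summaries.

Tissue-level correlations in this pipeline involve as few as seven points,
where the large-sample t approximation to Spearman's p-value is unreliable;
for tie-free samples with n <= 9 the two-sided p is computed by full
enumeration of the n! rank permutations instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["SpearmanResult", "spearman", "group_means"]

EXACT_N_MAX = 9


@dataclass
class SpearmanResult:
    r: float
    p_two_sided: float
    n: int
    method: str  # "exact-permutation" | "large-sample"


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def spearman(x, y) -> SpearmanResult:
    """Spearman correlation; exact enumeration p for tie-free n <= 9.

    Midranks are used for ties (with the product-moment formula on ranks);
    constant input raises because the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: constant vector")
    rx, ry = _rank(x), _rank(y)
    tie_free = (np.unique(x).size == n) and (np.unique(y).size == n)
    if tie_free:
        d2 = float(((rx - ry) ** 2).sum())
        r = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    else:
        r = float(np.corrcoef(rx, ry)[0, 1])
    if tie_free and n <= EXACT_N_MAX:
        p = _exact_p(n, abs(r))
        return SpearmanResult(r=r, p_two_sided=p, n=n, method="exact-permutation")
    t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 2)))
    return SpearmanResult(r=r, p_two_sided=p, n=n, method="large-sample")


def _exact_p(n: int, abs_r: float) -> float:
    """Two-sided p over all n! equally likely rank orderings."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1.0)
    total = math.factorial(n)
    perms = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(range(n))),
        dtype=np.intp,
        count=total * n,
    ).reshape(total, n)
    d2 = ((base[None, :] - base[perms]) ** 2).sum(axis=1)
    rp = 1.0 - 6.0 * d2 / denom
    count = int((np.abs(rp) >= abs_r - 1e-12).sum())
    return count / total


def group_means(values, labels) -> pd.DataFrame:
    """Per-group n, mean, sample sd, and missing-value counts.

    NaN values are excluded from the mean/sd and reported in n_missing;
    a group with a single non-missing value gets sd = NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size == 0:
        raise ValueError("empty input")
    rows = []
    for g in pd.unique(labels):
        v = values[labels == g]
        ok = ~np.isnan(v)
        vv = v[ok]
        rows.append(
            {
                "group": g,
                "n": int(ok.sum()),
                "mean": float(vv.mean()) if vv.size else math.nan,
                "sd": float(vv.std(ddof=1)) if vv.size > 1 else math.nan,
                "n_missing": int((~ok).sum()),
            }
        )
    return pd.DataFrame(rows)
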