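"""Tissue-specificity scoring (SPM) and the two-rule gene classification.

SPM is implemented as the cosine similarity between a gene's expression
profile and the idealized profile expressed in a single tissue: spm[t] =
values[t] / ||values||_2, so sum(spm^2) = 1 and spm[t] = 1 exactly when
expression is confined to tissue t. A gene is called tissue-specific when
SPM exceeds a threshold (default 0.9) in exactly one tissue AND its
transcript is detected (EST evidence) in only that tissue; it is called
non-specific when SPM stays below a ceiling (default 0.4) in every tissue.
The scorer is pluggable should a different specificity measure be wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "SpecificityScores",
    "spm",
    "classify_tissue_specific",
    "classify_non_specific",
    "detection_from_counts",
    "classify_matrix",
]


@dataclass
class ExpressionProfile:
    gene_id: str
    values: np.ndarray  # non-negative, one per tissue
    detected: np.ndarray  # boolean, one per tissue
    tissues: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError(f"{self.gene_id}: profile needs >= 1 tissue")
        if (self.values < 0).any():
            raise ValueError(f"{self.gene_id}: negative expression values")
        if self.values.shape != self.detected.shape:
            raise ValueError(f"{self.gene_id}: values/detected length mismatch")
        if (self.detected & (self.values == 0)).any():
            warnings.warn(
                f"{self.gene_id}: detected in a tissue with zero expression",
                stacklevel=2,
            )


@dataclass
class SpecificityScores:
    gene_id: str
    spm: np.ndarray
    tissues: list[str]
    argmax_tissue: str
    n_detected: int
    detected: np.ndarray


def spm(profile: ExpressionProfile) -> SpecificityScores:
    """Cosine specificity score per tissue; errors on all-zero profiles."""
    norm = float(np.linalg.norm(profile.values))
    if norm == 0.0:
        raise ValueError(f"{profile.gene_id}: unexpressed gene (all zeros)")
    scores = profile.values / norm
    return SpecificityScores(
        gene_id=profile.gene_id,
        spm=scores,
        tissues=list(profile.tissues),
        argmax_tissue=profile.tissues[int(np.argmax(scores))],
        n_detected=int(profile.detected.sum()),
        detected=profile.detected,
    )


def classify_tissue_specific(
    scores: SpecificityScores, spm_threshold: float = 0.9
) -> str | None:
    """The tissue a gene is specific to, or None.

    Requires SPM > threshold in exactly one tissue, transcript detection in
    exactly one tissue, and agreement between the two; combining the score
    rule with the detection rule is deliberately stricter than either alone.
    """
    above = np.flatnonzero(scores.spm > spm_threshold)
    if above.size != 1 or scores.n_detected != 1:
        return None
    det = np.flatnonzero(scores.detected)
    if det.size != 1 or det[0] != above[0]:
        return None
    return scores.tissues[int(above[0])]


def classify_non_specific(
    scores: SpecificityScores, ceiling: float = 0.4
) -> bool:
    """True iff every tissue's SPM is below the ceiling (broad expression)."""
    return bool((scores.spm < ceiling).all())


def detection_from_counts(
    est_counts: Sequence[int] | np.ndarray, min_hits: int = 1
) -> np.ndarray:
    """Presence/absence calls from per-tissue EST (or read) counts."""
    arr = np.asarray(est_counts)
    if (arr < 0).any():
        raise ValueError("negative EST counts")
    return arr >= min_hits


def classify_matrix(
    expression: pd.DataFrame,
    detection: pd.DataFrame | None = None,
    spm_threshold: float = 0.9,
    nonspecific_ceiling: float = 0.4,
    min_hits: int = 1,
    scorer: Callable[[ExpressionProfile], SpecificityScores] = spm,
) -> pd.DataFrame:
    """Classify every gene of an expression matrix (genes x tissues).

    ``detection`` is a parallel 0/1 (or count) matrix of transcript
    evidence; when omitted, detection falls back to expression > 0.
    Returns a DataFrame gene_id, class in {specific, non_specific, other},
    tissue (the specific tissue or NA), spm_max.
    """
    tissues = list(expression.columns)
    zero_cols = [t for t in tissues if (expression[t] == 0).all()]
    if zero_cols:
        warnings.warn(f"dropping all-zero tissue column(s): {zero_cols}",
                      stacklevel=2)
        expression = expression.drop(columns=zero_cols)
        if detection is not None:
            detection = detection.drop(columns=zero_cols)
        tissues = list(expression.columns)
    rows = []
    for gene_id, vals in expression.iterrows():
        values = vals.to_numpy(dtype=float)
        if detection is not None:
            det = detection_from_counts(
                detection.loc[gene_id].to_numpy(), min_hits
            )
        else:
            det = values > 0
        if not values.any():
            rows.append({"gene_id": gene_id, "class": "other",
                         "tissue": None, "spm_max": np.nan})
            continue
        scores = scorer(ExpressionProfile(str(gene_id), values, det, tissues))
        tissue = classify_tissue_specific(scores, spm_threshold)
        if tissue is not None:
            cls = "specific"
        elif classify_non_specific(scores, nonspecific_ceiling):
            cls = "non_specific"
        else:
            cls = "other"
        rows.append(
            {
                "gene_id": gene_id,
                "class": cls,
                "tissue": tissue,
                "spm_max": float(scores.spm.max()),
            }
        )
    return pd.DataFrame(rows)
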