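"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes in
rice tissue-specific genes:

* per-tissue GC3-ending codon preference gradients (tissue-level GC3 means
  spanning roughly 0.51-0.73, the range observed across rice tissues),
  with gene-level preferences dispersed around the tissue mean;
* expression matrices containing planted tissue-specific genes (high
  signal in exactly one tissue) and planted broadly expressed genes
  (exchangeable moderate counts everywhere), with matching EST-style
  detection counts;
* ortholog pairs with controlled numbers of synonymous and nonsynonymous
  one-step codon substitutions.

Codon choice is a two-stage draw — pick the G/C-ending subset of the
synonymous family with gene-specific probability g, then uniformly within
the subset — which instantiates tissue GC3 variation with one
interpretable knob per tissue. All draws flow from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_core import CodingSequence, GeneticCode

__all__ = [
    "TissueModel",
    "ExpressionNoise",
    "OrthologClass",
    "SimulationConfig",
    "default_config",
    "gen_codon_dataset",
    "gen_expression_matrix",
    "gen_ortholog_pairs",
    "write_expression_tsvs",
]

# Tissue-level GC3 means patterned on observed rice tissue gradients.
_DEFAULT_TISSUE_GC3 = {
    "root": 0.733,
    "shoot": 0.708,
    "leaf": 0.573,
    "anther": 0.717,
    "embryo": 0.696,
    "endosperm": 0.550,
    "seed5d": 0.511,
}


@dataclass
class TissueModel:
    name: str
    n_genes: int = 30
    gc3_pref: float = 0.6  # probability a synonymous choice is G/C-ending
    gene_dispersion: float = 60.0  # Beta concentration of gene-level prefs
    aa_dirichlet: np.ndarray | float = 25.0  # per-AA Dirichlet alpha
    length_mean_codons: int = 300

    def __post_init__(self) -> None:
        if not (0.0 < self.gc3_pref < 1.0):
            raise ValueError(f"{self.name}: gc3_pref must be inside (0,1)")
        if self.n_genes < 1:
            raise ValueError(f"{self.name}: n_genes must be >= 1")
        if self.gene_dispersion <= 0:
            raise ValueError(f"{self.name}: gene_dispersion must be > 0")


@dataclass
class ExpressionNoise:
    """Overdispersed count model: mean scaled by a Gamma(shape, 1/shape)
    factor, then Poisson. Larger ``overdispersion`` approaches Poisson."""

    specific_mean: float = 5000.0
    background_mean: float = 50.0
    nonspecific_mean: float = 5000.0
    overdispersion: float = 10000.0
    est_specific_mean: float = 6.0
    est_nonspecific_mean: float = 3.0


@dataclass
class OrthologClass:
    n_pairs: int
    k_syn: int
    k_non: int


@dataclass
class SimulationConfig:
    tissues: list[TissueModel]
    seed: int = 0
    n_nonspecific: int = 60
    noise: ExpressionNoise = field(default_factory=ExpressionNoise)
    ortholog_settings: dict[str, OrthologClass] = field(
        default_factory=lambda: {
            "specific": OrthologClass(n_pairs=20, k_syn=30, k_non=12),
            "non_specific": OrthologClass(n_pairs=20, k_syn=12, k_non=4),
        }
    )
    nonspecific_model: TissueModel = field(
        default_factory=lambda: TissueModel(name="non_specific", gc3_pref=0.466)
    )


def default_config(seed: int = 0, n_genes_per_tissue: int = 30) -> SimulationConfig:
    tissues = [
        TissueModel(name=t, n_genes=n_genes_per_tissue, gc3_pref=g)
        for t, g in _DEFAULT_TISSUE_GC3.items()
    ]
    return SimulationConfig(tissues=tissues, seed=seed)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _gc_subsets(code: GeneticCode) -> dict[str, tuple[list[str], list[str]]]:
    """Per amino acid, the (G/C-ending, A/T-ending) synonymous codons."""
    out = {}
    for aa, fam in code.families.items():
        gc = [c for c in fam if c[2] in "GC"]
        at = [c for c in fam if c[2] in "AT"]
        out[aa] = (gc, at)
    return out


def _draw_gene(
    model: TissueModel,
    code: GeneticCode,
    subsets,
    aas: list[str],
    alpha: np.ndarray,
    rng: np.random.Generator,
) -> str:
    length = max(30, int(round(rng.normal(model.length_mean_codons,
                                          0.15 * model.length_mean_codons))))
    p_aa = rng.dirichlet(alpha)
    aa_seq = rng.choice(len(aas), size=length, p=p_aa)
    g = rng.beta(
        model.gc3_pref * model.gene_dispersion,
        (1.0 - model.gc3_pref) * model.gene_dispersion,
    )
    codons = []
    for ai in aa_seq:
        gc, at = subsets[aas[ai]]
        if not gc or not at:  # no GC3 choice in this family
            fam = gc or at
            codons.append(fam[int(rng.integers(len(fam)))])
        elif rng.random() < g:
            codons.append(gc[int(rng.integers(len(gc)))])
        else:
            codons.append(at[int(rng.integers(len(at)))])
    return "".join(codons) + "TAA"


def gen_codon_dataset(
    config: SimulationConfig,
    code: GeneticCode | None = None,
    include_nonspecific: bool = False,
) -> tuple[list[CodingSequence], dict[str, str]]:
    """Tissue-labelled CDS records plus a gene -> tissue label map.

    Each gene carries a terminal stop codon and no internal stops. With
    ``include_nonspecific`` the broadly expressed genes (label
    ``non_specific``) are appended using the dedicated model.
    """
    code = code or GeneticCode.standard()
    subsets = _gc_subsets(code)
    aas = list(code.amino_acids)
    rng = _rng(config, stage=1)
    records: list[CodingSequence] = []
    labels: dict[str, str] = {}
    models = list(config.tissues)
    if include_nonspecific:
        m = config.nonspecific_model
        models.append(
            TissueModel(
                name=m.name,
                n_genes=config.n_nonspecific,
                gc3_pref=m.gc3_pref,
                gene_dispersion=m.gene_dispersion,
                aa_dirichlet=m.aa_dirichlet,
                length_mean_codons=m.length_mean_codons,
            )
        )
    for model in models:
        alpha = np.asarray(model.aa_dirichlet, dtype=float)
        if alpha.ndim == 0:
            alpha = np.full(len(aas), float(alpha))
        for k in range(model.n_genes):
            gid = f"{model.name}_{k:04d}"
            seq = _draw_gene(model, code, subsets, aas, alpha, rng)
            records.append(CodingSequence(gid, seq, tissue_label=model.name))
            labels[gid] = model.name
    return records, labels


def _overdispersed_counts(
    mean: float, size, shape: float, rng: np.random.Generator
) -> np.ndarray:
    lam = mean * rng.gamma(shape, 1.0 / shape, size=size)
    return rng.poisson(lam)


def gen_expression_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(expression, detection, truth) for planted specific/non-specific genes.

    Row order: the tissue-specific genes of each tissue model in order,
    then ``n_nonspecific`` broadly expressed genes. Expression is an
    overdispersed count/intensity matrix; detection is an EST-style hit
    count matrix (0 background for specific genes). Truth records the
    planted class and tissue.
    """
    rng = _rng(config, stage=2)
    noise = config.noise
    tissues = [m.name for m in config.tissues]
    T = len(tissues)
    gene_ids: list[str] = []
    expr_rows = []
    det_rows = []
    truth = []
    for ti, model in enumerate(config.tissues):
        for k in range(model.n_genes):
            gid = f"{model.name}_{k:04d}"
            vals = _overdispersed_counts(
                noise.background_mean, T, noise.overdispersion, rng
            ).astype(float)
            vals[ti] = _overdispersed_counts(
                noise.specific_mean, None, noise.overdispersion, rng
            )
            est = np.zeros(T, dtype=int)
            est[ti] = rng.poisson(noise.est_specific_mean)
            gene_ids.append(gid)
            expr_rows.append(vals)
            det_rows.append(est)
            truth.append({"gene_id": gid, "class": "specific", "tissue": model.name})
    for k in range(config.n_nonspecific):
        gid = f"non_specific_{k:04d}"
        vals = _overdispersed_counts(
            noise.nonspecific_mean, T, noise.overdispersion, rng
        ).astype(float)
        est = rng.poisson(noise.est_nonspecific_mean, size=T)
        gene_ids.append(gid)
        expr_rows.append(vals)
        det_rows.append(est)
        truth.append({"gene_id": gid, "class": "non_specific", "tissue": None})
    expression = pd.DataFrame(expr_rows, index=gene_ids, columns=tissues)
    detection = pd.DataFrame(det_rows, index=gene_ids, columns=tissues)
    return expression, detection, pd.DataFrame(truth)


def write_expression_tsvs(expression, detection, truth, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_id")
    detection.to_csv(outdir / "detection.tsv", sep="\t", index_label="gene_id")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _one_step_neighbors(code: GeneticCode) -> dict[str, tuple[list[str], list[str]]]:
    """Per sense codon: (synonymous, nonsynonymous) one-step sense neighbors."""
    out: dict[str, tuple[list[str], list[str]]] = {}
    for codon in code.sense_codons:
        syn: list[str] = []
        non: list[str] = []
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                aa = code.codon_to_aa[alt]
                if aa == "*":
                    continue
                (syn if aa == code.codon_to_aa[codon] else non).append(alt)
        out[codon] = (syn, non)
    return out


def apply_substitutions(
    cds: str,
    k_syn: int,
    k_non: int,
    code: GeneticCode,
    rng: np.random.Generator,
    max_tries: int = 100000,
) -> str:
    """Apply exactly k_syn synonymous and k_non nonsynonymous one-step
    codon changes (in random interleaved order), never creating a stop."""
    neighbors = _one_step_neighbors(code)
    body = cds[:-3] if cds[-3:] in code.stop_codons else cds
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    todo = ["syn"] * k_syn + ["non"] * k_non
    rng.shuffle(todo)
    for kind in todo:
        done = False
        for _ in range(max_tries):
            i = int(rng.integers(len(codons)))
            syn, non = neighbors[codons[i]]
            pool = syn if kind == "syn" else non
            if pool:
                codons[i] = pool[int(rng.integers(len(pool)))]
                done = True
                break
        if not done:
            raise ValueError(
                f"could not place a {kind} substitution ({k_syn}+{k_non} "
                f"requested on {len(codons)} codons)"
            )
    tail = cds[-3:] if cds[-3:] in code.stop_codons else ""
    return "".join(codons) + tail


def gen_ortholog_pairs(
    config: SimulationConfig, code: GeneticCode | None = None
) -> tuple[list[tuple[CodingSequence, CodingSequence]], pd.DataFrame]:
    """Ortholog pairs with controlled divergence per gene class.

    Each pair is an ancestor CDS drawn from the non-specific tissue model
    and a descendant carrying exactly k_syn synonymous and k_non
    nonsynonymous one-step substitutions for its class. Truth records the
    class and the planted counts.
    """
    code = code or GeneticCode.standard()
    subsets = _gc_subsets(code)
    aas = list(code.amino_acids)
    rng = _rng(config, stage=3)
    base = config.nonspecific_model
    alpha = np.asarray(base.aa_dirichlet, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(len(aas), float(alpha))
    pairs: list[tuple[CodingSequence, CodingSequence]] = []
    truth = []
    for cls, settings in config.ortholog_settings.items():
        for k in range(settings.n_pairs):
            pid = f"{cls}_pair_{k:04d}"
            anc = _draw_gene(base, code, subsets, aas, alpha, rng)
            der = apply_substitutions(anc, settings.k_syn, settings.k_non, code, rng)
            pairs.append(
                (
                    CodingSequence(f"{pid}_a", anc),
                    CodingSequence(f"{pid}_b", der),
                )
            )
            truth.append(
                {
                    "pair_id": pid,
                    "class": cls,
                    "k_syn": settings.k_syn,
                    "k_non": settings.k_non,
                }
            )
    return pairs, pd.DataFrame(truth)
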