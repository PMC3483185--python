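"""End-to-end orchestration: metrics -> classification -> ICA ->
permutation -> correlations -> substitution rates, with TSV reports.

Every number written to the summary tables is recomputable from the
per-gene TSVs; a run manifest records the configuration and seed so a rerun
reproduces the outputs byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codon_core import (
    CodingSequence,
    GeneticCode,
    build_usage_matrix,
    count_codons,
    read_fasta,
    read_labels_tsv,
    validate_cds,
)
from .evo_rates import (
    align_proteins_global,
    group_contrast,
    ng86_pair,
    thread_codons,
)
from .ica_decomposition import (
    blocked_from_usage,
    decompose_inertia,
    elementary_ca,
    permutation_test,
)
from .specificity import classify_matrix
from .stats_utils import group_means, spearman
from .usage_metrics import (
    CodonCountVector,
    ReferenceWeights,
    metrics_table,
    reference_weights,
)

__all__ = ["PipelineConfig", "run_full", "summarize_tissues", "load_cds"]


@dataclass
class PipelineConfig:
    cds_fasta: str | Path
    out_dir: str | Path
    labels_tsv: str | Path | None = None
    expression_tsv: str | Path | None = None
    detection_tsv: str | Path | None = None
    ref_weights_tsv: str | Path | None = None
    ortholog_fasta: str | Path | None = None  # two records per pair
    ortholog_groups_tsv: str | Path | None = None
    spm_threshold: float = 0.9
    nonspecific_ceiling: float = 0.4
    permutations: int = 1000
    seed: int = 0
    strict_cds: bool = True
    cai_exclude_single_codon_families: bool = True


def load_cds(
    fasta_path, labels_tsv=None, code: GeneticCode | None = None, strict=True
):
    """Read, validate and label CDS records.

    Labels from the TSV override FASTA ``tissue=`` keys with a warning on
    conflict.
    """
    code = code or GeneticCode.standard()
    records = [validate_cds(r, code, strict=strict) for r in read_fasta(fasta_path)]
    labels = {r.gene_id: r.tissue_label for r in records if r.tissue_label}
    if labels_tsv is not None:
        tsv = read_labels_tsv(labels_tsv)
        for g, t in tsv.items():
            if g in labels and labels[g] != t:
                warnings.warn(
                    f"label conflict for {g}: FASTA={labels[g]!r} TSV={t!r}; "
                    "TSV wins",
                    stacklevel=2,
                )
            labels[g] = t
    return records, labels


def summarize_tissues(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue n and mean +/- sd of each usage metric."""
    rows = []
    for tissue, sub in metrics.groupby("tissue", sort=False):
        row = {"tissue": tissue, "n": len(sub)}
        for col in ("ENC", "CAI", "GC1", "GC2", "GC3", "GCall", "length_nt"):
            v = sub[col].to_numpy(dtype=float)
            ok = ~np.isnan(v)
            row[f"{col}_mean"] = float(v[ok].mean()) if ok.any() else np.nan
            row[f"{col}_sd"] = float(v[ok].std(ddof=1)) if ok.sum() > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tissuecodon {__version__} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_full(config: PipelineConfig) -> dict:
    """Run every stage the inputs allow; returns a dict of key results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    code = GeneticCode.standard()
    cfg_json = json.dumps(
        {k: str(v) for k, v in asdict(config).items() if k != "out_dir"},
        sort_keys=True,
    )
    import hashlib

    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:8]
    results: dict = {}

    records, labels = load_cds(
        config.cds_fasta, config.labels_tsv, code, strict=config.strict_cds
    )
    vectors = [count_codons(r, code) for r in records]
    if not labels:
        raise ValueError("no tissue labels available (FASTA keys or TSV)")
    matrix = build_usage_matrix(vectors, labels, code)

    if config.ref_weights_tsv is not None:
        weights = ReferenceWeights.from_tsv(config.ref_weights_tsv)
    else:
        # fall back: pool the whole dataset as its own reference set
        pooled = CodonCountVector("pooled", np.sum([v.counts for v in vectors], axis=0))
        weights = reference_weights(pooled, code)
        warnings.warn(
            "no reference weight table given; using pooled dataset counts",
            stacklevel=2,
        )

    metrics = metrics_table(matrix, weights, code)
    _write(metrics, out / "metrics.tsv", cfg_hash)
    summary = summarize_tissues(metrics)
    _write(summary, out / "tissue_summary.tsv", cfg_hash)
    results["metrics"] = metrics
    results["tissue_summary"] = summary

    # tissue-level Spearman: mean ENC vs mean CAI across tissues
    if len(summary) >= 3:
        try:
            sp = spearman(summary["ENC_mean"], summary["CAI_mean"])
            results["spearman_enc_cai"] = sp
            _write(
                pd.DataFrame(
                    [{"pair": "tissue_mean_ENC_vs_CAI", "r": sp.r,
                      "p": sp.p_two_sided, "n": sp.n, "method": sp.method}]
                ),
                out / "spearman.tsv",
                cfg_hash,
            )
        except ValueError:
            pass

    if config.expression_tsv is not None:
        expression = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
        detection = None
        if config.detection_tsv is not None:
            detection = pd.read_csv(config.detection_tsv, sep="\t", index_col=0)
        classes = classify_matrix(
            expression,
            detection,
            spm_threshold=config.spm_threshold,
            nonspecific_ceiling=config.nonspecific_ceiling,
        )
        _write(classes, out / "classification.tsv", cfg_hash)
        results["classification"] = classes

    # internal correspondence analysis on the labelled usage matrix
    table = blocked_from_usage(matrix, code)
    decomp = decompose_inertia(table)
    _write(decomp.to_frame(), out / "inertia_decomposition.tsv", cfg_hash)
    results["decomposition"] = decomp
    eig_rows = []
    for panel in "abcdefghi":
        ana = elementary_ca(table, panel)
        for k, ev in enumerate(ana.eigenvalues[:10]):
            eig_rows.append(
                {"panel": panel, "axis": k + 1, "eigenvalue": float(ev),
                 "component_inertia": ana.component_inertia}
            )
        if panel == "d":
            results["panel_d"] = ana
            coords = pd.DataFrame(
                ana.row_coords[:, : min(3, ana.row_coords.shape[1])],
                columns=[f"Axis{i+1}" for i in
                         range(min(3, ana.row_coords.shape[1]))],
            )
            coords.insert(0, "tissue", ana.row_ids)
            _write(coords, out / "panel_d_tissue_coords.tsv", cfg_hash)
    _write(pd.DataFrame(eig_rows), out / "eigenvalues.tsv", cfg_hash)

    # Axis-1 (tissue) coordinates vs tissue GC3/GCall
    if "panel_d" in results and len(table.row_block_names) >= 3:
        ana = results["panel_d"]
        gc3 = summary.set_index("tissue").reindex(ana.row_ids)["GC3_mean"]
        gcall = summary.set_index("tissue").reindex(ana.row_ids)["GCall_mean"]
        if ana.row_coords.shape[1] > 0 and not gc3.isna().any():
            ax1 = ana.row_coords[:, 0]
            rows = []
            for name, v in (("GC3", gc3), ("GCall", gcall)):
                sp = spearman(ax1, v.to_numpy())
                rows.append({"pair": f"panel_d_Axis1_vs_{name}", "r": sp.r,
                             "p": sp.p_two_sided, "n": sp.n,
                             "method": sp.method})
                results[f"spearman_axis1_{name.lower()}"] = sp
            _write(pd.DataFrame(rows), out / "spearman_axis1.tsv", cfg_hash)

    perm = permutation_test(table, B=config.permutations, seed=config.seed)
    _write(
        pd.DataFrame({"permuted_fraction": perm.permuted}),
        out / "permutation_trace.tsv",
        cfg_hash,
    )
    _write(
        pd.DataFrame(
            [{"observed_fraction": perm.observed_fraction, "mean": perm.mean,
              "sd": perm.sd, "p_value": perm.p_value, "B": perm.n_permutations}]
        ),
        out / "permutation_summary.tsv",
        cfg_hash,
    )
    results["permutation"] = perm

    if config.ortholog_fasta is not None and config.ortholog_groups_tsv is not None:
        rates, contrast = run_rates(
            config.ortholog_fasta, config.ortholog_groups_tsv, code,
            strict=config.strict_cds,
        )
        _write(rates, out / "rates.tsv", cfg_hash)
        _write(contrast, out / "rates_contrast.tsv", cfg_hash)
        results["rates"] = rates
        results["contrast"] = contrast

    manifest = {
        "tool": "tissuecodon",
        "version": __version__,
        "config": json.loads(cfg_json),
        "config_hash": cfg_hash,
        "n_genes": len(matrix.gene_ids),
        "n_tissues": len(matrix.tissues),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results


def run_rates(ortholog_fasta, groups_tsv, code=None, strict=True):
    """NG86 rates + group contrast from a paired FASTA (two records per
    pair, consecutive) and a pair_id -> group TSV."""
    code = code or GeneticCode.standard()
    records = read_fasta(ortholog_fasta)
    if len(records) % 2 != 0:
        raise ValueError("paired FASTA must hold an even number of records")
    groups = read_labels_tsv(groups_tsv)
    rate_rows = []
    rate_objs = []
    for i in range(0, len(records), 2):
        a = validate_cds(records[i], code, strict=strict)
        b = validate_cds(records[i + 1], code, strict=strict)
        pid = _shared_pair_id(a.gene_id, b.gene_id)
        aln = align_proteins_global(a.translate(code), b.translate(code))
        caln = thread_codons(aln, a, b, code, pair_id=pid)
        r = ng86_pair(caln, code)
        rate_objs.append(r)
        rate_rows.append(
            {"pair_id": r.pair_id, "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
             "pS": r.pS, "pN": r.pN, "dS": r.dS, "dN": r.dN,
             "status": "saturated" if r.saturated else "ok"}
        )
    contrast = group_contrast(rate_objs, groups)
    return pd.DataFrame(rate_rows), contrast


def _shared_pair_id(id_a: str, id_b: str) -> str:
    for suffix in ("_a", "_b"):
        if id_a.endswith(suffix):
            id_a = id_a[: -len(suffix)]
        if id_b.endswith(suffix):
            id_b = id_b[: -len(suffix)]
    return id_a if id_a == id_b else f"{id_a}|{id_b}"
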