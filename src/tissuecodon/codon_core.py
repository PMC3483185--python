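"""Genetic-code model, CDS ingestion and validation, codon counting.

The analyses downstream (usage metrics, internal correspondence analysis)
all consume the labeled gene x 61-sense-codon count matrix assembled here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "CodingSequence",
    "CodonCountVector",
    "CodonUsageMatrix",
    "read_fasta",
    "write_fasta",
    "read_labels_tsv",
    "validate_cds",
    "count_codons",
    "build_usage_matrix",
]

_BASES = "ACGT"
STOP = "*"


@dataclass(frozen=True)
class GeneticCode:
    """A codon table plus the derived synonymous-family structure.

    ``families`` maps each amino acid (one-letter) to its sorted list of
    synonymous codons; ``degeneracy_class`` gives the family size k in
    {1, 2, 3, 4, 6} used by Wright's ENC estimator.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]
    degeneracy_class: Mapping[str, int]
    sense_codons: tuple[str, ...]
    stop_codons: tuple[str, ...]
    codon_index: Mapping[str, int] = field(repr=False, default_factory=dict)

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_table_id(1)

    @classmethod
    def from_table_id(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa: dict[str, str] = {}
        for b1 in _BASES:
            for b2 in _BASES:
                for b3 in _BASES:
                    codon = b1 + b2 + b3
                    if codon in table.stop_codons:
                        codon_to_aa[codon] = STOP
                    else:
                        codon_to_aa[codon] = table.forward_table[codon]
        sense = tuple(sorted(c for c, a in codon_to_aa.items() if a != STOP))
        stops = tuple(sorted(table.stop_codons))
        fams: dict[str, list[str]] = {}
        for codon in sense:
            fams.setdefault(codon_to_aa[codon], []).append(codon)
        families = {aa: tuple(sorted(cods)) for aa, cods in fams.items()}
        degeneracy = {aa: len(cods) for aa, cods in families.items()}
        index = {codon: i for i, codon in enumerate(sense)}
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            families=families,
            degeneracy_class=degeneracy,
            sense_codons=sense,
            stop_codons=stops,
            codon_index=index,
        )

    def aa_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.families))


@dataclass
class CodingSequence:
    gene_id: str
    nucleotides: str
    tissue_label: str | None = None

    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]

    def translate(self, code: GeneticCode) -> str:
        out = []
        for c in self.codons():
            out.append(code.codon_to_aa.get(c, "X"))
        return "".join(out)


@dataclass
class CodonCountVector:
    """Counts over the 61 sense codons (alphabetical order); ambiguous
    codons are skipped, never imputed, and tallied in ``skipped``."""

    gene_id: str
    counts: np.ndarray
    skipped: int = 0

    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self, code: GeneticCode) -> dict[str, int]:
        return {c: int(self.counts[i]) for c, i in code.codon_index.items()}


@dataclass
class CodonUsageMatrix:
    """Genes x 61 sense codons with per-gene tissue labels.

    Row order is input order; column order is the fixed alphabetical codon
    order, so exports and eigendecompositions are reproducible.
    """

    counts: np.ndarray  # I x J
    gene_ids: list[str]
    codons: list[str]
    tissue_of: dict[str, str]
    tissues: list[str]

    @property
    def tissue_labels(self) -> list[str]:
        return [self.tissue_of[g] for g in self.gene_ids]

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.codons)
        df.insert(0, "tissue", self.tissue_labels)
        df.to_csv(path, sep="\t", index_label="gene_id")


def _clean_sequence(raw: str) -> str:
    return raw.upper().replace("U", "T").replace(" ", "")


def read_fasta(path) -> list[CodingSequence]:
    """Read a (possibly wrapped) FASTA file into CodingSequence records.

    The description line may carry a ``tissue=<name>`` key used as the
    tissue label. Uppercases and maps RNA U to DNA T.
    """
    records: list[CodingSequence] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(_make_record(header, chunks))
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise ValueError(
                        f"{path}: line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.strip())
    if header is not None:
        records.append(_make_record(header, chunks))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def _make_record(header: str, chunks: list[str]) -> CodingSequence:
    fields = header.split()
    gene_id = fields[0]
    tissue = None
    for f in fields[1:]:
        if f.startswith("tissue="):
            tissue = f[len("tissue=") :]
    return CodingSequence(gene_id, _clean_sequence("".join(chunks)), tissue)


def write_fasta(records: Iterable[CodingSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f">{rec.gene_id}"
            if rec.tissue_label is not None:
                desc += f" tissue={rec.tissue_label}"
            fh.write(desc + "\n")
            seq = rec.nucleotides
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_labels_tsv(path) -> dict[str, str]:
    """Two-column TSV gene_id<TAB>tissue; a header row is tolerated."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in {"gene_id", "gene"}:
                continue
            labels[parts[0]] = parts[1]
    return labels


def validate_cds(
    seq: CodingSequence, code: GeneticCode, strict: bool = True
) -> CodingSequence:
    """Validate a CDS: strip one terminal stop codon, enforce frame.

    Strict mode (default) rejects length % 3 != 0 and internal stop codons;
    lenient mode truncates a trailing partial codon with a warning. Codons
    containing ambiguous bases are never treated as stops.
    """
    nt = _clean_sequence(seq.nucleotides)
    if not nt:
        raise ValueError(f"{seq.gene_id}: empty sequence")
    bad = set(nt) - set("ACGTN")
    if bad:
        raise ValueError(f"{seq.gene_id}: non-nucleotide symbols {sorted(bad)}")
    if len(nt) % 3 != 0:
        if strict:
            raise ValueError(
                f"{seq.gene_id}: length {len(nt)} is not a multiple of 3"
            )
        warnings.warn(
            f"{seq.gene_id}: truncating {len(nt) % 3} trailing nucleotide(s)",
            stacklevel=2,
        )
        nt = nt[: len(nt) - len(nt) % 3]
    if len(nt) >= 3 and nt[-3:] in code.stop_codons:
        nt = nt[:-3]
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    internal = [i for i, c in enumerate(codons) if c in code.stop_codons]
    if internal:
        if strict:
            raise ValueError(
                f"{seq.gene_id}: internal stop codon(s) at codon position(s) "
                f"{[i + 1 for i in internal]}"
            )
        warnings.warn(
            f"{seq.gene_id}: {len(internal)} internal stop codon(s) retained "
            "(lenient mode); they will be ignored by codon counting",
            stacklevel=2,
        )
    return replace(seq, nucleotides=nt)


def count_codons(seq: CodingSequence, code: GeneticCode) -> CodonCountVector:
    """Count sense codons; N-containing codons are skipped and tallied."""
    counts = np.zeros(len(code.sense_codons), dtype=np.int64)
    skipped = 0
    for codon in seq.codons():
        idx = code.codon_index.get(codon)
        if idx is not None:
            counts[idx] += 1
        elif codon in code.stop_codons:
            continue
        else:
            skipped += 1
    return CodonCountVector(seq.gene_id, counts, skipped)


def build_usage_matrix(
    vectors: Sequence[CodonCountVector],
    labels: Mapping[str, str],
    code: GeneticCode | None = None,
    drop_empty: bool = True,
) -> CodonUsageMatrix:
    """Assemble the labeled gene x codon matrix consumed by the ICA.

    Empty rows (genes with no counted codons) and empty columns (codons
    never observed) are dropped with a warning because the chi-square
    metric is undefined on zero margins.
    """
    code = code or GeneticCode.standard()
    seen: set[str] = set()
    for v in vectors:
        if v.gene_id in seen:
            raise ValueError(f"duplicate gene_id {v.gene_id!r}")
        seen.add(v.gene_id)
        if v.gene_id not in labels:
            raise ValueError(f"gene {v.gene_id!r} has no tissue label")
    counts = np.vstack([v.counts for v in vectors]).astype(np.int64)
    gene_ids = [v.gene_id for v in vectors]
    codons = list(code.sense_codons)
    if drop_empty:
        row_ok = counts.sum(axis=1) > 0
        if not row_ok.all():
            dropped = [g for g, ok in zip(gene_ids, row_ok) if not ok]
            warnings.warn(f"dropping {len(dropped)} all-zero gene row(s): "
                          f"{dropped[:5]}", stacklevel=2)
            counts = counts[row_ok]
            gene_ids = [g for g, ok in zip(gene_ids, row_ok) if ok]
        col_ok = counts.sum(axis=0) > 0
        if not col_ok.all():
            dropped_c = [c for c, ok in zip(codons, col_ok) if not ok]
            warnings.warn(f"dropping {len(dropped_c)} unobserved codon "
                          f"column(s): {dropped_c[:5]}", stacklevel=2)
            counts = counts[:, col_ok]
            codons = [c for c, ok in zip(codons, col_ok) if ok]
    tissue_of = {g: labels[g] for g in gene_ids}
    tissues: list[str] = []
    for g in gene_ids:
        if tissue_of[g] not in tissues:
            tissues.append(tissue_of[g])
    return CodonUsageMatrix(counts, gene_ids, codons, tissue_of, tissues)
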