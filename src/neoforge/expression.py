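"""Transcript-abundance ingestion and the gene-level expression filter.

Abundance tables use the de-facto layout of pseudo-alignment quantifiers
(``target_id``, ``length``, ``eff_length``, ``est_counts``, ``tpm``); only
``target_id`` and ``tpm`` are required. Transcript TPMs are summed per gene,
and candidate neoepitopes from genes expressed below 1 TPM are excluded.
Candidates whose gene has no expression data are kept and flagged — the
expression filter is an optional stage, and silence is not evidence of
absence of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from neoforge.binding import AnnotatedCandidate

logger = logging.getLogger(__name__)

DEFAULT_TPM_THRESHOLD = 1.0
NO_EXPRESSION_FLAG = "no-expression-data"


@dataclass
class AbundanceRecord:
    target_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"{self.target_id}: negative TPM")


def read_abundance(path: str) -> list[AbundanceRecord]:
    """Read a quantifier abundance TSV; requires ``target_id`` and ``tpm``
    columns, ignores any others."""
    table = pd.read_csv(path, sep="\t")
    for col in ("target_id", "tpm"):
        if col not in table.columns:
            raise ValueError(f"abundance table {path} lacks required column {col!r}")
    return [
        AbundanceRecord(str(t), float(v))
        for t, v in zip(table["target_id"], table["tpm"])
    ]


def read_tx2gene(path: str) -> dict[str, str]:
    """Read a transcript-to-gene TSV (columns transcript_id, gene_symbol)."""
    table = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "gene_symbol"):
        if col not in table.columns:
            raise ValueError(f"tx2gene table {path} lacks required column {col!r}")
    return dict(zip(table["transcript_id"].astype(str),
                    table["gene_symbol"].astype(str)))


def gene_tpm(
    records: Iterable[AbundanceRecord], tx2gene: Mapping[str, str]
) -> dict[str, float]:
    """Aggregate transcript TPMs to gene level by summation.

    Transcripts absent from the transcript→gene map are ignored with a
    warning; genes with no quantified transcript are absent from the result.
    """
    out: dict[str, float] = {}
    for rec in records:
        gene = tx2gene.get(rec.target_id)
        if gene is None:
            logger.warning("transcript %s not in tx2gene map; ignored", rec.target_id)
            continue
        out[gene] = out.get(gene, 0.0) + rec.tpm
    return out


def filter_by_expression(
    candidates: list[AnnotatedCandidate],
    gene_tpm_map: Mapping[str, float],
    threshold: float = DEFAULT_TPM_THRESHOLD,
) -> tuple[list[AnnotatedCandidate], list[AnnotatedCandidate]]:
    """Partition candidates into (kept, excluded) by gene expression.

    A candidate is excluded iff its gene appears in the map with TPM below
    the threshold. Genes absent from the map keep the candidate, flagged
    ``no-expression-data``.
    """
    kept, excluded = [], []
    for cand in candidates:
        tpm = gene_tpm_map.get(cand.gene_symbol)
        if tpm is None:
            cand.expression_flag = NO_EXPRESSION_FLAG
            kept.append(cand)
        elif tpm < threshold:
            excluded.append(cand)
        else:
            kept.append(cand)
    return kept, excluded
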