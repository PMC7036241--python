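"""Cohort-level analytics: shared-neoantigen recurrence, per-residue binding
coverage profiles, and the RNA-seq genotype-concordance benchmark.

Most candidate neoepitopes are private to one tumor, but recurrent hotspot
mutations (e.g. RAC1 P29S in melanoma) produce identical peptide–HLA pairs
in many patients; the recurrence table surfaces those as candidates for
off-the-shelf vaccines. Recurrence identity includes the restricting allele:
the same peptide presented by different alleles yields distinct rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from neoforge.binding import AnnotatedCandidate, HlaAllele
from neoforge.variants import VariantRecord

logger = logging.getLogger(__name__)


def _round_half_up(value: float, digits: int = 2) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(10) ** -digits,
                                               rounding=ROUND_HALF_UP))


@dataclass
class RecurrenceRow:
    """One shared neoantigen: (gene, protein change, peptide, allele) with
    the number of carrier samples and its cohort frequency in percent."""

    gene_symbol: str
    aa_change: str
    peptide: str
    allele: HlaAllele
    n_samples: int
    cohort_size: int
    frequency_pct: float

    def __post_init__(self) -> None:
        if not 1 <= self.n_samples <= self.cohort_size:
            raise ValueError("n_samples must be in [1, cohort_size]")


def recurrence_table(
    candidates_by_sample: Mapping[str, Sequence[AnnotatedCandidate]],
    cohort_size: int,
    category_filter: set[str] | None = frozenset({"strong"}),
) -> list[RecurrenceRow]:
    """Aggregate per-sample candidates into a shared-neoantigen table.

    One row per distinct (gene, aa_change, peptide, allele) whose binder
    category is in ``category_filter`` (``None`` = no category restriction)
    in at least one sample; ``n_samples`` counts distinct carrier samples.
    Rows are sorted by ``n_samples`` descending, ties broken lexicographically
    by gene then peptide. Frequencies are 100·n/cohort_size rounded half-up
    to two decimals.
    """
    n_observed = len(candidates_by_sample)
    if cohort_size < n_observed:
        raise ValueError(
            f"cohort_size {cohort_size} smaller than the {n_observed} observed samples"
        )
    carriers: dict[tuple[str, str, str, HlaAllele], set[str]] = {}
    for sample_id, candidates in candidates_by_sample.items():
        for cand in candidates:
            if category_filter is not None and cand.category not in category_filter:
                continue
            key = (cand.gene_symbol, cand.aa_change, cand.mut_peptide, cand.allele)
            carriers.setdefault(key, set()).add(sample_id)
    rows = [
        RecurrenceRow(
            gene_symbol=gene, aa_change=change, peptide=peptide, allele=allele,
            n_samples=len(samples), cohort_size=cohort_size,
            frequency_pct=_round_half_up(100.0 * len(samples) / cohort_size),
        )
        for (gene, change, peptide, allele), samples in carriers.items()
    ]
    rows.sort(key=lambda r: (-r.n_samples, r.gene_symbol, r.peptide, r.allele.name))
    return rows


@dataclass
class CoverageProfile:
    """Per-residue binding-prediction coverage along a protein.

    Counts start at 1 for every residue — regions never covered by a
    predicted binder stay at the baseline — and each binder interval
    increments the residues it spans.
    """

    protein_length: int
    counts: list[int]


def coverage_profile(
    protein_length: int, binder_positions: Iterable[tuple[int, int]]
) -> CoverageProfile:
    """Build the coverage profile from 1-based inclusive binder intervals."""
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    counts = [1] * protein_length
    for start, end in binder_positions:
        if not 1 <= start <= end <= protein_length:
            raise ValueError(
                f"interval ({start},{end}) out of range for protein of "
                f"length {protein_length}"
            )
        for i in range(start - 1, end):
            counts[i] += 1
    return CoverageProfile(protein_length, counts)


def genotype_concordance(
    called: Sequence[VariantRecord],
    truth: Iterable[tuple[str, int, str, str]],
) -> float:
    """Fraction of called variants whose (chrom, pos, ref, alt) appears in a
    truth genotype set; sites are matched exactly, zygosity is not compared.

    Returns 0.0 with a warning when no variants were called.
    """
    truth_keys = set(truth)
    if not called:
        logger.warning("no called variants; concordance undefined, returning 0.0")
        return 0.0
    concordant = sum(1 for rec in called if rec.key in truth_keys)
    return concordant / len(called)
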