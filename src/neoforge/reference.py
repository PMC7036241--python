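"""Transcript models: coding sequences, exon maps, and coordinate conversion.

A :class:`TranscriptModel` is the reference frame for all downstream
reconstruction: it holds the spliced coding sequence (CDS), the exon map that
places the CDS on the genome, and the derived protein. Models are
assembly-agnostic — variants are validated against the supplied CDS rather
than against a particular genome build, so any assembly whose coordinates
match the exon map works.

Coordinates are 1-based inclusive throughout (matching VCF); conversions to
0-based happen only at slicing boundaries inside functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

_VALID_BASES = frozenset("ACGTN")


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Translation stops at (and excludes) the first stop codon; a trailing
    partial codon is ignored; any codon containing ``N`` yields ``X``.

    Raises
    ------
    ValueError
        If the input is empty or contains characters outside ``ACGTN``.
    """
    if not cds:
        raise ValueError("cannot translate an empty sequence")
    cds = cds.upper()
    bad = set(cds) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid nucleotide(s) in CDS: {sorted(bad)}")
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            protein.append("X")
            continue
        if codon in STOP_CODONS:
            break
        protein.append(GENETIC_CODE[codon])
    return "".join(protein)


@dataclass
class TranscriptModel:
    """A coding transcript: CDS, exon map, and derived protein.

    ``exons`` are (genomic_start, genomic_end) pairs, 1-based inclusive,
    ordered 5'→3' in *transcript* orientation: ascending genomic coordinates
    on the '+' strand, descending on the '-' strand.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str
    protein_sequence: str = field(default="")

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        self.cds_sequence = self.cds_sequence.upper()
        if not self.protein_sequence:
            self.protein_sequence = translate(self.cds_sequence)

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    def validate(self) -> None:
        """Check the model invariants, raising ``ValueError`` on violation."""
        span = sum(end - start + 1 for start, end in self.exons)
        if span != len(self.cds_sequence):
            raise ValueError(
                f"{self.transcript_id}: exon lengths sum to {span} but CDS is "
                f"{len(self.cds_sequence)} nt"
            )
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.transcript_id}: exon ({start},{end}) inverted")
        genomic_sorted = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcript (5'→3') order"
            )
        if len(self.cds_sequence) % 3 != 0:
            logger.warning(
                "%s: CDS length %d not a multiple of 3; trailing bases ignored",
                self.transcript_id, len(self.cds_sequence),
            )
        if self.protein_sequence != translate(self.cds_sequence):
            raise ValueError(f"{self.transcript_id}: protein does not match CDS")

    def contains(self, genomic_pos: int) -> bool:
        return any(start <= genomic_pos <= end for start, end in self.exons)


def genomic_to_cds(transcript: TranscriptModel, genomic_pos: int) -> int:
    """Map a genomic position to a 1-based CDS position, strand-aware.

    On the '-' strand the 3'-most genomic base of the first exon in
    transcript order maps to CDS position 1.
    """
    offset = 0
    for start, end in transcript.exons:
        if start <= genomic_pos <= end:
            if transcript.strand == "+":
                return offset + (genomic_pos - start) + 1
            return offset + (end - genomic_pos) + 1
        offset += end - start + 1
    raise ValueError(
        f"position {transcript.chrom}:{genomic_pos} not in CDS of "
        f"{transcript.transcript_id}"
    )


def cds_to_genomic(transcript: TranscriptModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds` (1-based both sides)."""
    if cds_pos < 1:
        raise ValueError("cds_pos must be >= 1")
    offset = 0
    for start, end in transcript.exons:
        length = end - start + 1
        if cds_pos <= offset + length:
            within = cds_pos - offset - 1
            if transcript.strand == "+":
                return start + within
            return end - within
        offset += length
    raise ValueError(
        f"cds_pos {cds_pos} beyond CDS of {transcript.transcript_id} "
        f"(length {offset})"
    )


def _parse_int_list(text: str) -> list[int]:
    return [int(tok) for tok in str(text).strip().strip(",").split(",") if tok]


def load_transcripts(cds_fasta: str, annotation_table: str) -> list[TranscriptModel]:
    """Load transcript models from a CDS FASTA plus an annotation table.

    The annotation table is TSV with columns ``transcript_id``,
    ``gene_symbol``, ``chrom``, ``strand``, ``exon_starts``, ``exon_ends``
    (the last two comma-separated, in ascending genomic order). FASTA records
    without an annotation row are skipped with a warning; models violating
    the transcript invariants are rejected with a logged reason.
    """
    try:
        table = pd.read_csv(annotation_table, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - surfaced as a single failure mode
        raise ValueError(f"unparseable annotation table {annotation_table}: {exc}")
    required = {"transcript_id", "gene_symbol", "chrom", "strand",
                "exon_starts", "exon_ends"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    rows = {row.transcript_id: row for row in table.itertuples(index=False)}

    models: list[TranscriptModel] = []
    for record in SeqIO.parse(cds_fasta, "fasta"):
        row = rows.get(record.id)
        if row is None:
            logger.warning("no annotation row for FASTA record %s; skipped", record.id)
            continue
        starts = _parse_int_list(row.exon_starts)
        ends = _parse_int_list(row.exon_ends)
        if len(starts) != len(ends):
            logger.warning("%s: exon_starts/exon_ends length mismatch; rejected",
                           record.id)
            continue
        exons = sorted(zip(starts, ends))
        if row.strand == "-":
            exons = exons[::-1]
        try:
            model = TranscriptModel(
                transcript_id=record.id,
                gene_symbol=row.gene_symbol,
                chrom=row.chrom,
                strand=row.strand,
                exons=[tuple(e) for e in exons],
                cds_sequence=str(record.seq),
            )
            model.validate()
        except ValueError as exc:
            logger.warning("rejected transcript %s: %s", record.id, exc)
            continue
        models.append(model)
    return models


def transcripts_by_position(
    models: list[TranscriptModel], chrom: str, pos: int
) -> list[TranscriptModel]:
    """All transcripts whose exons contain a genomic position."""
    return [m for m in models if m.chrom == chrom and m.contains(pos)]
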