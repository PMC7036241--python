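"""Mutant protein reconstruction and 21-mer neoepitope window extraction.

Each non-synonymous effect call is turned into a mutant protein by applying
the variant to the CDS and translating; for frameshifts translation simply
continues in the shifted frame until the first stop, so the novel C-terminal
peptide falls out of the same code path.

From the mutant protein a peptide *window* is cut: 21 residues with the
altered residue at the center. If fewer than 10 residues flank the mutation
on either side, the window slides to the protein edge (first or last 21
residues); proteins shorter than 21 residues are emitted whole. Frameshift
windows take up to 10 wild-type residues of context followed by the entire
novel sequence through the new C-terminus, and carry no wild-type window —
no positionally matched wild-type counterpart exists for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from neoforge.reference import TranscriptModel, translate
from neoforge.variants import EffectCall, apply_variant_to_cds, _diff_span

logger = logging.getLogger(__name__)

WINDOW_SIZE = 21
FLANK = 10  # residues on each side of the altered residue in a full window


@dataclass
class NeoepitopeWindow:
    """Paired mutant/wild-type peptide window around an altered residue.

    ``mut_index`` is the 1-based position of the first altered residue within
    ``mut_window``; ``altered_span`` the number of altered residues the window
    covers. ``wt_window`` is present only for missense windows, where it has
    the same length and differs at exactly ``mut_index``.
    """

    sample_id: str
    gene_symbol: str
    transcript_id: str
    effect_class: str
    mut_window: str
    wt_window: str | None
    mut_index: int
    altered_span: int
    label: str

    def __post_init__(self) -> None:
        if not 1 <= self.mut_index <= len(self.mut_window):
            raise ValueError("mut_index outside mut_window")


def build_mutant_protein(
    transcript: TranscriptModel, effect: EffectCall
) -> tuple[str, int]:
    """Apply the effect's variant to the CDS and translate.

    Returns the mutant protein and the 1-based position of the first residue
    differing from the wild-type protein. Frameshift translation runs through
    the shifted frame until the first stop codon.
    """
    mut_cds, _ = apply_variant_to_cds(transcript, effect.variant)
    mut_protein = translate(mut_cds) if mut_cds else ""
    wt_protein = transcript.protein_sequence
    prefix, _ = _diff_span(wt_protein, mut_protein)
    first_altered = prefix + 1
    return mut_protein, first_altered


def extract_window(
    wt_protein: str,
    mut_protein: str,
    first_altered_pos: int,
    effect_class: str,
    *,
    sample_id: str = "",
    gene_symbol: str = "",
    transcript_id: str = "",
    label: str = "",
) -> NeoepitopeWindow:
    """Cut the neoepitope window around the first altered residue.

    Missense and inframe effects yield a 21-mer with the altered residue
    centered, sliding to the protein edge when fewer than 10 residues flank
    it; a protein shorter than 21 residues is emitted whole. Frameshifts
    yield up to 10 preceding wild-type residues plus the whole novel tail.
    """
    if not 1 <= first_altered_pos <= len(mut_protein):
        raise ValueError(
            f"first_altered_pos {first_altered_pos} outside mutant protein "
            f"of length {len(mut_protein)}"
        )
    p = first_altered_pos
    n = len(mut_protein)

    if effect_class == "frameshift":
        start = max(1, p - FLANK)
        mut_window = mut_protein[start - 1 :]
        mut_index = p - start + 1
        return NeoepitopeWindow(
            sample_id, gene_symbol, transcript_id, effect_class,
            mut_window, None, mut_index,
            altered_span=len(mut_window) - mut_index + 1, label=label,
        )

    # altered run length from prefix/suffix comparison of the two proteins
    prefix, suffix = _diff_span(wt_protein, mut_protein)
    span = max(1, len(mut_protein) - suffix - prefix)

    if n <= WINDOW_SIZE:
        start = 1
    elif p - 1 < FLANK:  # mutation near the protein start
        start = 1
    elif n - p < FLANK:  # mutation near the protein end
        start = n - WINDOW_SIZE + 1
    else:
        start = p - FLANK
    end = min(n, start + WINDOW_SIZE - 1)
    mut_window = mut_protein[start - 1 : end]
    mut_index = p - start + 1
    span = min(span, len(mut_window) - mut_index + 1)

    wt_window = None
    if effect_class == "missense":
        wt_window = wt_protein[start - 1 : end]

    return NeoepitopeWindow(
        sample_id, gene_symbol, transcript_id, effect_class,
        mut_window, wt_window, mut_index, span, label,
    )


def make_window(
    transcript: TranscriptModel, effect: EffectCall, sample_id: str = ""
) -> NeoepitopeWindow | None:
    """Build the neoepitope window for a non-synonymous effect call.

    Returns ``None`` (with a warning) when the mutant protein is empty or the
    altered residue lies beyond it (e.g. an immediate stop).
    """
    mut_protein, first_altered = build_mutant_protein(transcript, effect)
    if not mut_protein or first_altered > len(mut_protein):
        logger.warning(
            "no window for %s on %s: mutant protein %s",
            effect.label, transcript.transcript_id,
            "empty" if not mut_protein else "truncated before the altered residue",
        )
        return None
    return extract_window(
        transcript.protein_sequence, mut_protein, first_altered,
        effect.effect_class,
        sample_id=sample_id,
        gene_symbol=transcript.gene_symbol,
        transcript_id=transcript.transcript_id,
        label=effect.label,
    )


def _header(window: NeoepitopeWindow, kind: str) -> str:
    ident = "|".join([
        window.sample_id, window.gene_symbol, window.transcript_id,
        window.label, kind,
    ])
    meta = f"effect={window.effect_class};index={window.mut_index};span={window.altered_span}"
    return f"{ident} {meta}"


def write_window_fasta(windows: list[NeoepitopeWindow], path: str) -> None:
    """Write windows as FASTA: ``>sample|gene|transcript|label|MUT`` records
    paired with ``...|WT`` records (the latter only when a wild-type window
    exists). Window geometry is kept in the record description."""
    with open(path, "w") as fh:
        for window in windows:
            fh.write(f">{_header(window, 'MUT')}\n{window.mut_window}\n")
            if window.wt_window is not None:
                fh.write(f">{_header(window, 'WT')}\n{window.wt_window}\n")


def read_window_fasta(path: str) -> list[NeoepitopeWindow]:
    """Inverse of :func:`write_window_fasta` (round-trip identity)."""
    from Bio import SeqIO

    windows: dict[tuple, dict] = {}
    order: list[tuple] = []
    for record in SeqIO.parse(path, "fasta"):
        parts = record.id.split("|")
        if len(parts) != 5 or parts[4] not in {"MUT", "WT"}:
            raise ValueError(f"malformed window FASTA header: {record.description}")
        sample, gene, transcript, label, kind = parts
        meta = {}
        desc = record.description.split(None, 1)
        if len(desc) == 2:
            meta = dict(kv.split("=", 1) for kv in desc[1].split(";") if "=" in kv)
        if "effect" not in meta or "index" not in meta or "span" not in meta:
            raise ValueError(f"window FASTA header missing metadata: {record.description}")
        key = (sample, gene, transcript, label)
        if key not in windows:
            windows[key] = {
                "sample_id": sample, "gene_symbol": gene,
                "transcript_id": transcript, "label": label,
                "effect_class": meta["effect"],
                "mut_index": int(meta["index"]),
                "altered_span": int(meta["span"]),
                "mut_window": None, "wt_window": None,
            }
            order.append(key)
        windows[key]["mut_window" if kind == "MUT" else "wt_window"] = str(record.seq)

    out = []
    for key in order:
        fields = windows[key]
        if fields["mut_window"] is None:
            raise ValueError(f"window {key} has a WT record but no MUT record")
        out.append(NeoepitopeWindow(**fields))
    return out
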