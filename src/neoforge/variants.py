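"""VCF ingestion, the RNA-seq depth filter, and variant effect classification.

Variants are read per (sample, biallelic alt): multi-allelic records are
split on ingest and star alleles dropped, so all downstream logic is
biallelic. Tumor-only calling produces no matched normal, so every called
non-reference genotype is accepted as somatic.

Effect classification works from first principles — the variant is applied
to the transcript CDS and both proteins are compared — but snpEff-style ANN
annotations carried by the VCF can optionally be trusted instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from cyvcf2 import VCF

from neoforge.reference import TranscriptModel, genomic_to_cds, translate

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NON_SYNONYMOUS_CLASSES = frozenset(
    {"missense", "inframe_insertion", "inframe_deletion", "frameshift"}
)

# snpEff sequence-ontology terms -> internal effect classes
_ANN_EFFECT_MAP = {
    "missense_variant": "missense",
    "conservative_inframe_insertion": "inframe_insertion",
    "disruptive_inframe_insertion": "inframe_insertion",
    "inframe_insertion": "inframe_insertion",
    "conservative_inframe_deletion": "inframe_deletion",
    "disruptive_inframe_deletion": "inframe_deletion",
    "inframe_deletion": "inframe_deletion",
    "frameshift_variant": "frameshift",
    "synonymous_variant": "synonymous",
}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class VariantRecord:
    """One biallelic variant call in one sample, with RNA-seq depth fields."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    sample_id: str
    depth: int = 0
    alt_depth: int = 0
    depth_known: bool = True
    alt_depth_known: bool = True
    annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")
        if self.depth_known and self.alt_depth_known and self.alt_depth > self.depth:
            raise ValueError("alt_depth exceeds depth")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class EffectCall:
    """A variant mapped onto a transcript, with its protein-level effect."""

    variant: VariantRecord
    transcript_id: str
    effect_class: str  # missense | inframe_insertion | inframe_deletion |
    #                    frameshift | synonymous | other
    cds_pos: int
    protein_pos: int  # 1-based first altered residue
    ref_aa: str
    alt_aa: str

    @property
    def label(self) -> str:
        """Short protein-change string, e.g. ``P29S`` or ``K5fs``."""
        p = self.protein_pos
        if self.effect_class == "missense":
            return f"{self.ref_aa}{p}{self.alt_aa}"
        if self.effect_class == "frameshift":
            return f"{self.ref_aa or '*'}{p}fs"
        if self.effect_class == "inframe_insertion":
            return f"{p}ins{self.alt_aa}"
        if self.effect_class == "inframe_deletion":
            return f"{p}del{self.ref_aa}"
        if self.effect_class == "synonymous":
            return f"{self.ref_aa}{p}="
        return f"{self.ref_aa or '?'}{p}{self.alt_aa or '?'}"


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a single- or multi-sample VCF into per-(sample, alt) records.

    One record is produced for every sample/alt pair where the sample's
    genotype calls that alt. DP is taken from FORMAT DP with INFO DP as
    fallback; alt depth from the alt's FORMAT AD column. Missing depth
    values are recorded as 0 with the corresponding ``*_known`` flag False.
    """
    try:
        vcf = VCF(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot open VCF {path}: {exc}")
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for var in vcf:
        alts = var.ALT or []
        ann = []
        try:
            raw_ann = var.INFO.get("ANN")
        except Exception:  # noqa: BLE001 - absent INFO field
            raw_ann = None
        if raw_ann:
            ann = str(raw_ann).split(",")
        dp_fmt = var.format("DP") if samples else None
        ad_fmt = var.format("AD") if samples else None
        info_dp = var.INFO.get("DP")

        if not samples:
            # sites-only VCF: emit one pseudo-sample record per alt
            for alt in alts:
                if alt == "*" or alt == var.REF:
                    continue
                records.append(VariantRecord(
                    chrom=var.CHROM, pos=var.POS, ref_allele=var.REF,
                    alt_allele=alt, sample_id="SAMPLE",
                    depth=int(info_dp) if info_dp is not None else 0,
                    depth_known=info_dp is not None,
                    alt_depth=0, alt_depth_known=False,
                    annotations=[a for a in ann if a.startswith(f"{alt}|")] or ann,
                ))
            continue

        for si, sample in enumerate(samples):
            gt = var.genotypes[si]
            called_alts = sorted({a for a in gt[:-1] if isinstance(a, int) and a > 0})
            for ai in called_alts:
                alt = alts[ai - 1]
                if alt == "*":
                    continue
                depth_known, depth = False, 0
                if dp_fmt is not None and dp_fmt[si][0] >= 0:
                    depth, depth_known = int(dp_fmt[si][0]), True
                elif info_dp is not None:
                    depth, depth_known = int(info_dp), True
                alt_known, alt_depth = False, 0
                if ad_fmt is not None and ad_fmt.shape[1] > ai and ad_fmt[si][ai] >= 0:
                    alt_depth, alt_known = int(ad_fmt[si][ai]), True
                if depth_known and alt_known and alt_depth > depth:
                    depth = alt_depth  # tolerate inconsistent DP/AD
                records.append(VariantRecord(
                    chrom=var.CHROM, pos=var.POS, ref_allele=var.REF,
                    alt_allele=alt, sample_id=sample,
                    depth=depth, depth_known=depth_known,
                    alt_depth=alt_depth, alt_depth_known=alt_known,
                    annotations=[a for a in ann if a.startswith(f"{alt}|")] or ann,
                ))
    return records


def filter_rnaseq_variants(
    records: list[VariantRecord], min_depth: int = 10, min_alt: int = 5
) -> list[VariantRecord]:
    """Keep variants with total depth >= ``min_depth`` and alt-supporting
    reads >= ``min_alt`` (the RNA-seq calling quality filter).

    Records with unknown DP or AD fail the filter. Order is preserved and
    the input list is not modified.
    """
    return [
        r for r in records
        if r.depth_known and r.alt_depth_known
        and r.depth >= min_depth and r.alt_depth >= min_alt
    ]


def apply_variant_to_cds(
    transcript: TranscriptModel, variant: VariantRecord
) -> tuple[str, int]:
    """Apply a variant to the transcript CDS; return (mutant CDS, cds_pos).

    Alleles are given on the genomic '+' strand and are reverse-complemented
    for '-'-strand transcripts. The entire REF allele must lie within the
    transcript's exons.
    """
    ref, alt = variant.ref_allele.upper(), variant.alt_allele.upper()
    if transcript.strand == "+":
        cds_pos = genomic_to_cds(transcript, variant.pos)
        ref_c, alt_c = ref, alt
    else:
        # the 3'-most genomic base of REF is the 5'-most CDS base
        cds_pos = genomic_to_cds(transcript, variant.pos + len(ref) - 1)
        ref_c, alt_c = _revcomp(ref), _revcomp(alt)
    cds = transcript.cds_sequence
    end = cds_pos - 1 + len(ref_c)
    if end > len(cds):
        raise ValueError(
            f"variant at {variant.chrom}:{variant.pos} extends past the CDS of "
            f"{transcript.transcript_id}"
        )
    observed = cds[cds_pos - 1 : end]
    if observed != ref_c:
        raise ValueError(
            f"REF allele mismatch at CDS {cds_pos} of {transcript.transcript_id}: "
            f"expected {ref_c}, CDS has {observed}"
        )
    return cds[: cds_pos - 1] + alt_c + cds[end:], cds_pos


def _diff_span(wt: str, mut: str) -> tuple[int, int]:
    """Common-prefix length and common-suffix length between two proteins,
    constrained so prefix + suffix <= min length."""
    prefix = 0
    for a, b in zip(wt, mut):
        if a != b:
            break
        prefix += 1
    suffix = 0
    max_suffix = min(len(wt), len(mut)) - prefix
    while suffix < max_suffix and wt[len(wt) - 1 - suffix] == mut[len(mut) - 1 - suffix]:
        suffix += 1
    return prefix, suffix


def effect_from_annotations(
    variant: VariantRecord, transcript_id: str
) -> str | None:
    """Effect class for a transcript from snpEff-style ANN strings, if any."""
    for ann in variant.annotations:
        fields = ann.split("|")
        if len(fields) < 7:
            continue
        if fields[6] and fields[6] != transcript_id:
            continue
        for term in fields[1].split("&"):
            if term in _ANN_EFFECT_MAP:
                return _ANN_EFFECT_MAP[term]
    return None


def classify_effect(
    variant: VariantRecord,
    transcript: TranscriptModel,
    trust_annotations: bool = False,
) -> EffectCall:
    """Classify a variant's effect on a transcript by translate-and-compare.

    The variant is applied to the CDS and the wild-type and mutant proteins
    are compared: identical proteins -> synonymous; an indel whose net length
    change is not divisible by 3 -> frameshift; frame-preserving length
    change -> inframe insertion/deletion; same-length substitution ->
    missense; stop-gain, stop-loss and start-loss -> other.

    With ``trust_annotations=True``, a snpEff-style ANN entry matching the
    transcript overrides the computed effect class (positions and residues
    are still computed from the models).
    """
    mut_cds, cds_pos = apply_variant_to_cds(transcript, variant)
    wt_protein = transcript.protein_sequence
    mut_protein = translate(mut_cds) if mut_cds else ""

    prefix, suffix = _diff_span(wt_protein, mut_protein)
    length_shift = len(variant.alt_allele) - len(variant.ref_allele)
    if length_shift % 3 != 0:
        # frame-disrupting by definition, even if the shifted translation
        # happens to re-encode the wild-type residues
        protein_pos = prefix + 1
        ref_aa = wt_protein[prefix : prefix + 1]
        alt_aa = mut_protein[prefix : prefix + 1]
        call = EffectCall(variant, transcript.transcript_id, "frameshift",
                          cds_pos, protein_pos, ref_aa, alt_aa)
    elif wt_protein == mut_protein:
        protein_pos = (cds_pos + 2) // 3
        aa = wt_protein[protein_pos - 1] if protein_pos <= len(wt_protein) else ""
        call = EffectCall(variant, transcript.transcript_id, "synonymous",
                          cds_pos, protein_pos, aa, aa)
    else:
        protein_pos = prefix + 1
        ref_aa = wt_protein[prefix : len(wt_protein) - suffix]
        alt_aa = mut_protein[prefix : len(mut_protein) - suffix]
        if not mut_protein or (wt_protein[:1] == "M" and mut_protein[:1] != "M"):
            effect = "other"  # start-loss
        elif len(mut_protein) < len(wt_protein) and wt_protein.startswith(mut_protein):
            effect = "other"  # stop-gain
        elif len(mut_protein) > len(wt_protein) and mut_protein.startswith(wt_protein):
            effect = "other"  # stop-loss
        elif len(mut_protein) == len(wt_protein):
            effect = "missense"
        elif len(mut_protein) > len(wt_protein):
            effect = "inframe_insertion"
        else:
            effect = "inframe_deletion"
        call = EffectCall(variant, transcript.transcript_id, effect,
                          cds_pos, protein_pos, ref_aa, alt_aa)

    if trust_annotations:
        annotated = effect_from_annotations(variant, transcript.transcript_id)
        if annotated is not None and annotated != call.effect_class:
            logger.info(
                "ANN overrides computed effect for %s on %s: %s -> %s",
                variant.key, transcript.transcript_id,
                call.effect_class, annotated,
            )
            call.effect_class = annotated
    return call
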