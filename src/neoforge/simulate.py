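"""Deterministic synthetic-data generator for end-to-end testing.

Generates a self-contained fixture directory — transcript models, per-sample
somatic VCFs with planted recurrent variants, per-sample abundance tables,
and an HLA allele list — so every pipeline stage is exercisable without any
download. Defaults emulate a melanoma-scale tumor cohort: 466 samples with
recurrent hotspot missense variants planted in 17, 6 and 5 carriers
(mirroring the observed sharing of RAC1 P29S-class hotspots), a couple of
private background variants per sample, and read depths spanning both sides
of the DP >= 10 / alt >= 5 RNA-seq filter thresholds.

Everything derives from a single seed. Carrier samples for planted variants
are the first ``n_carriers`` samples, so the carrier sets are stable across
seeds while background noise and sequences change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from neoforge.reference import GENETIC_CODE, STOP_CODONS, TranscriptModel, translate

SENSE_CODONS = sorted(set(GENETIC_CODE) - STOP_CODONS)
DEFAULT_ALLELES = ("HLA-A*02:01", "HLA-A*11:01")
_BASES = "ACGT"


@dataclass
class PlantedVariant:
    """A variant planted in the first ``n_carriers`` samples of the cohort."""

    gene_index: int
    effect_class: str  # missense | frameshift | inframe_insertion | inframe_deletion
    protein_pos: int
    n_carriers: int


@dataclass
class FixtureSpec:
    """Conditions of the synthetic cohort."""

    n_genes: int = 6
    cds_length_range: tuple[int, int] = (260, 340)  # codons
    n_samples: int = 466
    planted_variants: list[PlantedVariant] = field(default_factory=lambda: [
        PlantedVariant(0, "missense", 29, 17),
        PlantedVariant(1, "missense", 250, 6),
        PlantedVariant(2, "missense", 29, 5),
    ])
    background_per_sample: int = 2
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.cds_length_range
        if not 2 <= lo <= hi:
            raise ValueError("cds_length_range must satisfy 2 <= min <= max")
        for pv in self.planted_variants:
            if not 0 <= pv.gene_index < self.n_genes:
                raise ValueError(f"planted gene index {pv.gene_index} out of range")
            if not 2 <= pv.protein_pos <= lo - 1:
                raise ValueError(
                    f"planted protein_pos {pv.protein_pos} not guaranteed valid "
                    f"for CDSs of >= {lo} codons"
                )
            if pv.n_carriers > self.n_samples:
                raise ValueError("n_carriers exceeds n_samples")


@dataclass
class Reference:
    models: list[TranscriptModel]
    cds_fasta: Path
    annotation_tsv: Path
    tx2gene_tsv: Path


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def make_reference(spec: FixtureSpec, outdir: str | Path) -> Reference:
    """Generate random single-exon transcript models, reproducibly.

    Each CDS starts with ATG, ends with a stop codon, and contains no
    internal stop; transcript ``i`` sits on its own chromosome ``chr{i+1}``
    with the exon starting at genomic position 1001.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    models = []
    lo, hi = spec.cds_length_range
    for i in range(spec.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        internal = rng.choice(SENSE_CODONS, size=n_codons - 1)
        cds = "ATG" + "".join(internal[1:]) + "TAA"
        start = 1001
        model = TranscriptModel(
            transcript_id=f"TX{i:03d}",
            gene_symbol=f"GENE{i:03d}",
            chrom=f"chr{i + 1}",
            strand="+",
            exons=[(start, start + len(cds) - 1)],
            cds_sequence=cds,
        )
        model.validate()
        models.append(model)

    cds_fasta = outdir / "cds.fasta"
    with open(cds_fasta, "w") as fh:
        for m in models:
            fh.write(f">{m.transcript_id}\n{m.cds_sequence}\n")
    annotation_tsv = outdir / "transcripts.tsv"
    with open(annotation_tsv, "w") as fh:
        fh.write("transcript_id\tgene_symbol\tchrom\tstrand\texon_starts\texon_ends\n")
        for m in models:
            starts = ",".join(str(s) for s, _ in sorted(m.exons))
            ends = ",".join(str(e) for _, e in sorted(m.exons))
            fh.write(f"{m.transcript_id}\t{m.gene_symbol}\t{m.chrom}\t{m.strand}"
                     f"\t{starts}\t{ends}\n")
    tx2gene_tsv = outdir / "tx2gene.tsv"
    with open(tx2gene_tsv, "w") as fh:
        fh.write("transcript_id\tgene_symbol\n")
        for m in models:
            fh.write(f"{m.transcript_id}\t{m.gene_symbol}\n")
    return Reference(models, cds_fasta, annotation_tsv, tx2gene_tsv)


def _plant_alleles(model: TranscriptModel, pv: PlantedVariant) -> tuple[int, str, str]:
    """Genomic (pos, ref, alt) realizing the requested effect at protein_pos."""
    cds = model.cds_sequence
    exon_start = model.exons[0][0]
    p = pv.protein_pos
    o = 3 * (p - 1)  # 0-based offset of the codon's first base
    codon = cds[o : o + 3]
    if pv.effect_class == "missense":
        old_aa = GENETIC_CODE[codon]
        for cpos in range(3):
            for base in _BASES:
                if base == codon[cpos]:
                    continue
                new = codon[:cpos] + base + codon[cpos + 1 :]
                if new not in STOP_CODONS and GENETIC_CODE[new] != old_aa:
                    return exon_start + o + cpos, codon[cpos], base
        raise RuntimeError("no missense substitution found")  # unreachable
    if pv.effect_class == "frameshift":
        # delete the codon's first base, anchored on the preceding base
        return exon_start + o - 1, cds[o - 1 : o + 1], cds[o - 1]
    if pv.effect_class == "inframe_insertion":
        # insert an alanine codon after codon p, anchored on its last base
        return exon_start + o + 2, cds[o + 2], cds[o + 2] + "GCA"
    if pv.effect_class == "inframe_deletion":
        # delete codon p, anchored on the last base of codon p-1
        return exon_start + o - 1, cds[o - 1 : o + 3], cds[o - 1]
    raise ValueError(f"unsupported planted effect class {pv.effect_class!r}")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""


def make_cohort_vcfs(
    spec: FixtureSpec, reference: Reference, outdir: str | Path
) -> list[Path]:
    """Write one single-sample somatic VCF per cohort sample.

    Planted variants appear in exactly the first ``n_carriers`` samples of
    the cohort; every sample additionally receives private background SNVs.
    DP is drawn uniformly from [4, 80) and alt depth from [1, DP], so records
    on both sides of the (DP 10, alt 5) filter thresholds exist.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = reference.models
    planted = [(pv, *_plant_alleles(models[pv.gene_index], pv))
               for pv in spec.planted_variants]

    contigs = "".join(
        f"##contig=<ID={m.chrom},length={m.exons[0][1] + 1000}>\n" for m in models
    )
    paths = []
    for si, sample in enumerate(_sample_ids(spec.n_samples)):
        rows = []
        taken: set[tuple[str, int]] = set()
        for pv, pos, ref, alt in planted:
            dp = int(rng.integers(4, 80))
            ad = int(rng.integers(1, dp + 1))
            if si < pv.n_carriers:
                model = models[pv.gene_index]
                rows.append((model.chrom, pos, ref, alt, dp, ad))
                taken.add((model.chrom, pos))
        for _ in range(spec.background_per_sample):
            model = models[int(rng.integers(len(models)))]
            cds_off = int(rng.integers(len(model.cds_sequence)))
            pos = model.exons[0][0] + cds_off
            ref = model.cds_sequence[cds_off]
            alt = _BASES[int(rng.integers(4))]
            dp = int(rng.integers(4, 80))
            ad = int(rng.integers(1, dp + 1))
            if alt == ref or (model.chrom, pos) in taken:
                continue  # skip colliding/no-op draws; keeps determinism
            taken.add((model.chrom, pos))
            rows.append((model.chrom, pos, ref, alt, dp, ad))
        rows.sort(key=lambda r: (r[0], r[1]))
        path = outdir / f"{sample}.vcf"
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER + contigs)
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     f"{sample}\n")
            for chrom, pos, ref, alt, dp, ad in rows:
                fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                         f"GT:DP:AD\t0/1:{dp}:{dp - ad},{ad}\n")
        paths.append(path)
    return paths


def make_abundance(
    reference: Reference, spec: FixtureSpec, outdir: str | Path
) -> list[Path]:
    """Write one abundance TSV per sample in the quantifier layout.

    Genes carrying planted variants are always expressed at >= 1 TPM; the
    last gene is pinned below 1 TPM so the expression-filter boundary is
    represented; remaining transcripts draw log-normal TPMs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    planted_genes = {pv.gene_index for pv in spec.planted_variants}
    low_gene = spec.n_genes - 1
    paths = []
    for sample in _sample_ids(spec.n_samples):
        path = outdir / f"{sample}.tsv"
        with open(path, "w") as fh:
            fh.write("target_id\tlength\teff_length\test_counts\ttpm\n")
            for gi, model in enumerate(reference.models):
                draw = float(rng.lognormal(mean=0.0, sigma=1.5))
                if gi in planted_genes and gi != low_gene:
                    tpm = 1.0 + draw
                elif gi == low_gene:
                    tpm = min(0.99, 0.2 * draw)
                else:
                    tpm = draw
                length = len(model.cds_sequence)
                fh.write(f"{model.transcript_id}\t{length}\t{length - 100}\t"
                         f"{tpm * 10:.2f}\t{tpm:.4f}\n")
        paths.append(path)
    return paths


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, object]:
    """Generate a complete fixture directory and its run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = make_reference(spec, outdir / "reference")
    vcfs = make_cohort_vcfs(spec, reference, outdir / "vcfs")
    abundance = make_abundance(reference, spec, outdir / "expression")
    alleles_path = outdir / "alleles.txt"
    alleles_path.write_text("\n".join(DEFAULT_ALLELES) + "\n")
    manifest = {
        "spec": asdict(spec),
        "distributions": {
            "depth": "uniform integer [4, 80)",
            "alt_depth": "uniform integer [1, DP]",
            "tpm": "lognormal(0, 1.5); planted genes shifted >= 1, "
                   "last gene capped < 1",
        },
        "carriers": {
            f"planted_{i}": _sample_ids(spec.n_samples)[: pv.n_carriers]
            for i, pv in enumerate(spec.planted_variants)
        },
        "alleles": list(DEFAULT_ALLELES),
        "n_vcfs": len(vcfs),
        "n_abundance_tables": len(abundance),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "reference": reference,
        "vcfs": vcfs,
        "abundance": abundance,
        "alleles": alleles_path,
        "manifest": outdir / "manifest.json",
    }
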