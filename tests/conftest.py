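import textwrap

import pytest

from neoforge.reference import TranscriptModel


VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    ##contig=<ID=chr1,length=100000>
    ##contig=<ID=chr2,length=100000>
    """)


def write_vcf(path, body_lines, samples=("S1",)):
    """Write a small VCF with the standard test header."""
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    header = VCF_HEADER + cols + "\t" + "\t".join(samples) + "\n"
    path.write_text(header + "\n".join(body_lines) + "\n")
    return path


def make_transcript(cds, transcript_id="TX1", gene="GENE1", chrom="chr1",
                    strand="+", start=101):
    """Single-exon transcript model wrapping a CDS at genomic `start`."""
    if strand == "+":
        exons = [(start, start + len(cds) - 1)]
    else:
        exons = [(start, start + len(cds) - 1)]
    model = TranscriptModel(
        transcript_id=transcript_id, gene_symbol=gene, chrom=chrom,
        strand=strand, exons=exons, cds_sequence=cds,
    )
    model.validate()
    return model


@pytest.fixture
def toy_cds():
    # MKPGFLS*  (8 codons incl. stop)
    return "ATGAAACCCGGGTTTCTGAGCTAA"


@pytest.fixture
def toy_transcript(toy_cds):
    return make_transcript(toy_cds)
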