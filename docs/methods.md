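# Methods

## Scope and model

`neoforge` turns somatic variant calls into ranked HLA-restricted neoepitope
candidates. The pipeline assumes variant calling, HLA typing and transcript
quantification have already happened upstream: its inputs are a VCF, a list
of HLA alleles, user-supplied transcript models (CDS FASTA + exon-map table),
and optionally a transcript-abundance table. It is assembly-agnostic —
variants are validated against the supplied CDS (the REF allele must match
the coding sequence at the mapped position) rather than against a particular
genome build, so any assembly whose coordinates match the exon maps works.
All internal coordinates are 1-based inclusive, matching VCF; conversions
happen only at slicing boundaries.

## Variant ingestion and effect classification

VCFs (single- or multi-sample) are read via cyvcf2 into one record per
(sample, biallelic alt) with a called non-reference genotype; multi-allelic
sites are split and star alleles dropped. Because tumor-only calling provides
no matched normal, every called non-reference genotype is treated as somatic.
DP comes from FORMAT DP with INFO DP fallback; alt support from the alt's
FORMAT AD column; missing values are recorded as 0 and flagged unknown.

The RNA-seq quality filter keeps records with DP ≥ 10 and alt-supporting
reads ≥ 5 (both defaults exposed as `--min-dp`/`--min-alt`). "Supported by at
least five reads" is read as alt-allele support (AD), the conservative
interpretation; records with unknown DP/AD fail the filter. The filter is an
opt-in stage (`--rna-filter`): it exists to control the false-positive rate
of RNA-seq-derived calls and is not applied to genome-derived somatic VCFs,
whose calling pipeline has its own filters.

Effects are classified from first principles by applying the variant to the
CDS and comparing translations, with this precedence:

1. an indel whose net length change is not divisible by 3 is a *frameshift*
   (by definition — even in the rare case where the shifted frame happens to
   re-encode the wild-type residues before a stop);
2. identical proteins → *synonymous*;
3. start-loss, stop-gain and stop-loss → *other* (no window is built: the
   altered "sequence" is a truncation, not a novel peptide);
4. equal-length proteins → *missense*; frame-preserving length changes →
   *inframe_insertion*/*inframe_deletion*.

Translation uses the standard genetic code, stops at (and excludes) the first
stop codon, drops a trailing partial codon, and renders any N-containing
codon as `X`. A CDS whose length is not a multiple of 3 is accepted with a
warning (tolerant ingestion of imperfect models); models whose exon lengths
disagree with the CDS length are rejected with a logged reason.

snpEff-style ANN strings, when present in the VCF, can be trusted instead of
the computed class (`--trust-annotations`); positions and residues are still
derived from the transcript models.

## Windows

The neoepitope window is a protein-space object: 21 residues with the first
altered residue at the center (index 11). "Near the start/end" is read at the
protein level — fewer than 10 flanking residues triggers the edge rule
(window = first or last 21 residues); proteins shorter than 21 residues are
emitted whole. For inframe indels that alter a run of residues the window
centers the *first* altered residue and `altered_span` records the run
length; anchoring on the first residue is deterministic and keeps the rule
identical to the missense case. Frameshift windows consist of up to 10
wild-type context residues followed by the entire novel tail through the new
C-terminus.

Wild-type pairing exists only for missense windows, where the wild-type
protein has a residue-for-residue counterpart; frameshift (and inframe-indel)
candidates therefore carry no DAI. Pairing a frameshift tail against the
reference protein would compare unrelated sequences, so it is deliberately
not done.

Window FASTA headers follow `>sample|gene|transcript|label|MUT` (or `|WT`);
window geometry (effect class, altered index, span) rides in the FASTA
description so that read/write is an identity round trip.

## Scoring, DAI and tiers

Candidate k-mers are every substring of the mutant window covering at least
one altered residue. Default lengths are 8–11 for class I and 15 for class II
— the conventional ranges for peptides presented by the two MHC classes.

Predictors sit behind a batch adapter (peptides + allele → IC50 list, order
preserving). The registered published methods (seven IEDB class I methods,
MHCflurry, four IEDB class II methods) are declared as out-of-process command
templates to be configured by the user; their scoring models are licensed
artifacts and are not re-implemented here. The built-in `toy` predictor is a
fixed position-weight scheme: per-allele, per-position residue weights in
[0, 1) derived from MD5 digests (stable across platforms and Python hash
randomization), averaged over the peptide and mapped to `50000**s` nM. It
produces deterministic, allele- and anchor-sensitive values in (1, 50000] —
enough structure to exercise every downstream stage — but it encodes no
binding biology: absolute affinities, tier proportions and DAI values under
the toy predictor are arbitrary. Wild-type peptides are scored in the same
pass with the same method.

DAI = IC50_wt / IC50_mut, so DAI > 1 means the mutation improves predicted
binding. Tier boundaries: strong < 50 nM; intermediate [50, 250] nM; weak
(250, 500) nM; non-binding ≥ 500 nM. The boundary inclusivities are pinned so
the three named tiers plus non-binding exactly partition (0, ∞); reports
render the tiers as High/Moderate/Low/Non-binding.

Scoring is batched and parallelizable by sample; unique (peptide, allele)
pairs are scored once and results are merged in a deterministic sort order,
so output is invariant to batch size, worker count and input order. A failing
predictor batch is logged and skipped without affecting other batches.

## Expression filter

Transcript TPMs are aggregated to gene level by summation (a gene is
expressed to the extent its isoforms are), and candidates from genes below
1 TPM (default, `--min-tpm`) are excluded. "Under 1 TPM" is read strictly: a
gene at exactly 1.0 TPM is kept. Genes absent from the abundance data keep
their candidates, flagged `no-expression-data` — the filter is an optional
evidence layer, and missing quantification is not evidence of silence.

## Cohort analytics

Recurrence rows are keyed by (gene, protein change, peptide, allele) — the
same peptide restricted by different alleles is a different vaccine target —
and count distinct carrier samples. Frequencies are 100·n/cohort_size rounded
half-up to two decimals (17/466 → 3.65). By default only strong binders are
tabulated (`--categories strong`); `--categories all` disables the tier
filter, which is also how the planted-recovery test isolates recurrence
counting from the toy predictor's arbitrary affinities.

Coverage profiles initialize every residue of a protein at 1 and increment
the residues each predicted binder spans, so uncovered regions remain visible
at baseline; `sum(counts) = protein_length + Σ interval lengths` is the
tested identity.

Genotype concordance is the fraction of called variants whose
(chrom, pos, ref, alt) appears in a truth set; sites are matched exactly and
zygosity is not compared. An empty call set returns 0.0 with a warning.

## Synthetic data generator

The generator emulates a melanoma-scale tumor cohort: by default 466 samples
over 6 single-exon transcripts of 260–340 codons, with recurrent missense
variants planted in 17, 6 and 5 carriers (the sharing pattern of hotspot
mutations such as RAC1 P29S/P29L and SERPINB3 E250K in large melanoma
cohorts, including one planted at protein position 29 and one at 250), two
private background SNVs per sample, read depths uniform on [4, 80) with alt
depth uniform on [1, DP] (straddling the DP 10 / alt 5 filter boundaries),
and log-normal TPMs with planted genes pinned ≥ 1 TPM and one gene pinned
below 1 TPM. Carriers are always the first n samples, so carrier sets are
stable across seeds while sequences and noise vary; everything else derives
from a single seed, and identical seeds produce byte-identical files.

What the generator does *not* emulate: mutational signatures, multi-exon
splicing, minus-strand genes (exercised in unit tests but not in fixtures),
linked variants and phasing, allele-specific expression, and any realistic
relationship between mutation and binding affinity (the toy predictor is
content-blind). Passing end-to-end tests therefore demonstrates that the
plumbing — coordinate mapping, reconstruction, windowing, enumeration,
counting, filtering — is correct under realistic file formats and scales, not
that predictions on real tumors are accurate; accuracy is inherited from
whichever external predictor is configured.

## Numerical and design choices

- Percentage rounding is decimal half-up (not banker's), to two decimals.
- Candidate reports sort by mutant IC50 ascending with a stable mergesort and
  lexicographic tie-breaks, making reruns byte-identical.
- Effect labels use a compact protein notation (`P29S`, `K5fs`, `3insA`).
- The recurrence table raises if the observed sample count exceeds the stated
  cohort size rather than silently renormalizing.
- Degenerate inputs are handled, not crashed on: empty mutant proteins skip
  window production with a warning, k longer than a window yields an empty
  candidate list with a warning, and an empty call set yields concordance 0.

## Problem sizes in the test suite

The end-to-end recurrence check runs the full pipeline over all 466
single-sample VCFs of the default synthetic cohort with one allele and
9-mers, which completes in seconds; unit and property tests run on small
constructed sequences. These sizes were chosen to keep the suite fast while
still covering the cohort-scale code paths at their default dimensions.
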