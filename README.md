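# neoforge

Neoantigen candidate discovery from somatic variants: from an annotated VCF
and transcript models to ranked, expression-filtered, HLA-restricted
neoepitope candidates, with cohort-level shared-neoantigen analytics.

Tumor-specific somatic mutations create mutated peptides (neoantigens) that
the immune system can recognize as foreign, making them prime targets for
personalized vaccines and engineered T-cell therapies. `neoforge` is aimed at
computational immuno-oncology researchers who have somatic variant calls and
want a transparent, testable path from those calls to a prioritized candidate
list — and, across a cohort, to the shared (recurrent) neoantigens that could
serve more than one patient.

## What it computes

For each non-synonymous somatic variant (missense, inframe indel, frameshift)
mapped onto a transcript model:

1. **Mutant protein reconstruction** — the variant is applied to the coding
   sequence and translated; frameshift translation continues in the shifted
   frame until the first stop, producing the novel C-terminal peptide.
2. **Neoepitope window** — a 21-mer with the altered residue at the center.
   With fewer than 10 flanking residues the window slides to the protein edge
   (first or last 21 residues). Missense windows are paired with the
   positionally matched wild-type 21-mer; frameshift windows have no
   wild-type counterpart.
3. **Candidate enumeration and scoring** — every k-mer covering an altered
   residue (class I lengths 8–11, class II 15) is scored against each HLA
   allele through a pluggable predictor adapter (batch of peptides + allele →
   IC50 in nM). Predicted binders are tiered by IC50:
   strong < 50 nM ≤ intermediate ≤ 250 nM < weak < 500 nM ≤ non-binding.
4. **Differential agretopicity index (DAI)** — the wild-type/mutant IC50 fold
   change, `DAI = IC50_wt / IC50_mut`; DAI > 1 flags a mutation that improves
   HLA binding over its wild-type counterpart.
5. **Expression filter** — transcript TPMs are summed per gene and candidates
   from genes expressed below 1 TPM are excluded.
6. **Cohort analytics** — shared-neoantigen recurrence tables (one row per
   gene/protein-change/peptide/allele with carrier counts and cohort
   frequency), per-residue binding coverage profiles, and a genotype
   concordance benchmark for RNA-seq-derived calls against a truth set.

The registry declares the conventional class I predictors (NetMHC, NetMHCpan,
NetMHCcons, NetMHCstabpan, PickPocket, SMM, SMMPMBEC, MHCflurry) and class II
predictors (NetMHCIIpan, NN-align, SMM-align, Sturniolo) as out-of-process
command adapters; a deterministic built-in `toy` predictor ships executable so
the entire pipeline runs and tests reproducibly without external binaries. The
toy predictor is a fixed position-weight scheme, not a trained affinity model
— see `docs/methods.md`.

## Worked example

Generate a synthetic cohort (466 samples, recurrent variants planted in 17, 6
and 5 carriers) and run one sample:

```bash
neoforge simulate --out fx --seed 7
neoforge run \
  --vcf fx/vcfs/S0001.vcf \
  --transcripts fx/reference/cds.fasta \
  --annotation fx/reference/transcripts.tsv \
  --alleles fx/alleles.txt \
  --expression fx/expression/S0001.tsv \
  --tx2gene fx/reference/tx2gene.tsv \
  --lengths 9 --out out
```

`out/S0001/candidates.tsv` begins (toy predictor, seed 7):

```
Gene     HLA_Allele   Mutation_Type  Ref_Peptide  Alt_Peptide  Ref_IC50  Alt_IC50  Category  DAI     AA_Change
GENE000  HLA-A*02:01  missense       IFRLLDDLF    IFRLMDDLF     23.1809   32.0839  High      0.7225  L29M
GENE000  HLA-A*02:01  missense       LLDDLFYYG    LMDDLFYYG    122.0509   62.5201  Moderate  1.9522  L29M
GENE001  HLA-A*02:01  missense       ACETCSNYR    ACETCSNYS     58.0321   62.9202  Moderate  0.9223  R250S
```

Each row is one candidate 9-mer: the mutant peptide (`Alt_Peptide`), its
wild-type counterpart at the same position, both predicted IC50s in nM, the
binder tier (High/Moderate/Low/Non-binding in reports), and the DAI. The
second row has DAI ≈ 1.95: the L29M mutation roughly doubles predicted
binding strength relative to wild-type, the pattern DAI is designed to flag.
Rows are sorted by mutant IC50, strongest predicted binders first.

Running all carrier samples into one output directory and aggregating:

```bash
neoforge cohort --dir out_all --cohort-size 466 --categories all --out recurrence.tsv
```

```
Gene     AA_Change  Neoepitope  HLA_Haplotype  Frequency  Frequency_pct
GENE000  L29M       FRLMDDLFY   HLA-A*02:01    17/466     3.65
GENE000  L29M       FRLMDDLFY   HLA-A*11:01    17/466     3.65
GENE000  L29M       GIFRLMDDL   HLA-A*02:01    17/466     3.65
```

The variant planted in 17 of 466 samples is recovered as a shared neoantigen
at 17/466 = 3.65% — the recurrence arithmetic used for hotspot mutations such
as RAC1 P29S in melanoma cohorts.

Other subcommands: `neoforge predict` scores an existing window FASTA,
`neoforge benchmark` computes genotype concordance of (RNA-seq-derived) calls
against a truth table. `--help` on any subcommand lists every flag and
default.

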