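# Methods

## Scope and data flow

`paneldx` covers the dry-lab half of a targeted-capture diagnostic
workflow. It consumes the standard products of upstream tools — FASTQ reads
(QC stage only), per-base depth tables (3-column chrom/pos/depth TSV, as
produced by `samtools depth`-style tools), and annotated single-sample
VCFs — and never realigns reads or re-calls small variants itself.
Coordinates follow each format's convention (BED 0-based half-open, VCF
and depth tables 1-based); all internal interval arithmetic is 0-based
half-open. Strand is ignored: every statistic here is strand-free.

Annotation transport: functional consequence, per-database allele
frequencies, predictor verdicts and a conservation flag are read from VCF
INFO keys (`CSQ`, `AF_<db>`, `PRED_<tool>`, `CONSERVED`, `GENE`,
`KNOWN_ID`). Re-implementing consequence or conservation predictors is out
of scope; the open `AF_<db>` map means new frequency sources need no
schema change.

## Read QC

Four removal rules, applied in a fixed order (adapter, N-fraction, mean
quality, low-quality bases) so each removed read has one recorded reason:

| rule | default | interpretation |
|---|---|---|
| adapter | ≥ 10 bp window, ≤ 1 mismatch | Hamming sliding window of the adapter across the read, partial overlaps at both ends allowed |
| N fraction | > 0.10 | strictly more than 10% ambiguous bases |
| mean quality | < 10 | arithmetic mean of Phred scores (not error-probability averaging) |
| low-quality bases | ≥ 50% below Phred 5 | ≥ is the conservative reading of a stated 50% threshold; configurable |

Reads are removed whole, never trimmed, and paired mates are removed
together; a mate dropped only because its partner failed is counted under
the partner's reason so the report always balances
(`n_input = n_kept + Σ removals + invalid`). FASTQ input defaults to
Phred+33 with a Phred+64 switch.

## Coverage statistics

Per-sample coverage is computed over the merged panel target: mean target
depth, percent of target bases at ≥ t× for each requested threshold
(non-increasing in t by construction), and the same for a 200 bp flanking
collar that excludes any base inside the target. Capture specificity is
reported as mapped-to-target over mapped-to-genome read counts when the
caller supplies them; base-level accounting is a parameter choice, not a
different code path.

## CNV detection

The depth rate of sample *s* in region *r* is the region's mean depth
divided by the sample's overall mean depth, cancelling library-size
differences. The z-score of a tested sample is taken against the
**leave-one-out baseline across the other samples of the same run, for the
same region** — justified by the strong cross-sample correlation of
per-region depths within a run. The alternative reading (baseline over the
*other regions of the same sample*) would conflate probe-to-probe capture
efficiency with CNV signal and is not used.

Numerical choices:

* sample standard deviation (n−1 denominator); baseline SD below 1e−6
  marks a region *uninformative* (NaN) — it is never called;
* the statistic is one observation against a baseline distribution, so no
  √n shrinkage of the baseline SD is applied;
* strict inequalities at the cutoff: z = ±3.0 exactly is not called;
* minimum baseline of 3 other samples, otherwise the run is rejected;
* one z per capture region (exon granularity); consecutive same-direction
  flagged regions of one gene merge into one call whose z_extreme is the
  most extreme constituent z.

The default cutoff 3 corresponds to the one-tailed 99.9th percentile of a
standard normal baseline (`zscore_percentile(3)` = 99.865).

## Variant triage

Candidate filter (order of predicates is immaterial; the filter is
idempotent): caller quality ≥ 20; functional consequence (SNV: nonsense,
splice-site, missense; indel: frameshift, in-frame indel, splice-site);
allele frequency < 0.01 **in every database where the variant is
observed** (absence passes — the permissive "rare in at least one
database" reading would keep common variants); optional phenotype gene
restriction. Unannotated consequences are treated as non-functional.

Tier assignment, first matching terminal rule wins, with every satisfied
clause recorded as evidence:

1. exact knowledge-table match on (chrom, pos, ref, alt) **or** nonsense /
   frameshift consequence → **pathogenic**;
2. conserved-region missense, splice variant disrupting a canonical GT
   donor / AG acceptor dinucleotide (positions taken from the panel's
   splice_site regions; without a panel the splice annotation is taken at
   face value), or ≥ `min_damaging_predictors` damaging verdicts →
   **suspected pathogenic**;
3. present in the local control database → **polymorphism**;
4. otherwise → **unknown significance**.

`min_damaging_predictors` defaults to 2 of the four conventional
predictors; the stricter ≥ 3 reading is one configuration change away.
Known-variant matching performs no indel re-normalisation beyond the VCF
representation (documented limitation). Tiering is monotone: adding a
damaging verdict can never demote a variant.

Summaries report consequence-class and zygosity percentages rounded to two
decimals; cohort phenotype tables group carriers by gene with
`mean (min–max) [n missing]` cells and integer-percent gene shares.

## Benchmarking

Calls are reduced to SNVs passing score ≥ 20, depth ≥ 20 and
alt-supporting-read fraction ≥ 28%, then compared site-by-site (position +
alt allele) with the truth set over the *covered* bases — target bases
with evaluable depth, which makes TN well-defined. Genotype concordance is
reported separately and never enters the confusion counts; indels are
excluded from the assessment. A truth site covered by a surviving call
with the wrong alt allele counts once as FP and once as FN.

Precision is TP / (TP + FP). The alternative TP / (TP + FN) — which equals
the TP ratio — is available behind `precision_text_formula=True`. Percents
round to two decimals (FP ratio to three, as its magnitude warrants).

## Synthetic data generator

The generator's defaults define the study conditions the tests exercise:

* **Depth model.** Expected depth of sample *s* in region *r* is
  `412 × scale_s × effect_r × copy_{s,r}` with negative-binomial noise
  (dispersion 400): 412× is a realistic mean capture depth for a
  high-depth diagnostic panel, and capture depth is overdispersed relative
  to Poisson. `scale_s` (lognormal, σ = 0.15) models library-yield
  differences; the shared `effect_r` (lognormal, σ = 0.4) models
  probe-specific capture efficiency and is what makes per-region depths
  correlate across samples (median pairwise r ≈ 0.95 under defaults, well
  above the 0.7 the caller relies on). Copy factors 0.5 / 1.5 model
  heterozygous deletion / duplication of a diploid locus, 0 a homozygous
  deletion.
* **Panel.** Six monogenic-diabetes genes (HNF4A, GCK, HNF1A, HNF1B, INS,
  KCNJ11), 10 exons of 150 bp per gene with 2 bp splice-site regions at
  exon boundaries, UTRs, and introns, laid out on a fictional contig
  (`panelsim1`) so nothing can depend on a real reference.
* **Variant tables.** Implanted classes carry annotations that force their
  intended tier (known missense via the generated knowledge table, stop
  gains, frameshift indels, splice variants inside splice-site regions,
  conserved/damaging missense); filler classes (common polymorphisms,
  rare benign missense, synonymous) land the post-filter candidate count
  in the 3–10 band per sample.
* **cohort70 preset.** 70 patients in 5 runs of 14, each carrying exactly
  one causal event: 63 small variants (36 known missense, 5 stop gains, 7
  splice-site, 15 frameshift indels) distributed over the genes in the
  published carrier proportions (GCK 26, HNF1A 28, HNF4A 9, HNF1B 2,
  INS 2, KCNJ11 3), plus 7 whole-exon CNVs spanning 1–2 exons (5
  heterozygous deletions, 2 duplications — deletions dominate because
  large HNF1B deletions are the classic structural event in monogenic
  diabetes). The run size of 14 gives each sample a 13-sample
  leave-one-out baseline.
* **Benchmark pairs.** Truth SNVs planted on covered positions; calls miss
  a truth site with probability e_fn = 0.09 and arise at a negative base
  with probability e_fp = 6e-5 (the error regime of a high-depth capture
  assessment); the generator tallies its own expected confusion counts
  exactly, including calls deliberately emitted below the depth filter.
* **Reads.** 90 bp paired-end-style reads with exact counts of each defect
  class, so expected QC reports are exact rather than statistical.

All outputs are deterministic functions of the config seed;
re-generating a bundle yields byte-identical files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: GC-dependent coverage bias, batch effects beyond
a single lognormal run structure, mappability artefacts, indel
representation ambiguity, predictor disagreement structure, population
allele-frequency spectra, and real breakpoints (events are exact multiples
of capture regions). Recovery rates on the synthetic cohort therefore
validate the implementation under its stated model, not clinical
sensitivity.

## Problem sizes

The default test and acceptance workloads are deliberately desk-scale: 70
samples × ~35 variants, 5 depth matrices of 14 × 60 regions, and 10,000
covered bases for benchmarking. The full suite runs in a few seconds; the
acceptance script in under two seconds.

## Known limitations

* No GC correction, segmentation (HMM/CBS) or breakpoint resolution: the
  CNV method is deliberately the plain per-region z-score.
* Site-level benchmarking only; no haplotype-aware comparison or indel
  normalisation.
* The knowledge table matches variants by exact coordinates and alleles;
  left-alignment differences between callers will miss.
* ACMG-style classification and transcript-aware consequence prediction
  are out of scope; tiers reflect the four-tier rule set above.
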