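# paneldx

Diagnostics toolkit for targeted gene-panel sequencing of monogenic
diabetes (MODY / neonatal diabetes), built for the analysis that follows
capture sequencing of a candidate-gene panel: pre-alignment read QC,
per-region coverage statistics, detection of exon-scale deletions and
duplications from read depth, rule-based variant pathogenicity triage, and
benchmarking of SNV calls against a reference truth set. A synthetic
fixture generator produces every input the pipeline needs, so the whole
toolkit runs and is tested without external data.

Intended users are bioinformaticians running clinical gene panels who
consume standard upstream outputs — per-base depth tables, annotated VCFs
— rather than raw alignments.

## Methods at a glance

**Read QC.** A read is *unqualified* and removed whole (never trimmed) if
it is adapter-polluted (a ≥ 10 bp adapter window matching with ≤ 1
mismatch), has > 10% ambiguous bases, mean Phred quality < 10, or ≥ 50% of
bases below Phred 5. Paired mates are removed together.

**CNV detection by depth rate.** For sample *s* and capture region *r*,
the depth rate is rate(s, r) = d̄(s, r) / d̄(s), the region's mean depth
normalised by the sample's overall mean depth. Because a region's capture
efficiency is a probe property, rates are tightly correlated across
samples of a run (r > 0.7), so each sample is scored against the
leave-one-out baseline of its run:

    z(r) = (rate(s, r) − mean_{s'≠s} rate(s', r)) / sd_{s'≠s} rate(s', r)

with z < −3 called a deletion and z > +3 a duplication (strict; ±3 is the
one-tailed 99.9th percentile of a standard-normal baseline). Consecutive
same-direction regions of one gene merge into a single call.

**Variant triage.** Candidates are variants with caller quality ≥ 20, a
functional consequence (SNVs: nonsense, splice-site, missense; indels:
frameshift, in-frame, splice-site), and allele frequency < 0.01 in every
public database where they are observed, optionally restricted to a
phenotype gene panel. Candidates are tiered *pathogenic* (known mutation
or stop/frameshift), *suspected pathogenic* (conserved-region missense,
splice variant breaking the canonical GT/AG dinucleotides, or ≥ 2 damaging
predictor verdicts), *polymorphism* (seen in controls) or *unknown
significance*.

**Benchmarking.** SNV calls passing score ≥ 20, depth ≥ 20 and
alt-fraction ≥ 28% are compared position-by-position with a truth set over
the covered target bases: accuracy = (TP + TN) / (TP + FN + TN + FP),
precision = TP / (TP + FP), TP/FN ratios relative to truth positives and
FP/TN ratios relative to truth negatives.

## Worked example

Generate the 70-sample synthetic cohort (each patient carries exactly one
implanted causal event) and triage one patient:

```
$ panel-dx simulate --preset cohort70 --seed 1 --out fx/
$ panel-dx triage --vcf fx/P01.vcf --panel fx/panel.bed --known fx/knowledge.tsv
panelsim1  1606   G  T  HNF4A  missense     unknown_significance  no_evidence
panelsim1  4124   C  A  HNF4A  missense     unknown_significance  no_evidence
panelsim1  12949  A  T  GCK    splice_site  suspected_pathogenic  splice_gt_at
panelsim1  24439  C  A  HNF1A  missense     unknown_significance  no_evidence
panelsim1  52888  G  C  KCNJ11 missense     unknown_significance  no_evidence
```

Of roughly 35 variants in P01's VCF, five survive the candidate filter
(within the expected 3–10 band) and one — the implanted GCK splice-site
mutation — is flagged suspected pathogenic via the GT/AG rule.

Benchmark arithmetic on a confusion tally:

```python
>>> from paneldx import ConfusionCounts, bench_report
>>> r = bench_report(ConfusionCounts(covered_bp=4944470, tp=5847,
...                                  tn=4937762, fp=280, fn=581))
>>> r.accuracy, r.precision, r.tp_ratio, r.fn_ratio, r.fp_ratio
(99.98, 95.43, 90.96, 9.04, 0.006)
```

Accuracy is the fraction of covered bases judged correctly; precision the
fraction of retained calls that are true; the FN ratio the fraction of
truth sites missed.

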