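"""Synthetic fixtures for every stage of the panel pipeline.

Generates, from a single seeded configuration: a capture panel on fictional
contigs, per-run depth matrices with correlated per-region capture
efficiencies and implanted exon-scale deletions/duplications, per-sample
variant tables with implanted pathogenic mutations and filler variants,
defective read sets with exact expected QC tallies, and truth/call pairs
with exact expected confusion counts.

Depth model: the expected depth of sample s in region r is

    depth_mean * sample_scale_s * region_effect_r * copy_factor_{s,r}

with negative-binomial noise (capture depth is overdispersed relative to
Poisson). The shared lognormal ``region_effect_r`` is what makes region
depths strongly correlated across samples of a run — the property the
z-score caller relies on.

Coordinates live on fictional contigs ("panelsim1", ...) so nothing can
accidentally depend on a real reference genome. All outputs are
deterministic functions of the config, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .benchmark_eval import ConfusionCounts
from .coverage_cnv import DepthMatrix
from .panel_io import (
    DepthTable,
    GenePanel,
    TargetRegion,
    VariantRecord,
    write_depth,
    write_knowledge,
    write_panel,
    write_variants,
)
from .read_qc import DEFAULT_ADAPTER, QCReport, ReadRecord
from .variant_triage import CohortRecord

CONTIG = "panelsim1"
BENCH_CONTIG = "panelsim_bench"

#: The six-gene monogenic diabetes panel used by the cohort presets.
PANEL_GENES = ("HNF4A", "GCK", "HNF1A", "HNF1B", "INS", "KCNJ11")

COPY_FACTORS = (0.0, 0.5, 1.5, 2.0)

VARIANT_CLASSES = (
    "known_pathogenic",
    "novel_lof",
    "novel_frameshift",
    "novel_splice",
    "novel_damaging_missense",
    "common_polymorphism",
    "benign_rare",
    "synonymous",
)

#: Implant classes whose expected tier is pathogenic or suspected.
CAUSAL_CLASSES = {
    "known_pathogenic": "pathogenic",
    "novel_lof": "pathogenic",
    "novel_frameshift": "pathogenic",
    "novel_splice": "suspected_pathogenic",
    "novel_damaging_missense": "suspected_pathogenic",
}

PREDICTORS = ("sift", "polyphen2", "mutationtaster", "bdgp")


@dataclass(frozen=True)
class CnvEvent:
    sample_id: str
    gene: str
    exon_first: int  # ordinal within gene, 1-based inclusive
    exon_last: int
    copy_factor: float

    def __post_init__(self) -> None:
        if self.copy_factor not in COPY_FACTORS:
            raise ValueError(
                f"copy_factor must be one of {COPY_FACTORS}, got {self.copy_factor}"
            )
        if not 1 <= self.exon_first <= self.exon_last:
            raise ValueError("invalid exon span")

    @property
    def direction(self) -> str:
        return "deletion" if self.copy_factor < 1.0 else "duplication"


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_samples: int = 20
    n_regions_per_gene: int = 10
    genes: tuple[str, ...] = PANEL_GENES
    depth_mean: float = 412.0  # panel-wide mean capture depth, fold
    region_effect_sd: float = 0.4  # lognormal spread of capture efficiency
    sample_scale_sd: float = 0.15  # lognormal spread of per-sample yield
    dispersion: float = 400.0  # negative-binomial size parameter
    cnv_events: tuple[CnvEvent, ...] = ()
    variant_mix: tuple[tuple[str, int], ...] = (
        ("known_pathogenic", 1),
        ("novel_damaging_missense", 1),
        ("benign_rare", 4),
        ("common_polymorphism", 10),
        ("synonymous", 20),
    )
    error_rates: tuple[float, float] = (6e-5, 0.09)  # (e_fp, e_fn)
    read_length: int = 90
    exon_bp: int = 150
    intron_bp: int = 350
    utr_bp: int = 100

    def __post_init__(self) -> None:
        for name, count in self.variant_mix:
            if name not in VARIANT_CLASSES:
                raise ValueError(f"unknown variant class {name!r}")
            if count < 0:
                raise ValueError("variant_mix counts must be >= 0")
        e_fp, e_fn = self.error_rates
        if not (0 <= e_fp < 1 and 0 <= e_fn < 1):
            raise ValueError("error_rates must be in [0, 1)")


# ---------------------------------------------------------------------------
# Panel


def build_panel(cfg: SimConfig) -> GenePanel:
    """Lay the configured genes end to end on one fictional contig.

    Per gene: a 5' UTR, then exons separated by introns, with 2 bp
    splice_site regions at each exon/intron boundary, then a 3' UTR.
    """
    regions: list[TargetRegion] = []
    cursor = 1000
    for gene in cfg.genes:
        regions.append(
            TargetRegion(CONTIG, cursor, cursor + cfg.utr_bp, gene, "UTR5")
        )
        cursor += cfg.utr_bp
        for exon in range(1, cfg.n_regions_per_gene + 1):
            if exon > 1:
                # acceptor AG dinucleotide just before the exon
                regions.append(
                    TargetRegion(CONTIG, cursor - 2, cursor, gene, "splice_site")
                )
            regions.append(
                TargetRegion(
                    CONTIG, cursor, cursor + cfg.exon_bp, gene, "CDS", exon_index=exon
                )
            )
            cursor += cfg.exon_bp
            if exon < cfg.n_regions_per_gene:
                # donor GT dinucleotide just after the exon
                regions.append(
                    TargetRegion(CONTIG, cursor, cursor + 2, gene, "splice_site")
                )
                regions.append(
                    TargetRegion(
                        CONTIG, cursor + 2, cursor + cfg.intron_bp - 2, gene, "intron"
                    )
                )
                cursor += cfg.intron_bp
        regions.append(
            TargetRegion(CONTIG, cursor, cursor + cfg.utr_bp, gene, "UTR3")
        )
        cursor += cfg.utr_bp + 5000  # intergenic gap
    return GenePanel(regions=regions)


def _cds_regions(panel: GenePanel) -> list[TargetRegion]:
    return panel.regions_of_class("CDS")


# ---------------------------------------------------------------------------
# Depth matrices with implanted CNVs


def gen_depth_matrix(
    cfg: SimConfig,
    panel: GenePanel | None = None,
    run_id: str = "run1",
    sample_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DepthMatrix, list[CnvEvent]]:
    """Simulate one run's per-region mean depths; returns the matrix and the
    implant manifest (the cnv_events actually applied)."""
    if cfg.n_samples < 4:
        raise ValueError("need n_samples >= 4 for a leave-one-out baseline")
    panel = panel or build_panel(cfg)
    regions = _cds_regions(panel)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    samples = (
        list(sample_ids)
        if sample_ids is not None
        else [f"{run_id}_S{i + 1:02d}" for i in range(cfg.n_samples)]
    )
    if len(samples) != cfg.n_samples:
        raise ValueError("sample_ids length must equal n_samples")

    region_effect = np.exp(rng.normal(0.0, cfg.region_effect_sd, len(regions)))
    sample_scale = np.exp(rng.normal(0.0, cfg.sample_scale_sd, len(samples)))
    copy = np.ones((len(samples), len(regions)))
    region_index = {
        (r.gene, r.exon_index): i for i, r in enumerate(regions)
    }
    applied: list[CnvEvent] = []
    for event in cfg.cnv_events:
        if event.sample_id not in samples:
            continue
        si = samples.index(event.sample_id)
        for exon in range(event.exon_first, event.exon_last + 1):
            ri = region_index.get((event.gene, exon))
            if ri is None:
                raise ValueError(
                    f"event references unknown exon {event.gene} exon {exon}"
                )
            copy[si, ri] = event.copy_factor
        applied.append(event)

    mu = cfg.depth_mean * np.outer(sample_scale, region_effect) * copy
    p = cfg.dispersion / (cfg.dispersion + np.maximum(mu, 1e-9))
    depth = rng.negative_binomial(cfg.dispersion, p).astype(float)
    depth[mu == 0] = 0.0
    matrix = DepthMatrix(
        run_id=run_id,
        samples=samples,
        regions=regions,
        mean_depth=depth,
        sample_mean_depth=depth.mean(axis=1),
    )
    return matrix, applied


def gen_depth_table(
    cfg: SimConfig,
    panel: GenePanel,
    sample_id: str = "S1",
    rng: np.random.Generator | None = None,
) -> DepthTable:
    """Per-base depth for one sample over every panel base (small panels
    only: intended for coverage-statistics fixtures)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    table = DepthTable(sample_id=sample_id)
    for region in panel.regions:
        mu = cfg.depth_mean * float(np.exp(rng.normal(0.0, cfg.region_effect_sd)))
        p = cfg.dispersion / (cfg.dispersion + mu)
        depths = rng.negative_binomial(cfg.dispersion, p, region.length)
        for offset, d in enumerate(depths):
            table.add(region.chrom, region.start + offset + 1, int(d))
    return table


# ---------------------------------------------------------------------------
# Variant cohorts


def _region_position(
    rng: np.random.Generator, regions: Sequence[TargetRegion], used: set[int]
) -> tuple[TargetRegion, int]:
    """A fresh 1-based position inside one of the given regions."""
    while True:
        region = regions[int(rng.integers(len(regions)))]
        pos = int(rng.integers(region.start + 1, region.end + 1))
        if pos not in used:
            used.add(pos)
            return region, pos


_BASES = "ACGT"


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[int(rng.integers(4))]
    while alt == ref:
        alt = _BASES[int(rng.integers(4))]
    return ref, alt


def _make_variant(
    vclass: str,
    gene: str,
    panel: GenePanel,
    rng: np.random.Generator,
    used: set[int],
    known_counter: list[int],
    knowledge: dict[tuple[str, int, str, str], dict[str, str]],
) -> VariantRecord:
    gene_regions = [r for r in panel.regions if r.gene == gene]
    cds = [r for r in gene_regions if r.region_class == "CDS"]
    splice = [r for r in gene_regions if r.region_class == "splice_site"]
    zygosity = "het" if rng.random() < 0.9 else "hom"
    depth = int(rng.integers(150, 500))
    alt_frac = 1.0 if zygosity == "hom" else round(float(rng.uniform(0.35, 0.6)), 2)
    common = dict(
        gene=gene,
        zygosity=zygosity,
        call_quality=float(rng.integers(40, 100)),
        depth=depth,
        alt_fraction=alt_frac,
    )
    if vclass == "known_pathogenic":
        region, pos = _region_position(rng, cds, used)
        ref, alt = _snv_alleles(rng)
        known_counter[0] += 1
        kid = f"KP{known_counter[0]:04d}"
        knowledge[(region.chrom, pos, ref, alt)] = {"gene": gene, "citation_id": kid}
        return VariantRecord(
            chrom=region.chrom, pos=pos, ref=ref, alt=alt, consequence="missense",
            known_pathogenic_id=kid, conserved=True, **common,
        )
    if vclass == "novel_lof":
        region, pos = _region_position(rng, cds, used)
        ref, alt = _snv_alleles(rng)
        return VariantRecord(
            chrom=region.chrom, pos=pos, ref=ref, alt=alt,
            consequence="nonsense", **common,
        )
    if vclass == "novel_frameshift":
        region, pos = _region_position(rng, cds, used)
        ref = _BASES[int(rng.integers(4))]
        return VariantRecord(
            chrom=region.chrom, pos=pos, ref=ref + "AC", alt=ref,
            consequence="frameshift", **common,
        )
    if vclass == "novel_splice":
        region, pos = _region_position(rng, splice, used)
        ref, alt = _snv_alleles(rng)
        return VariantRecord(
            chrom=region.chrom, pos=pos, ref=ref, alt=alt,
            consequence="splice_site", **common,
        )
    if vclass == "novel_damaging_missense":
        region, pos = _region_position(rng, cds, used)
        ref, alt = _snv_alleles(rng)
        return VariantRecord(
            chrom=region.chrom, pos=pos, ref=ref, alt=alt, consequence="missense",
            conserved=True,
            predictor_calls={p: "damaging" for p in PREDICTORS[:3]},
            **common,
        )
    if vclass == "common_polymorphism":
        region, pos = _region_position(rng, cds, used)
        ref, alt = _snv_alleles(rng)
        return VariantRecord(
            chrom=region.chrom, pos=pos, ref=ref, alt=alt, consequence="missense",
            db_afs={"thousand_genomes": round(float(rng.uniform(0.02, 0.4)), 3)},
            **common,
        )
    if vclass == "benign_rare":
        region, pos = _region_position(rng, cds, used)
        ref, alt = _snv_alleles(rng)
        return VariantRecord(
            chrom=region.chrom, pos=pos, ref=ref, alt=alt, consequence="missense",
            db_afs={"thousand_genomes": round(float(rng.uniform(1e-4, 5e-3)), 5)},
            predictor_calls={p: "benign" for p in PREDICTORS},
            **common,
        )
    if vclass == "synonymous":
        region, pos = _region_position(rng, cds, used)
        ref, alt = _snv_alleles(rng)
        return VariantRecord(
            chrom=region.chrom, pos=pos, ref=ref, alt=alt,
            consequence="synonymous", **common,
        )
    raise ValueError(f"unknown variant class {vclass!r}")


@dataclass
class VariantCohort:
    panel: GenePanel
    variants: dict[str, list[VariantRecord]]
    knowledge: dict[tuple[str, int, str, str], dict[str, str]]
    expected_tiers: dict[str, list[tuple[tuple[str, int, str, str], str]]]
    expected_candidates: dict[str, int]


def gen_variant_cohort(
    cfg: SimConfig,
    panel: GenePanel | None = None,
    sample_ids: Sequence[str] | None = None,
    causal_overrides: Mapping[str, tuple[str, str]] | None = None,
    rng: np.random.Generator | None = None,
) -> VariantCohort:
    """Per-sample variant tables with implanted classes.

    Each sample receives the configured ``variant_mix``. ``causal_overrides``
    maps sample_id -> (variant_class, gene) and adds one causal implant of
    that class in that gene on top of the mix (used by the cohort presets
    to give every patient exactly one causal mutation).
    """
    panel = panel or build_panel(cfg)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    samples = (
        list(sample_ids)
        if sample_ids is not None
        else [f"P{i + 1:02d}" for i in range(cfg.n_samples)]
    )
    knowledge: dict[tuple[str, int, str, str], dict[str, str]] = {}
    known_counter = [0]
    variants: dict[str, list[VariantRecord]] = {}
    expected: dict[str, list[tuple[tuple[str, int, str, str], str]]] = {}
    expected_candidates: dict[str, int] = {}
    genes = list(cfg.genes)
    for sample in samples:
        used: set[int] = set()
        recs: list[VariantRecord] = []
        exp: list[tuple[tuple[str, int, str, str], str]] = []
        n_candidates = 0
        mix = list(cfg.variant_mix)
        if causal_overrides and sample in causal_overrides:
            vclass, gene = causal_overrides[sample]
            v = _make_variant(vclass, gene, panel, rng, used, known_counter, knowledge)
            recs.append(v)
            exp.append((v.key, CAUSAL_CLASSES[vclass]))
            n_candidates += 1
        for vclass, count in mix:
            for _ in range(count):
                gene = genes[int(rng.integers(len(genes)))]
                v = _make_variant(
                    vclass, gene, panel, rng, used, known_counter, knowledge
                )
                recs.append(v)
                if vclass in CAUSAL_CLASSES:
                    exp.append((v.key, CAUSAL_CLASSES[vclass]))
                if vclass in CAUSAL_CLASSES or vclass == "benign_rare":
                    n_candidates += 1
        variants[sample] = recs
        expected[sample] = exp
        expected_candidates[sample] = n_candidates
    return VariantCohort(
        panel=panel,
        variants=variants,
        knowledge=knowledge,
        expected_tiers=expected,
        expected_candidates=expected_candidates,
    )


# ---------------------------------------------------------------------------
# Reads


def _clean_read(rng: np.random.Generator, cfg: SimConfig, read_id: str) -> ReadRecord:
    seq = "".join(_BASES[i] for i in rng.integers(0, 4, cfg.read_length))
    quals = tuple(int(q) for q in rng.integers(30, 40, cfg.read_length))
    return ReadRecord(read_id=read_id, sequence=seq, qualities=quals)


def gen_reads(
    cfg: SimConfig,
    n_clean: int = 100,
    defects: Mapping[str, int] | None = None,
    adapter: str = DEFAULT_ADAPTER,
) -> tuple[list[ReadRecord], QCReport]:
    """Reads with exact counts of each defect class, plus the expected
    QC report (exact by construction, not statistical)."""
    defects = dict(defects or {})
    rng = np.random.default_rng(cfg.seed)
    reads: list[ReadRecord] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"simread_{counter:05d}"

    for _ in range(n_clean):
        reads.append(_clean_read(rng, cfg, next_id()))
    for _ in range(defects.get("adapter", 0)):
        base = _clean_read(rng, cfg, next_id())
        insert_at = int(rng.integers(0, cfg.read_length - len(adapter) + 1))
        seq = (
            base.sequence[:insert_at]
            + adapter
            + base.sequence[insert_at + len(adapter):]
        )
        reads.append(ReadRecord(base.read_id, seq, base.qualities))
    for _ in range(defects.get("n_fraction", 0)):
        base = _clean_read(rng, cfg, next_id())
        n_ns = int(cfg.read_length * 0.12) or 1  # 12% ambiguous bases
        positions = rng.choice(cfg.read_length, size=n_ns, replace=False)
        seq = list(base.sequence)
        for p in positions:
            seq[p] = "N"
        reads.append(ReadRecord(base.read_id, "".join(seq), base.qualities))
    for _ in range(defects.get("mean_quality", 0)):
        base = _clean_read(rng, cfg, next_id())
        quals = tuple(int(q) for q in rng.integers(6, 10, cfg.read_length))
        reads.append(ReadRecord(base.read_id, base.sequence, quals))
    for _ in range(defects.get("low_quality_bases", 0)):
        base = _clean_read(rng, cfg, next_id())
        half = cfg.read_length // 2 + cfg.read_length % 2
        quals = tuple([4] * half + [30] * (cfg.read_length - half))
        reads.append(ReadRecord(base.read_id, base.sequence, quals))

    expected = QCReport(
        n_input=len(reads),
        n_kept=n_clean,
        removal_counts={
            reason: defects.get(reason, 0)
            for reason in ("adapter", "n_fraction", "mean_quality", "low_quality_bases")
        },
    )
    order = rng.permutation(len(reads))
    return [reads[i] for i in order], expected


# ---------------------------------------------------------------------------
# Benchmark truth/call pairs


@dataclass
class BenchBundle:
    truth: list[VariantRecord]
    calls: list[VariantRecord]
    covered: set[tuple[str, int]]
    expected: ConfusionCounts


def gen_bench_pair(
    cfg: SimConfig,
    n_covered: int = 10_000,
    n_truth: int = 500,
    n_lowqual_calls: int = 5,
) -> BenchBundle:
    """Planted truth/call pair with the generator's own exact tally.

    True SNVs are planted at ``n_truth`` covered positions; calls miss a
    truth site with probability e_fn and arise spuriously at each negative
    base with probability e_fp. ``n_lowqual_calls`` detected truth sites
    are emitted with sub-threshold depth so the benchmark filters must
    remove them (they count as FN in the expected tally).
    """
    e_fp, e_fn = cfg.error_rates
    rng = np.random.default_rng(cfg.seed)
    covered = {(BENCH_CONTIG, int(p)) for p in range(1, n_covered + 1)}
    truth_pos = sorted(
        int(p) for p in rng.choice(n_covered, size=n_truth, replace=False) + 1
    )
    truth_set = set(truth_pos)

    truth: list[VariantRecord] = []
    calls: list[VariantRecord] = []
    tp = fn = fp = 0
    detected: list[tuple[int, str, str]] = []
    for pos in truth_pos:
        ref, alt = _snv_alleles(rng)
        truth.append(
            VariantRecord(
                chrom=BENCH_CONTIG, pos=pos, ref=ref, alt=alt,
                zygosity="het", call_quality=99.0, depth=100, alt_fraction=0.5,
            )
        )
        if rng.random() < e_fn:
            fn += 1
        else:
            detected.append((pos, ref, alt))
    n_low = min(n_lowqual_calls, len(detected))
    low_idx = set(
        int(i) for i in rng.choice(len(detected), size=n_low, replace=False)
    ) if n_low else set()
    for i, (pos, ref, alt) in enumerate(detected):
        low = i in low_idx
        calls.append(
            VariantRecord(
                chrom=BENCH_CONTIG, pos=pos, ref=ref, alt=alt,
                zygosity="het",
                call_quality=35.0,
                depth=5 if low else int(rng.integers(50, 300)),
                alt_fraction=0.5,
            )
        )
        if low:
            fn += 1
        else:
            tp += 1
    negatives = np.array(
        [p for p in range(1, n_covered + 1) if p not in truth_set]
    )
    fp_mask = rng.random(negatives.size) < e_fp
    for pos in negatives[fp_mask]:
        ref, alt = _snv_alleles(rng)
        calls.append(
            VariantRecord(
                chrom=BENCH_CONTIG, pos=int(pos), ref=ref, alt=alt,
                zygosity="het", call_quality=40.0,
                depth=int(rng.integers(50, 300)), alt_fraction=0.45,
            )
        )
        fp += 1
    tn = n_covered - tp - fn - fp
    return BenchBundle(
        truth=truth,
        calls=calls,
        covered=covered,
        expected=ConfusionCounts(covered_bp=n_covered, tp=tp, tn=tn, fp=fp, fn=fn),
    )


# ---------------------------------------------------------------------------
# Cohort phenotypes


def gen_cohort_phenotypes(
    gene_by_sample: Mapping[str, str], seed: int = 0
) -> list[CohortRecord]:
    """Plausible phenotype records for the mutation carriers of a cohort."""
    rng = np.random.default_rng(seed)
    records = []
    for sample, gene in gene_by_sample.items():
        height = round(float(rng.normal(172, 9)), 1)
        weight = round(float(rng.normal(72, 12)), 1)
        records.append(
            CohortRecord(
                sample_id=sample,
                pathogenic_gene=gene,
                sex="M" if rng.random() < 0.5 else "F",
                age_at_examination=round(float(rng.uniform(10, 70)), 1),
                age_at_diagnosis=round(float(rng.uniform(5, 45)), 1),
                height=height,
                weight=weight,
                bmi=round(weight / (height / 100.0) ** 2, 1),
                hba1c=round(float(rng.uniform(5.5, 9.5)), 1),
                treatment=("ins", "ins+OHA", "OHA", "diet")[int(rng.integers(4))],
            )
        )
    return records


# ---------------------------------------------------------------------------
# The cohort70 preset


#: Carriers per gene in the 70-sample preset (integer gene shares 37/40/13/3/3/4%).
COHORT70_GENE_COUNTS = {
    "GCK": 26,
    "HNF1A": 28,
    "HNF4A": 9,
    "HNF1B": 2,
    "INS": 2,
    "KCNJ11": 3,
}

#: Small-variant class split of the 63 point-mutation carriers.
COHORT70_CLASS_COUNTS = {
    "known_pathogenic": 36,  # missense, previously reported
    "novel_lof": 5,  # stop gains
    "novel_splice": 7,
    "novel_frameshift": 15,  # indels
}

COHORT70_RUN_SIZE = 14


@dataclass
class CohortBundle:
    config: SimConfig
    panel: GenePanel
    runs: list[DepthMatrix]
    cnv_manifest: list[CnvEvent]
    cohort: VariantCohort
    phenotypes: list[CohortRecord]
    gene_by_sample: dict[str, str]


def cohort70(seed: int = 1) -> CohortBundle:
    """The 70-sample monogenic-diabetes cohort preset.

    Every sample carries exactly one implanted causal event: 63 small
    pathogenic variants (36 known missense, 5 stop gains, 7 splice-site,
    15 frameshift indels) across the six panel genes in the published
    carrier proportions, and 7 whole-exon CNVs (5 heterozygous deletions,
    2 duplications). Samples are sequenced in 5 runs of 14.
    """
    # Background mix carries no causal classes: each patient's single causal
    # event is implanted via causal_overrides, so the implant manifest and
    # the designated events coincide one-to-one.
    cfg = SimConfig(
        seed=seed,
        n_samples=70,
        genes=PANEL_GENES,
        variant_mix=(
            ("benign_rare", 4),
            ("common_polymorphism", 10),
            ("synonymous", 20),
        ),
    )
    rng = np.random.default_rng(seed)
    panel = build_panel(cfg)
    samples = [f"P{i + 1:02d}" for i in range(70)]

    gene_list = [g for g, n in COHORT70_GENE_COUNTS.items() for _ in range(n)]
    class_list = [c for c, n in COHORT70_CLASS_COUNTS.items() for _ in range(n)]
    class_list += ["cnv"] * 7
    rng.shuffle(gene_list)
    rng.shuffle(class_list)
    gene_by_sample = dict(zip(samples, gene_list))

    cnv_events: list[CnvEvent] = []
    causal_overrides: dict[str, tuple[str, str]] = {}
    n_dels = 0
    for sample, vclass in zip(samples, class_list):
        gene = gene_by_sample[sample]
        if vclass == "cnv":
            # 5 heterozygous deletions, 2 duplications, spanning 1-2 exons
            factor = 0.5 if n_dels < 5 else 1.5
            n_dels += 1
            first = int(rng.integers(1, cfg.n_regions_per_gene))
            last = min(first + int(rng.integers(0, 2)), cfg.n_regions_per_gene)
            cnv_events.append(
                CnvEvent(
                    sample_id=sample, gene=gene,
                    exon_first=first, exon_last=last, copy_factor=factor,
                )
            )
        else:
            causal_overrides[sample] = (vclass, gene)

    runs: list[DepthMatrix] = []
    manifest: list[CnvEvent] = []
    for r in range(0, 70, COHORT70_RUN_SIZE):
        run_samples = samples[r : r + COHORT70_RUN_SIZE]
        run_cfg = replace(
            cfg,
            n_samples=len(run_samples),
            cnv_events=tuple(e for e in cnv_events if e.sample_id in run_samples),
        )
        matrix, applied = gen_depth_matrix(
            run_cfg,
            panel=panel,
            run_id=f"run{r // COHORT70_RUN_SIZE + 1}",
            sample_ids=run_samples,
            rng=rng,
        )
        runs.append(matrix)
        manifest.extend(applied)

    cohort = gen_variant_cohort(
        cfg, panel=panel, sample_ids=samples,
        causal_overrides=causal_overrides, rng=rng,
    )
    phenotypes = gen_cohort_phenotypes(gene_by_sample, seed=seed)
    return CohortBundle(
        config=cfg,
        panel=panel,
        runs=runs,
        cnv_manifest=manifest,
        cohort=cohort,
        phenotypes=phenotypes,
        gene_by_sample=gene_by_sample,
    )


# ---------------------------------------------------------------------------
# File emission


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> None:
    """Emit the bundle as plain-text files: panel BED, per-run region-depth
    TSV, per-sample VCF, knowledge TSV and the CNV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_panel(bundle.panel, outdir / "panel.bed")
    write_knowledge(bundle.cohort.knowledge, outdir / "knowledge.tsv")
    for matrix in bundle.runs:
        with open(outdir / f"{matrix.run_id}.region_depth.tsv", "w") as fh:
            header = "\t".join(
                f"{r.gene}_exon{r.exon_index}" for r in matrix.regions
            )
            fh.write(f"sample\t{header}\n")
            for si, sample in enumerate(matrix.samples):
                row = "\t".join(f"{d:.1f}" for d in matrix.mean_depth[si])
                fh.write(f"{sample}\t{row}\n")
    contigs = {CONTIG: 1_000_000}
    for sample, recs in bundle.cohort.variants.items():
        write_variants(
            recs, outdir / f"{sample}.vcf", sample_id=sample, contig_lengths=contigs
        )
    with open(outdir / "cnv_manifest.tsv", "w") as fh:
        fh.write("sample\tgene\texon_first\texon_last\tcopy_factor\n")
        for e in bundle.cnv_manifest:
            fh.write(
                f"{e.sample_id}\t{e.gene}\t{e.exon_first}\t{e.exon_last}\t"
                f"{e.copy_factor:g}\n"
            )
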