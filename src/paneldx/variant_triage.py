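"""Candidate filtering and four-tier pathogenicity triage for a gene panel.

Candidates are variants that survive three predicates — caller quality,
functional consequence, and rarity in public allele-frequency databases —
optionally restricted to a phenotype-specific gene set. Survivors are
placed in one of four tiers:

``pathogenic``
    known pathogenic variant (exact match in the knowledge table) or a
    loss-of-function variant (stop gain / frameshift);
``suspected_pathogenic``
    novel variant with supporting evidence: conserved-region missense,
    splice variant breaking the canonical GT donor / AG acceptor
    dinucleotides, or a consensus of damaging predictor verdicts;
``polymorphism``
    variant also seen in the local control cohort;
``unknown_significance``
    everything else.

The rarity rule requires the allele frequency to be below the threshold in
every database where the variant is observed; a variant absent from all
databases passes. The predictor-consensus clause defaults to >= 2 damaging
verdicts out of the four conventional tools (SIFT, PolyPhen-2,
MutationTaster, BDGP splice predictor); the count is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .panel_io import GenePanel, VariantRecord

log = logging.getLogger(__name__)

FUNCTIONAL_SNV_CLASSES = frozenset({"nonsense", "splice_site", "missense"})
FUNCTIONAL_INDEL_CLASSES = frozenset({"frameshift", "inframe_indel", "splice_site"})

TIERS = ("pathogenic", "suspected_pathogenic", "polymorphism", "unknown_significance")

KnowledgeTable = Mapping[tuple[str, int, str, str], Mapping[str, str]]
ControlSet = frozenset  # of (chrom, pos, ref, alt)


@dataclass(frozen=True)
class TriageConfig:
    min_call_quality: float = 20.0
    max_af: float = 0.01
    functional_snv_classes: frozenset[str] = FUNCTIONAL_SNV_CLASSES
    functional_indel_classes: frozenset[str] = FUNCTIONAL_INDEL_CLASSES
    min_damaging_predictors: int = 2
    restrict_genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.max_af < 1.0:
            raise ValueError("max_af must be in (0, 1)")
        if self.min_damaging_predictors < 1:
            raise ValueError("min_damaging_predictors must be >= 1")


@dataclass
class ClassifiedVariant:
    variant: VariantRecord
    tier: str
    evidence: list[str]


def is_functional(variant: VariantRecord, cfg: TriageConfig) -> bool:
    if variant.is_snv:
        return variant.consequence in cfg.functional_snv_classes
    if variant.is_indel:
        return variant.consequence in cfg.functional_indel_classes
    return False


def is_rare(variant: VariantRecord, cfg: TriageConfig) -> bool:
    """Below the AF threshold in every database where observed; absence passes."""
    if not variant.db_afs:
        return True
    return max(variant.db_afs.values()) < cfg.max_af


def filter_candidates(
    variants: Iterable[VariantRecord], cfg: TriageConfig | None = None
) -> list[VariantRecord]:
    """Reduce a sample's variant list to potential mutation candidates."""
    cfg = cfg or TriageConfig()
    kept: list[VariantRecord] = []
    for v in variants:
        if v.call_quality < cfg.min_call_quality:
            continue
        if not v.consequence:
            log.debug("%s:%d has no consequence annotation; treated as non-functional",
                      v.chrom, v.pos)
            continue
        if not is_functional(v, cfg):
            continue
        if not is_rare(v, cfg):
            continue
        if cfg.restrict_genes is not None and v.gene not in cfg.restrict_genes:
            continue
        kept.append(v)
    return kept


def _breaks_gt_at(variant: VariantRecord, panel: GenePanel | None) -> bool:
    """Splice variant disrupting a canonical donor GT / acceptor AG site.

    Splice dinucleotide positions are taken from the panel's splice_site
    regions; without a panel the splice_site consequence annotation is
    taken at face value.
    """
    if variant.consequence != "splice_site":
        return False
    if panel is None:
        return True
    return any(
        r.overlaps(variant.chrom, variant.pos - 1)
        for r in panel.regions_of_class("splice_site")
    )


def classify(
    variant: VariantRecord,
    known_db: KnowledgeTable,
    cfg: TriageConfig | None = None,
    control_db: frozenset[tuple[str, int, str, str]] | None = None,
    panel: GenePanel | None = None,
) -> ClassifiedVariant:
    """Assign one of the four tiers to a candidate variant.

    ``evidence`` records every satisfied clause, not only the deciding one.
    """
    cfg = cfg or TriageConfig()
    evidence: list[str] = []
    known = variant.key in known_db or (
        variant.known_pathogenic_id is not None
        and any(
            meta.get("citation_id") == variant.known_pathogenic_id
            for meta in known_db.values()
        )
    )
    if known:
        evidence.append("known_pathogenic")
    if variant.consequence in ("nonsense", "frameshift"):
        evidence.append("lof_stop_frameshift")
    conserved_missense = variant.consequence == "missense" and variant.conserved
    if conserved_missense:
        evidence.append("conserved_missense")
    gt_at = _breaks_gt_at(variant, panel)
    if gt_at:
        evidence.append("splice_gt_at")
    n_damaging = sum(
        1 for verdict in variant.predictor_calls.values() if verdict == "damaging"
    )
    predictor_consensus = n_damaging >= cfg.min_damaging_predictors
    if predictor_consensus:
        evidence.append(f"predictor_consensus_{n_damaging}")
    in_controls = control_db is not None and variant.key in control_db
    if in_controls:
        evidence.append("control_database")

    if known or variant.consequence in ("nonsense", "frameshift"):
        tier = "pathogenic"
    elif conserved_missense or gt_at or predictor_consensus:
        tier = "suspected_pathogenic"
    elif in_controls:
        tier = "polymorphism"
    else:
        tier = "unknown_significance"
        evidence.append("no_evidence")
    return ClassifiedVariant(variant=variant, tier=tier, evidence=evidence)


def triage(
    variants: Iterable[VariantRecord],
    known_db: KnowledgeTable,
    cfg: TriageConfig | None = None,
    control_db: frozenset[tuple[str, int, str, str]] | None = None,
    panel: GenePanel | None = None,
) -> list[ClassifiedVariant]:
    """filter_candidates followed by classify, the full triage of a sample."""
    cfg = cfg or TriageConfig()
    return [
        classify(v, known_db, cfg, control_db=control_db, panel=panel)
        for v in filter_candidates(variants, cfg)
    ]


# ---------------------------------------------------------------------------
# Summaries


def _pct(part: float, total: float, ndigits: int = 2) -> float:
    return round(100.0 * part / total, ndigits) if total else 0.0


@dataclass
class VariantSummary:
    """Counts of SNVs and indels by consequence class and zygosity.

    Counts are floats so that cross-sample averages can be summarised with
    the same arithmetic as integer per-sample tallies.
    """

    snv_by_class: dict[str, float] = field(default_factory=dict)
    indel_by_class: dict[str, float] = field(default_factory=dict)
    snv_zygosity: dict[str, float] = field(default_factory=dict)
    indel_zygosity: dict[str, float] = field(default_factory=dict)

    @property
    def total_snvs(self) -> float:
        return sum(self.snv_zygosity.values()) or sum(self.snv_by_class.values())

    @property
    def total_indels(self) -> float:
        return sum(self.indel_zygosity.values()) or sum(self.indel_by_class.values())

    def snv_class_percents(self) -> dict[str, float]:
        return {c: _pct(n, self.total_snvs) for c, n in self.snv_by_class.items()}

    def indel_class_percents(self) -> dict[str, float]:
        return {c: _pct(n, self.total_indels) for c, n in self.indel_by_class.items()}

    def snv_zygosity_percents(self) -> dict[str, float]:
        return {z: _pct(n, self.total_snvs) for z, n in self.snv_zygosity.items()}

    def indel_zygosity_percents(self) -> dict[str, float]:
        return {z: _pct(n, self.total_indels) for z, n in self.indel_zygosity.items()}

    @classmethod
    def from_counts(
        cls,
        snv_by_class: Mapping[str, float] | None = None,
        indel_by_class: Mapping[str, float] | None = None,
        snv_zygosity: Mapping[str, float] | None = None,
        indel_zygosity: Mapping[str, float] | None = None,
    ) -> "VariantSummary":
        """Build a summary directly from tallies (e.g. published averages)."""
        return cls(
            snv_by_class=dict(snv_by_class or {}),
            indel_by_class=dict(indel_by_class or {}),
            snv_zygosity=dict(snv_zygosity or {}),
            indel_zygosity=dict(indel_zygosity or {}),
        )


def summarize_variants(variants: Iterable[VariantRecord]) -> VariantSummary:
    """Tally a variant list by type, consequence class and zygosity."""
    summary = VariantSummary()
    for v in variants:
        by_class = summary.snv_by_class if v.is_snv else summary.indel_by_class
        zyg = summary.snv_zygosity if v.is_snv else summary.indel_zygosity
        cls_key = v.consequence or "unannotated"
        by_class[cls_key] = by_class.get(cls_key, 0) + 1
        zyg[v.zygosity] = zyg.get(v.zygosity, 0) + 1
    return summary


# ---------------------------------------------------------------------------
# Cohort phenotype table


NUMERIC_COHORT_FIELDS = (
    "age_at_examination",
    "age_at_diagnosis",
    "height",
    "weight",
    "bmi",
    "hba1c",
)

TREATMENTS = ("ins", "ins+OHA", "OHA", "diet")


@dataclass
class CohortRecord:
    """Phenotype record of one mutation carrier; any field may be missing."""

    sample_id: str
    pathogenic_gene: str | None = None
    sex: str | None = None
    age_at_examination: float | None = None
    age_at_diagnosis: float | None = None
    height: float | None = None  # cm
    weight: float | None = None  # kg
    bmi: float | None = None  # kg/m^2
    hba1c: float | None = None  # percent
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.bmi is not None and self.height and self.weight:
            expected = self.weight / (self.height / 100.0) ** 2
            if abs(self.bmi - expected) > 0.1:
                raise ValueError(
                    f"{self.sample_id}: bmi {self.bmi} inconsistent with "
                    f"height/weight (expected {expected:.1f})"
                )
        if self.treatment is not None and self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")


def _cell(values: list[float], n_missing: int) -> str:
    if not values:
        return f"NA [{n_missing}]"
    mean = sum(values) / len(values)
    return f"{mean:.2f} ({min(values):g}-{max(values):g}) [{n_missing}]"


def summarize_cohort(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Per-gene phenotype table: n, sex split, mean (min-max) [n missing]
    for each numeric field, and the treatment split; plus a Total row."""
    groups: dict[str, list[CohortRecord]] = {}
    for r in records:
        groups.setdefault(r.pathogenic_gene or "unknown", []).append(r)
    rows = []
    order = sorted(groups) + ["Total"]
    groups["Total"] = list(records)
    for gene in order:
        members = groups[gene]
        row: dict[str, object] = {"gene": gene, "n": len(members)}
        row["sex_m_f"] = (
            f"{sum(1 for m in members if m.sex == 'M')}/"
            f"{sum(1 for m in members if m.sex == 'F')}"
        )
        for fname in NUMERIC_COHORT_FIELDS:
            values = [getattr(m, fname) for m in members if getattr(m, fname) is not None]
            row[fname] = _cell(values, len(members) - len(values))
        row["treatment"] = "/".join(
            str(sum(1 for m in members if m.treatment == t)) for t in TREATMENTS
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def gene_shares(records: Sequence[CohortRecord]) -> dict[str, int]:
    """Percent of carriers per pathogenic gene, rounded to integer percent."""
    total = len(records)
    counts: dict[str, int] = {}
    for r in records:
        gene = r.pathogenic_gene or "unknown"
        counts[gene] = counts.get(gene, 0) + 1
    return {g: round(100.0 * n / total) for g, n in counts.items()} if total else {}
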