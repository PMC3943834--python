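"""Truth-set benchmarking of SNV calls over covered target bases.

Calls are first reduced to high-quality SNVs (caller score, site depth and
alt-supporting read fraction thresholds), then compared position by
position against a truth set restricted to the covered bases:

* TP — filtered call matching the truth allele at a covered position;
* FP — filtered call at a covered position absent from the truth set (or
  with a mismatching alt allele);
* FN — covered truth position with no surviving matching call;
* TN — every remaining covered base.

Matching is site-level (position + alt allele); genotype concordance is
reported separately and does not enter the confusion counts. Indels are
excluded — the assessment is defined over SNVs only.

``covered`` is the set of target bases with evaluable coverage (typically
depth >= the benchmark's min_depth in the evaluated sample), which makes
the true-negative count well-defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .panel_io import DepthTable, VariantRecord

log = logging.getLogger(__name__)

Position = tuple[str, int]


@dataclass(frozen=True)
class BenchFilters:
    min_score: float = 20.0
    min_depth: int = 20
    min_alt_fraction: float = 0.28

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_alt_fraction <= 1.0:
            raise ValueError("min_alt_fraction must be in [0, 1]")

    def passes(self, v: VariantRecord) -> bool:
        return (
            v.call_quality >= self.min_score
            and v.depth >= self.min_depth
            and v.alt_fraction >= self.min_alt_fraction
        )


@dataclass
class ConfusionCounts:
    covered_bp: int
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn != self.covered_bp:
            raise ValueError("TP + TN + FP + FN must equal covered_bp")


@dataclass
class BenchReport:
    counts: ConfusionCounts
    tp_ratio: float | None
    fn_ratio: float | None
    tn_ratio: float
    fp_ratio: float
    accuracy: float
    precision: float | None

    def to_tsv(self) -> str:
        c = self.counts
        def fmt(x: float | None) -> str:
            return "NA" if x is None else f"{x}"
        return (
            f"covered_bp\t{c.covered_bp}\n"
            f"tp\t{c.tp}\ntn\t{c.tn}\nfp\t{c.fp}\nfn\t{c.fn}\n"
            f"tp_ratio_pct\t{fmt(self.tp_ratio)}\n"
            f"tn_ratio_pct\t{self.tn_ratio}\n"
            f"fn_ratio_pct\t{fmt(self.fn_ratio)}\n"
            f"fp_ratio_pct\t{self.fp_ratio}\n"
            f"accuracy_pct\t{self.accuracy}\n"
            f"precision_pct\t{fmt(self.precision)}\n"
        )


def covered_positions(
    depth: DepthTable, min_depth: int = 20, restrict_to: Iterable[Position] | None = None
) -> set[Position]:
    """Target bases with depth >= min_depth, optionally intersected with a
    position set (e.g. the merged panel target)."""
    covered = {
        (chrom, pos)
        for chrom, posmap in depth.records.items()
        for pos, d in posmap.items()
        if d >= min_depth
    }
    if restrict_to is not None:
        covered &= set(restrict_to)
    return covered


def confusion_counts(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    covered: set[Position],
    f: BenchFilters | None = None,
) -> ConfusionCounts:
    """Position-by-position confusion tally of SNV calls against truth."""
    f = f or BenchFilters()
    truth_alleles: dict[Position, set[str]] = {}
    for t in truth:
        if not t.is_snv:
            continue
        key = (t.chrom, t.pos)
        if key in covered:
            truth_alleles.setdefault(key, set()).add(t.alt)

    n_outside = 0
    call_alleles: dict[Position, set[str]] = {}
    for c in calls:
        if not c.is_snv or not f.passes(c):
            continue
        key = (c.chrom, c.pos)
        if key not in covered:
            n_outside += 1
            continue
        call_alleles.setdefault(key, set()).add(c.alt)
    if n_outside:
        log.info("%d filtered calls outside the covered region ignored", n_outside)

    tp = fp = 0
    for key, alts in call_alleles.items():
        if key in truth_alleles and alts & truth_alleles[key]:
            tp += 1
        else:
            fp += 1
    fn = sum(
        1
        for key, alts in truth_alleles.items()
        if not (call_alleles.get(key, set()) & alts)
    )
    tn = len(covered) - tp - fp - fn
    return ConfusionCounts(covered_bp=len(covered), tp=tp, tn=tn, fp=fp, fn=fn)


def genotype_concordance(
    calls: Sequence[VariantRecord], truth: Sequence[VariantRecord]
) -> float | None:
    """Fraction of allele-matched SNV calls whose zygosity also matches."""
    truth_by_key = {t.key: t for t in truth if t.is_snv}
    matched = [c for c in calls if c.is_snv and c.key in truth_by_key]
    if not matched:
        return None
    agree = sum(1 for c in matched if c.zygosity == truth_by_key[c.key].zygosity)
    return agree / len(matched)


def bench_report(
    c: ConfusionCounts, precision_text_formula: bool = False
) -> BenchReport:
    """Ratios and summary statistics from a confusion tally.

    TP and FN ratios are fractions of the truth positives; TN and FP ratios
    of the truth negatives. Accuracy is (TP + TN) / covered. Precision is
    TP / (TP + FP); ``precision_text_formula=True`` switches to
    TP / (TP + FN), which equals the TP ratio. Percents are rounded to two
    decimals, the FP ratio to three.
    """
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    tp_ratio = round(100.0 * c.tp / pos, 2) if pos else None
    fn_ratio = round(100.0 * c.fn / pos, 2) if pos else None
    tn_ratio = round(100.0 * c.tn / neg, 2) if neg else 0.0
    fp_ratio = round(100.0 * c.fp / neg, 3) if neg else 0.0
    accuracy = round(100.0 * (c.tp + c.tn) / c.covered_bp, 2) if c.covered_bp else 0.0
    if precision_text_formula:
        precision = tp_ratio
    else:
        precision = round(100.0 * c.tp / (c.tp + c.fp), 2) if (c.tp + c.fp) else None
    return BenchReport(
        counts=c,
        tp_ratio=tp_ratio,
        fn_ratio=fn_ratio,
        tn_ratio=tn_ratio,
        fp_ratio=fp_ratio,
        accuracy=accuracy,
        precision=precision,
    )
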