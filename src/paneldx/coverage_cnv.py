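"""Coverage statistics and depth-rate z-score detection of exon-scale CNVs.

Capture depth of a given region is strongly correlated across samples
sequenced in the same run (the per-region capture efficiency is a property
of the probe, not the sample), so a sample's relative depth in one region
can be scored against the same region in the other samples of its run.

For sample s and region r the depth rate is

    rate[s, r] = mean_depth[s, r] / mean_depth_of_sample[s]

and the z-score of the tested sample against the leave-one-out baseline is

    z[r] = (rate[s, r] - mean_{s' != s} rate[s', r]) / sd_{s' != s} rate[s', r]

with the sample standard deviation (n-1 denominator). A region is called a
deletion when z < -cutoff and a duplication when z > +cutoff, strictly; the
default cutoff 3 corresponds to the one-tailed 99.9th percentile of a
standard normal baseline. Consecutive flagged regions of the same gene and
direction are merged into a single call.

The test statistic is a single observation against the baseline
distribution, so no sqrt(n) factor is applied to the baseline SD. Regions
whose baseline SD falls below a small floor are uninformative and are never
called.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .panel_io import DepthTable, GenePanel, TargetRegion

log = logging.getLogger(__name__)

#: Baseline SD below this floor marks a region uninformative.
SD_FLOOR = 1e-6

#: Smallest usable leave-one-out baseline.
MIN_BASELINE = 3

DEFAULT_CUTOFF = 3.0


class BaselineTooSmallError(ValueError):
    """Raised when a run has too few samples for a leave-one-out baseline."""


@dataclass
class CoverageReport:
    mean_depth_target: float
    coverage_at: dict[int, float]
    mean_depth_flanking: float
    coverage_flanking_1x: float
    capture_specificity: float | None = None
    mean_read_length: float | None = None

    def to_tsv(self) -> str:
        lines = [f"mean_depth_target\t{self.mean_depth_target:.2f}"]
        for t in sorted(self.coverage_at):
            lines.append(f"coverage_ge_{t}x_pct\t{self.coverage_at[t]:.2f}")
        if self.capture_specificity is not None:
            lines.append(f"capture_specificity_pct\t{self.capture_specificity:.2f}")
        lines.append(f"mean_depth_flanking\t{self.mean_depth_flanking:.2f}")
        lines.append(f"coverage_flanking_1x_pct\t{self.coverage_flanking_1x:.2f}")
        if self.mean_read_length is not None:
            lines.append(f"mean_read_length\t{self.mean_read_length:.2f}")
        return "\n".join(lines) + "\n"


@dataclass
class DepthMatrix:
    """Per-region mean depths for the samples of one sequencing run."""

    run_id: str
    samples: list[str]
    regions: list[TargetRegion]
    mean_depth: np.ndarray  # shape (n_samples, n_regions)
    sample_mean_depth: np.ndarray  # shape (n_samples,)

    def __post_init__(self) -> None:
        self.mean_depth = np.asarray(self.mean_depth, dtype=float)
        self.sample_mean_depth = np.asarray(self.sample_mean_depth, dtype=float)
        if self.mean_depth.shape != (len(self.samples), len(self.regions)):
            raise ValueError("mean_depth shape inconsistent with samples/regions")
        if (self.mean_depth < 0).any() or (self.sample_mean_depth < 0).any():
            raise ValueError("depths must be non-negative")

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)


@dataclass
class CnvCall:
    sample_id: str
    gene: str
    chrom: str
    start: int
    end: int
    regions: list[int]
    direction: str  # "deletion" | "duplication"
    z_extreme: float
    per_region_z: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Coverage statistics


def coverage_stats(
    depth: DepthTable,
    panel: GenePanel,
    thresholds: Sequence[int] = (1, 20),
    flank_bp: int = 200,
    mapped_total: float | None = None,
    mapped_on_target: float | None = None,
    mean_read_length: float | None = None,
) -> CoverageReport:
    """Per-sample coverage summary over the merged panel target.

    coverage_at[t] is the percent of target bases with depth >= t;
    capture specificity is 100 * mapped_on_target / mapped_total when both
    mapped read (or base) counts are supplied. The flanking region is the
    ``flank_bp`` bases on each side of each merged target interval,
    excluding any base inside the target itself.
    """
    if not panel.regions:
        raise ValueError("empty panel")
    if not thresholds or any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive integers")
    merged = panel.merged_intervals()
    target_depths: list[int] = []
    target_positions: dict[str, set[int]] = {}
    for chrom, start, end in merged:
        pos_set = target_positions.setdefault(chrom, set())
        for pos0 in range(start, end):
            target_depths.append(depth.depth_at(chrom, pos0 + 1))
            pos_set.add(pos0)
    arr = np.asarray(target_depths, dtype=float)
    total_bp = arr.size
    coverage_at = {
        int(t): 100.0 * float((arr >= t).sum()) / total_bp for t in thresholds
    }
    flank_depths: list[int] = []
    for chrom, start, end in merged:
        in_target = target_positions[chrom]
        for pos0 in range(max(0, start - flank_bp), start):
            if pos0 not in in_target:
                flank_depths.append(depth.depth_at(chrom, pos0 + 1))
        for pos0 in range(end, end + flank_bp):
            if pos0 not in in_target:
                flank_depths.append(depth.depth_at(chrom, pos0 + 1))
    flank_arr = np.asarray(flank_depths, dtype=float)
    specificity = None
    if mapped_total and mapped_on_target is not None:
        specificity = 100.0 * mapped_on_target / mapped_total
    return CoverageReport(
        mean_depth_target=float(arr.mean()),
        coverage_at=coverage_at,
        mean_depth_flanking=float(flank_arr.mean()) if flank_arr.size else 0.0,
        coverage_flanking_1x=(
            100.0 * float((flank_arr >= 1).sum()) / flank_arr.size
            if flank_arr.size
            else 0.0
        ),
        capture_specificity=specificity,
        mean_read_length=mean_read_length,
    )


def depth_matrix_from_tables(
    run_id: str,
    tables: Mapping[str, DepthTable],
    panel: GenePanel,
    regions: Sequence[TargetRegion] | None = None,
) -> DepthMatrix:
    """Build a run's DepthMatrix from per-sample per-base depth tables.

    ``regions`` defaults to the panel's CDS regions (the exon-level
    granularity at which CNVs are scored); the per-sample mean depth is
    taken over all merged panel bases.
    """
    if regions is None:
        regions = panel.regions_of_class("CDS") or panel.regions
    samples = list(tables)
    merged = panel.merged_intervals()
    mean_depth = np.zeros((len(samples), len(regions)))
    sample_mean = np.zeros(len(samples))
    for si, sample in enumerate(samples):
        table = tables[sample]
        total = 0
        total_bp = 0
        for chrom, start, end in merged:
            for pos0 in range(start, end):
                total += table.depth_at(chrom, pos0 + 1)
            total_bp += end - start
        sample_mean[si] = total / total_bp if total_bp else 0.0
        for ri, region in enumerate(regions):
            depths = [
                table.depth_at(region.chrom, pos0 + 1)
                for pos0 in range(region.start, region.end)
            ]
            mean_depth[si, ri] = float(np.mean(depths))
    return DepthMatrix(
        run_id=run_id,
        samples=samples,
        regions=list(regions),
        mean_depth=mean_depth,
        sample_mean_depth=sample_mean,
    )


# ---------------------------------------------------------------------------
# Depth-rate z-scores


def region_depth_rates(matrix: DepthMatrix) -> tuple[np.ndarray, list[str]]:
    """Normalise each sample's region depths by its overall mean depth.

    Returns (rates, kept_samples); samples with zero mean depth are
    excluded with a warning.
    """
    keep = matrix.sample_mean_depth > 0
    if not keep.all():
        for sid in np.array(matrix.samples)[~keep]:
            log.warning("sample %s has zero mean depth; excluded from rates", sid)
    rates = (
        matrix.mean_depth[keep] / matrix.sample_mean_depth[keep, np.newaxis]
    )
    kept_samples = [s for s, k in zip(matrix.samples, keep) if k]
    return rates, kept_samples


def cnv_zscores(
    rates: np.ndarray, samples: Sequence[str], sample_id: str
) -> np.ndarray:
    """Per-region z-scores of one sample against the leave-one-out baseline.

    Regions whose baseline SD is below the floor get NaN (uninformative).
    Requires at least MIN_BASELINE other samples in the run.
    """
    idx = list(samples).index(sample_id)
    others = np.delete(rates, idx, axis=0)
    if others.shape[0] < MIN_BASELINE:
        raise BaselineTooSmallError(
            f"need >= {MIN_BASELINE} baseline samples, have {others.shape[0]}"
        )
    mu = others.mean(axis=0)
    sd = others.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (rates[idx] - mu) / sd
    z[sd < SD_FLOOR] = np.nan
    return z


def call_cnvs(
    z: np.ndarray,
    regions: Sequence[TargetRegion],
    sample_id: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[CnvCall]:
    """Threshold per-region z-scores and merge consecutive calls.

    Strict inequalities: a region is a deletion iff z < -cutoff and a
    duplication iff z > +cutoff; |z| == cutoff is not called. Consecutive
    flagged regions of the same gene and direction form one merged call.
    """
    if len(z) != len(regions):
        raise ValueError("z length must match regions")

    def direction(value: float) -> str | None:
        if math.isnan(value):
            return None
        if value < -cutoff:
            return "deletion"
        if value > cutoff:
            return "duplication"
        return None

    calls: list[CnvCall] = []
    current: CnvCall | None = None
    for i, (zi, region) in enumerate(zip(z, regions)):
        d = direction(float(zi))
        if d is None:
            current = None
            continue
        if (
            current is not None
            and current.direction == d
            and current.gene == region.gene
            and current.chrom == region.chrom
            and current.regions[-1] == i - 1
        ):
            current.end = region.end
            current.regions.append(i)
            current.per_region_z.append(float(zi))
            extreme = min if d == "deletion" else max
            current.z_extreme = extreme(current.z_extreme, float(zi))
        else:
            current = CnvCall(
                sample_id=sample_id,
                gene=region.gene,
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                regions=[i],
                direction=d,
                z_extreme=float(zi),
                per_region_z=[float(zi)],
            )
            calls.append(current)
    return calls


def call_cnvs_for_run(
    matrix: DepthMatrix, cutoff: float = DEFAULT_CUTOFF
) -> dict[str, list[CnvCall]]:
    """Score every sample of a run against its leave-one-out baseline."""
    rates, samples = region_depth_rates(matrix)
    out: dict[str, list[CnvCall]] = {}
    for sid in samples:
        z = cnv_zscores(rates, samples, sid)
        out[sid] = call_cnvs(z, matrix.regions, sid, cutoff=cutoff)
    return out


def zscore_percentile(cutoff: float = DEFAULT_CUTOFF) -> float:
    """One-tailed standard-normal percentile of the cutoff, in percent."""
    return 100.0 * float(norm.cdf(cutoff))


def write_cnv_calls(calls: Sequence[CnvCall], path) -> None:
    """Write calls as a BED-like TSV (0-based half-open spans)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsample\tgene\tdirection\tz_extreme\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.sample_id}\t{c.gene}\t"
                f"{c.direction}\t{c.z_extreme:.3f}\n"
            )
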