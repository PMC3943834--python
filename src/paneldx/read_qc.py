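"""Pre-alignment read filtering ("unqualified reads").

A read is unqualified — and removed whole, never trimmed — when it is
polluted by adapter sequence, carries more than 10% ambiguous (N) bases,
has a mean Phred quality below 10, or has at least 50% of bases below
Phred 5. Paired-end mates are removed together when either fails.

Rule interpretation notes:

* "more than 10% nucleotides out of read length" is read as the standard
  ambiguous-base rule: fraction of N bases strictly greater than 0.10.
* the low-quality-base rule uses >= 50% (the conservative reading of a
  stated threshold); the fraction is configurable.
* mean quality is the arithmetic mean of Phred scores, not
  error-probability averaging.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

#: Standard Illumina paired-end adapter (read 1), the default contaminant.
DEFAULT_ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"

REASONS = ("adapter", "n_fraction", "mean_quality", "low_quality_bases")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    mate: int | None = None

    def validate(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"{self.read_id}: negative Phred score")


@dataclass(frozen=True)
class QCThresholds:
    adapter_seq: str = DEFAULT_ADAPTER
    adapter_min_match: int = 10
    adapter_max_mismatch: int = 1
    max_n_fraction: float = 0.10
    min_mean_quality: float = 10.0
    low_qual_threshold: int = 5
    max_low_qual_fraction: float = 0.50

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must be in [0, 1]")
        if not 0.0 <= self.max_low_qual_fraction <= 1.0:
            raise ValueError("max_low_qual_fraction must be in [0, 1]")
        if self.adapter_min_match <= 0 or self.adapter_max_mismatch < 0:
            raise ValueError("adapter parameters must be non-negative")


@dataclass
class QCReport:
    n_input: int = 0
    n_kept: int = 0
    removal_counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS}
    )
    n_invalid: int = 0

    def to_tsv(self) -> str:
        lines = [f"n_input\t{self.n_input}", f"n_kept\t{self.n_kept}"]
        lines += [f"removed_{r}\t{self.removal_counts[r]}" for r in REASONS]
        lines.append(f"invalid\t{self.n_invalid}")
        return "\n".join(lines) + "\n"


def is_adapter_polluted(read: ReadRecord, t: QCThresholds) -> bool:
    """True iff a window of >= adapter_min_match adapter bases aligns within
    the read with <= adapter_max_mismatch mismatches.

    The adapter is slid across the read at every offset, including partial
    overlaps at either end, and each overlap of sufficient length is scored
    by Hamming distance.
    """
    if not t.adapter_seq:
        raise ValueError("adapter_seq must be non-empty")
    seq = read.sequence.upper()
    adapter = t.adapter_seq.upper()
    n, m = len(seq), len(adapter)
    # offset = position of adapter[0] relative to seq[0]; negatives allow
    # a trailing adapter fragment at the read start.
    for offset in range(-(m - t.adapter_min_match), n - t.adapter_min_match + 1):
        lo = max(0, offset)
        hi = min(n, offset + m)
        if hi - lo < t.adapter_min_match:
            continue
        mismatches = 0
        for i in range(lo, hi):
            if seq[i] != adapter[i - offset]:
                mismatches += 1
                if mismatches > t.adapter_max_mismatch:
                    break
        else:
            return True
    return False


def failure_reason(read: ReadRecord, t: QCThresholds) -> str | None:
    """First firing removal rule, in the fixed order adapter, n_fraction,
    mean_quality, low_quality_bases; None when the read is qualified."""
    if is_adapter_polluted(read, t):
        return "adapter"
    n = len(read.sequence)
    if n == 0:
        return None
    if read.sequence.upper().count("N") / n > t.max_n_fraction:
        return "n_fraction"
    if sum(read.qualities) / n < t.min_mean_quality:
        return "mean_quality"
    n_low = sum(1 for q in read.qualities if q < t.low_qual_threshold)
    if n_low / n >= t.max_low_qual_fraction:
        return "low_quality_bases"
    return None


def filter_reads(
    reads: Iterable[ReadRecord], t: QCThresholds | None = None
) -> tuple[list[ReadRecord], QCReport]:
    """Filter a single-end read stream; returns kept reads and the report."""
    t = t or QCThresholds()
    report = QCReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.n_input += 1
        try:
            read.validate()
        except ValueError as exc:
            log.warning("dropping malformed read: %s", exc)
            report.n_invalid += 1
            continue
        reason = failure_reason(read, t)
        if reason is None:
            kept.append(read)
            report.n_kept += 1
        else:
            report.removal_counts[reason] += 1
    return kept, report


def filter_read_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]], t: QCThresholds | None = None
) -> tuple[list[tuple[ReadRecord, ReadRecord]], QCReport]:
    """Filter paired reads in lock-step: if either mate fails, both are
    removed. A mate dropped only because its partner failed is counted
    under the partner's reason, keeping n_input == n_kept + sum(removals).
    """
    t = t or QCThresholds()
    report = QCReport()
    kept: list[tuple[ReadRecord, ReadRecord]] = []
    for r1, r2 in pairs:
        report.n_input += 2
        try:
            r1.validate()
            r2.validate()
        except ValueError as exc:
            log.warning("dropping malformed pair: %s", exc)
            report.n_invalid += 2
            continue
        reason1 = failure_reason(r1, t)
        reason2 = failure_reason(r2, t)
        if reason1 is None and reason2 is None:
            kept.append((r1, r2))
            report.n_kept += 2
        else:
            report.removal_counts[reason1 or reason2] += 1
            report.removal_counts[reason2 or reason1] += 1
    return kept, report


# ---------------------------------------------------------------------------
# FASTQ I/O


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (optionally gzipped) FASTQ file."""
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(
                read_id=title.split()[0],
                sequence=seq,
                qualities=tuple(ord(c) - phred_offset for c in qual),
            )


def write_fastq(
    reads: Iterable[ReadRecord], path: str | Path, phred_offset: int = 33
) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + phred_offset) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def filter_fastq_pair(
    in1: str | Path,
    in2: str | Path,
    out_prefix: str,
    t: QCThresholds | None = None,
    phred_offset: int = 33,
) -> QCReport:
    """Filter two lock-step FASTQ files, writing <prefix>.1.fq / <prefix>.2.fq."""
    pairs = zip(read_fastq(in1, phred_offset), read_fastq(in2, phred_offset))
    kept, report = filter_read_pairs(pairs, t)
    write_fastq((r1 for r1, _ in kept), f"{out_prefix}.1.fq", phred_offset)
    write_fastq((r2 for _, r2 in kept), f"{out_prefix}.2.fq", phred_offset)
    return report
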