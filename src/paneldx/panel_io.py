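"""Data model and I/O for target panels, per-base depth tables and variants.

Coordinate conventions
----------------------
BED input is 0-based half-open; VCF and depth tables are 1-based. All
interval arithmetic inside the package uses the 0-based half-open
convention. Strand is ignored throughout: depth and variant logic on a
capture panel is strand-free.

Annotations (consequence, database allele frequencies, predictor verdicts,
conservation) are transported on VCF INFO fields rather than computed here;
running consequence or conservation predictors is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import cyvcf2

log = logging.getLogger(__name__)

REGION_CLASSES = frozenset(
    {"CDS", "intron", "UTR5", "UTR3", "promoter", "splice_site", "intergenic"}
)

CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "splice_site",
        "synonymous",
        "frameshift",
        "inframe_indel",
        "UTR5",
        "UTR3",
        "intron",
        "intergenic",
        "promoter",
        "read_through",
    }
)

VTYPES = frozenset({"SNV", "insertion", "deletion"})


class PanelFormatError(ValueError):
    """Malformed panel, depth, variant or knowledge-table input."""


@dataclass(frozen=True)
class TargetRegion:
    """One captured interval, annotated with gene and region class.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive.
    """

    chrom: str
    start: int
    end: int
    gene: str
    region_class: str
    exon_index: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelFormatError(
                f"region {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.region_class not in REGION_CLASSES:
            raise PanelFormatError(
                f"unknown region class {self.region_class!r} "
                f"(expected one of {sorted(REGION_CLASSES)})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, chrom: str, pos0: int) -> bool:
        """True if the 0-based position falls inside this region."""
        return chrom == self.chrom and self.start <= pos0 < self.end


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Union of half-open intervals, per chromosome, sorted. Idempotent."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


@dataclass
class GenePanel:
    """An ordered collection of target regions forming a capture panel."""

    regions: list[TargetRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=TargetRegion.sort_key)

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.regions}

    def merged_intervals(self) -> list[tuple[str, int, int]]:
        return merge_intervals((r.chrom, r.start, r.end) for r in self.regions)

    @property
    def total_target_bp(self) -> int:
        """Length sum after merging overlapping intervals."""
        return sum(e - s for _, s, e in self.merged_intervals())

    def regions_of_class(self, region_class: str) -> list[TargetRegion]:
        return [r for r in self.regions if r.region_class == region_class]

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class VariantRecord:
    """One called variant with genotype, quality and annotation payload.

    ``pos`` is 1-based (VCF convention). ``db_afs`` is an open map from
    database name to allele frequency so new frequency sources need no
    schema change; ``predictor_calls`` maps predictor name to one of
    ``damaging``/``benign``/``unknown``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str = ""
    zygosity: str = "het"
    call_quality: float = 0.0
    depth: int = 0
    alt_fraction: float = 0.0
    gene: str = ""
    consequence: str = ""
    db_afs: dict[str, float] = field(default_factory=dict)
    predictor_calls: dict[str, str] = field(default_factory=dict)
    known_pathogenic_id: str | None = None
    conserved: bool = False

    def __post_init__(self) -> None:
        if not self.vtype:
            self.vtype = infer_vtype(self.ref, self.alt)
        if self.vtype not in VTYPES:
            raise PanelFormatError(f"unknown variant type {self.vtype!r}")
        expected = infer_vtype(self.ref, self.alt)
        if self.vtype != expected:
            raise PanelFormatError(
                f"vtype {self.vtype!r} inconsistent with ref={self.ref} alt={self.alt}"
            )
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise PanelFormatError(
                f"alt_fraction {self.alt_fraction} outside [0, 1]"
            )
        if self.zygosity not in ("het", "hom"):
            raise PanelFormatError(f"zygosity must be het or hom, got {self.zygosity!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.vtype == "SNV"

    @property
    def is_indel(self) -> bool:
        return self.vtype in ("insertion", "deletion")


def infer_vtype(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    raise PanelFormatError(f"cannot type variant ref={ref!r} alt={alt!r}")


@dataclass
class DepthTable:
    """Per-base sequencing depth for one sample.

    Positions are 1-based; positions absent from the table are interpreted
    as depth 0 by downstream consumers.
    """

    sample_id: str
    records: dict[str, dict[int, int]] = field(default_factory=dict)

    def add(self, chrom: str, pos: int, depth: int) -> None:
        if depth < 0:
            raise PanelFormatError(f"negative depth {depth} at {chrom}:{pos}")
        chrom_map = self.records.setdefault(chrom, {})
        chrom_map[pos] = depth

    def depth_at(self, chrom: str, pos: int) -> int:
        return self.records.get(chrom, {}).get(pos, 0)

    def __len__(self) -> int:
        return sum(len(m) for m in self.records.values())


# ---------------------------------------------------------------------------
# Readers


def load_panel(path: str | Path) -> GenePanel:
    """Read a capture panel from BED (0-based half-open).

    The BED name field carries the annotation as ``GENE|CLASS[|EXON]``,
    e.g. ``GCK|CDS|1``.
    """
    regions: list[TargetRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelFormatError(
                    f"{path}:{lineno}: expected >= 4 BED columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name_parts = fields[3].split("|")
            if len(name_parts) < 2:
                raise PanelFormatError(
                    f"{path}:{lineno}: name field must be GENE|CLASS[|EXON], "
                    f"got {fields[3]!r}"
                )
            exon = int(name_parts[2]) if len(name_parts) > 2 else None
            try:
                regions.append(
                    TargetRegion(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        gene=name_parts[0],
                        region_class=name_parts[1],
                        exon_index=exon,
                    )
                )
            except PanelFormatError as exc:
                raise PanelFormatError(f"{path}:{lineno}: {exc}") from exc
    return GenePanel(regions=regions)


def write_panel(panel: GenePanel, path: str | Path) -> None:
    """Write a panel back to BED with the GENE|CLASS[|EXON] name field."""
    with open(path, "w") as fh:
        for r in panel.regions:
            name = f"{r.gene}|{r.region_class}"
            if r.exon_index is not None:
                name += f"|{r.exon_index}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def load_depth(path: str | Path, sample_id: str | None = None) -> DepthTable:
    """Read a 3-column chrom/pos/depth TSV (1-based positions)."""
    if sample_id is None:
        sample_id = Path(path).stem
    table = DepthTable(sample_id=sample_id)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                pos, depth = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: non-integer field") from exc
            if depth < 0:
                raise PanelFormatError(f"{path}:{lineno}: negative depth {depth}")
            table.add(fields[0], pos, depth)
    return table


def write_depth(table: DepthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(table.records):
            for pos in sorted(table.records[chrom]):
                fh.write(f"{chrom}\t{pos}\t{table.records[chrom][pos]}\n")


_INFO_PREFIX_AF = "AF_"
_INFO_PREFIX_PRED = "PRED_"


def load_variants(path: str | Path) -> list[VariantRecord]:
    """Read annotated variants from a VCF 4.x file.

    One record per ALT allele (multi-allelic sites are split). Annotations
    come from INFO keys GENE, CSQ, AF_<db>, PRED_<tool>, CONSERVED and
    KNOWN_ID; zygosity from the single sample's GT; alt_fraction from AD
    when present. Records with a missing genotype are skipped with a
    warning.
    """
    records: list[VariantRecord] = []
    vcf = cyvcf2.VCF(str(path))
    try:
        for v in vcf:
            gts = v.genotypes
            if not gts or any(a < 0 for a in gts[0][:-1]):
                log.warning(
                    "skipping %s:%d %s: missing genotype", v.CHROM, v.POS, v.REF
                )
                continue
            alleles = gts[0][:-1]
            ad = None
            try:
                ad_arr = v.format("AD")
                if ad_arr is not None:
                    ad = [int(x) for x in ad_arr[0]]
            except KeyError:
                ad = None
            db_afs: dict[str, float] = {}
            predictor_calls: dict[str, str] = {}
            for key, value in dict(v.INFO).items():
                if key.startswith(_INFO_PREFIX_AF):
                    db_afs[key[len(_INFO_PREFIX_AF):]] = float(value)
                elif key.startswith(_INFO_PREFIX_PRED):
                    predictor_calls[key[len(_INFO_PREFIX_PRED):]] = str(value)
            for alt_index, alt in enumerate(v.ALT, start=1):
                allele_count = alleles.count(alt_index)
                if allele_count == 0 and len(v.ALT) > 1:
                    continue
                zygosity = "hom" if allele_count == len(alleles) and allele_count > 0 else "het"
                depth = int(v.INFO.get("DP") or 0)
                if ad is not None and sum(ad) > 0:
                    depth = depth or sum(ad)
                    alt_fraction = ad[alt_index] / sum(ad) if alt_index < len(ad) else 0.0
                else:
                    alt_fraction = 1.0 if zygosity == "hom" else 0.5
                records.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        zygosity=zygosity,
                        call_quality=float(v.QUAL) if v.QUAL is not None else 0.0,
                        depth=depth,
                        alt_fraction=alt_fraction,
                        gene=str(v.INFO.get("GENE") or ""),
                        consequence=str(v.INFO.get("CSQ") or ""),
                        db_afs=db_afs,
                        predictor_calls=predictor_calls,
                        known_pathogenic_id=(
                            str(v.INFO["KNOWN_ID"]) if v.INFO.get("KNOWN_ID") else None
                        ),
                        conserved=bool(v.INFO.get("CONSERVED", False)),
                    )
                )
    finally:
        vcf.close()
    return records


_VCF_INFO_HEADER = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Functional consequence">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">',
    '##INFO=<ID=CONSERVED,Number=0,Type=Flag,Description="Position in a cross-species conserved block">',
    '##INFO=<ID=KNOWN_ID,Number=1,Type=String,Description="Identifier in the known-pathogenic knowledge table">',
    '##INFO=<ID=TIER,Number=1,Type=String,Description="Assigned pathogenicity tier">',
    '##INFO=<ID=EVIDENCE,Number=1,Type=String,Description="Fired classification rules, comma separated">',
]


def write_variants(
    records: Sequence[VariantRecord],
    path: str | Path,
    sample_id: str = "SAMPLE",
    contig_lengths: Mapping[str, int] | None = None,
    extra_info: Sequence[Mapping[str, str]] | None = None,
) -> None:
    """Write variant records as a single-sample VCF 4.2 text file.

    ``extra_info``, when given, is a per-record map of additional INFO
    key/values (used to attach TIER/EVIDENCE after classification).
    """
    db_names = sorted({db for r in records for db in r.db_afs})
    pred_names = sorted({p for r in records for p in r.predictor_calls})
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    else:
        for chrom in sorted({r.chrom for r in records}):
            lines.append(f"##contig=<ID={chrom}>")
    lines.extend(_VCF_INFO_HEADER)
    for db in db_names:
        lines.append(
            f'##INFO=<ID=AF_{db},Number=1,Type=Float,Description="Allele frequency in {db}">'
        )
    for p in pred_names:
        lines.append(
            f'##INFO=<ID=PRED_{p},Number=1,Type=String,Description="Verdict of predictor {p}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for i, r in enumerate(sorted(records, key=lambda x: (x.chrom, x.pos, x.ref, x.alt))):
        info_parts = []
        if r.gene:
            info_parts.append(f"GENE={r.gene}")
        if r.consequence:
            info_parts.append(f"CSQ={r.consequence}")
        if r.depth:
            info_parts.append(f"DP={r.depth}")
        for db, af in sorted(r.db_afs.items()):
            info_parts.append(f"AF_{db}={af:g}")
        for pred, verdict in sorted(r.predictor_calls.items()):
            info_parts.append(f"PRED_{pred}={verdict}")
        if r.conserved:
            info_parts.append("CONSERVED")
        if r.known_pathogenic_id:
            info_parts.append(f"KNOWN_ID={r.known_pathogenic_id}")
        if extra_info is not None:
            for k, v in extra_info[i].items():
                info_parts.append(f"{k}={v}")
        gt = "1/1" if r.zygosity == "hom" else "0/1"
        alt_reads = round(r.depth * r.alt_fraction)
        ad = f"{r.depth - alt_reads},{alt_reads}"
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.call_quality:g}\t.\t"
            + (";".join(info_parts) or ".")
            + f"\tGT:AD\t{gt}:{ad}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Knowledge table of known pathogenic variants


def load_knowledge(path: str | Path) -> dict[tuple[str, int, str, str], dict[str, str]]:
    """Read the known-pathogenic knowledge table.

    TSV with header: chrom, pos, ref, alt, gene, citation_id. Matching
    downstream is exact on (chrom, pos, ref, alt); indel representations
    are not re-normalised beyond what the VCF provides.
    """
    table: dict[tuple[str, int, str, str], dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["chrom", "pos", "ref", "alt", "gene", "citation_id"]
        if header[: len(required)] != required:
            raise PanelFormatError(
                f"{path}: knowledge table header must start with {required}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise PanelFormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{lineno}: non-integer pos") from exc
            key = (fields[0], pos, fields[2], fields[3])
            table[key] = {"gene": fields[4], "citation_id": fields[5]}
    return table


def write_knowledge(
    table: Mapping[tuple[str, int, str, str], Mapping[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tcitation_id\n")
        for (chrom, pos, ref, alt), meta in sorted(table.items()):
            fh.write(
                f"{chrom}\t{pos}\t{ref}\t{alt}\t{meta['gene']}\t{meta['citation_id']}\n"
            )
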