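"""Coordinate data model and I/O for gene 3'UTRs and repeat annotations.

All internal coordinates are 0-based half-open. BED is native; RepeatMasker
``.out`` and VCF coordinates (both 1-based) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RepeatAnnotation",
    "read_bed",
    "write_bed",
    "read_repeatmasker_out",
    "read_gff3_utr3",
    "intersect",
    "merge_intervals",
    "alu_segments_in_utr3",
    "is_alu",
]


class BedParseError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene with the union of its transcript 3'UTR intervals.

    ``utr3_length`` is the length of the merged union (the denominator used
    when SNP counts are taken over the union).  ``longest_utr3_length`` is the
    length of the longest single annotated UTR among the gene's transcripts,
    kept separately because per-gene SNP densities use the longest annotated
    UTR as denominator.
    """

    gene_id: str
    transcript_id: str
    utr3: list[GenomicInterval] = field(default_factory=list)
    longest_utr3_length: int = 0

    def __post_init__(self) -> None:
        self.utr3 = merge_intervals(self.utr3)
        if self.longest_utr3_length == 0:
            self.longest_utr3_length = self.utr3_length

    @property
    def utr3_length(self) -> int:
        return sum(len(iv) for iv in self.utr3)


@dataclass(frozen=True)
class RepeatAnnotation:
    interval: GenomicInterval
    repeat_name: str
    repeat_class: str = ""

    def __post_init__(self) -> None:
        if not self.repeat_name:
            raise ValueError("repeat_name must be non-empty")


def is_alu(repeat_name: str, count_flam_fram: bool = False) -> bool:
    """Alu-family membership by subfamily name.

    FLAM/FRAM (free left/right Alu monomer) fragments are counted only when
    ``count_flam_fram`` is set.
    """
    if repeat_name.startswith("Alu"):
        return True
    if count_flam_fram and (
        repeat_name.startswith("FLAM") or repeat_name.startswith("FRAM")
    ):
        return True
    return False


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals, preserving file order."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = cols[3] if len(cols) > 3 else None
            strand = cols[5] if len(cols) > 5 and cols[5] in {"+", "-"} else "+"
            try:
                out.append(GenomicInterval(cols[0], start, end, strand, name))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand == "-":
                cols += [iv.name or ".", "0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def read_repeatmasker_out(path: str) -> list[RepeatAnnotation]:
    """Parse a RepeatMasker ``.out`` file (3 header lines, whitespace columns).

    Genomic begin/end are 1-based inclusive in the file and converted to
    0-based half-open here.
    """
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3 or not line.strip():
                continue
            cols = line.split()
            if len(cols) < 11:
                raise ValueError(
                    f"{path}:{lineno}: expected >=11 whitespace-separated columns"
                )
            try:
                begin, end = int(cols[5]), int(cols[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = "-" if cols[8] in {"C", "-"} else "+"
            iv = GenomicInterval(cols[4], begin - 1, end, strand)
            out.append(RepeatAnnotation(iv, repeat_name=cols[9], repeat_class=cols[10]))
    return out


def read_gff3_utr3(path: str) -> dict[str, GeneModel]:
    """Read ``three_prime_UTR`` features from a GFF3 file into gene models.

    Returns a mapping gene_id -> GeneModel with the union of all transcript
    3'UTR intervals and the longest single-transcript UTR length recorded.
    """
    per_tx: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cols[2] != "three_prime_UTR":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            tx = attrs.get("Parent") or attrs.get("transcript_id") or attrs.get("ID")
            gene = attrs.get("gene_id") or attrs.get("gene") or tx
            if tx is None:
                raise ValueError(f"{path}:{lineno}: three_prime_UTR without Parent/ID")
            iv = GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6])
            per_tx.setdefault(tx, []).append(iv)
            tx_gene[tx] = gene
    genes: dict[str, GeneModel] = {}
    for tx, ivs in per_tx.items():
        gene = tx_gene[tx]
        tx_len = sum(len(i) for i in merge_intervals(ivs))
        if gene in genes:
            gm = genes[gene]
            gm.utr3 = merge_intervals(gm.utr3 + ivs)
            gm.longest_utr3_length = max(gm.longest_utr3_length, tx_len)
        else:
            genes[gene] = GeneModel(gene, tx, list(ivs), longest_utr3_length=tx_len)
    return genes


def intersect(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval | None:
    """Intersection of two intervals, or None when empty (incl. abutment)."""
    if a.chrom != b.chrom:
        return None
    start, end = max(a.start, b.start), min(a.end, b.end)
    if start >= end:
        return None
    return GenomicInterval(a.chrom, start, end, a.strand)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (not merely abutting-by-name) intervals per chromosome.

    Abutting intervals ([a,b) and [b,c)) are merged as well, so the result is
    a minimal sorted set of disjoint intervals.
    """
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(
                    last.chrom, last.start, iv.end, last.strand, last.name
                )
        else:
            merged.append(iv)
    return merged


def alu_segments_in_utr3(
    gene: GeneModel,
    repeats: Sequence[RepeatAnnotation],
    count_flam_fram: bool = False,
) -> list[GenomicInterval]:
    """Alu-derived segments of a gene's 3'UTR.

    Intersects each merged UTR interval with every Alu-class repeat and merges
    the results; each segment carries the source subfamily name (the first
    one, where merging joined several).
    """
    pieces: list[GenomicInterval] = []
    for utr in gene.utr3:
        for rep in repeats:
            if not is_alu(rep.repeat_name, count_flam_fram):
                continue
            ov = intersect(utr, rep.interval)
            if ov is not None:
                pieces.append(
                    GenomicInterval(ov.chrom, ov.start, ov.end, utr.strand, rep.repeat_name)
                )
    return merge_intervals(pieces)
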