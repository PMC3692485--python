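"""Genomic interval types and annotation/read parsers.

Coordinates are 0-based half-open internally (BED convention).  GTF input,
which is 1-based inclusive, is converted at parse time.  refFlat and BED
inputs are already 0-based half-open.

Gene models with multiple isoforms sharing a ``gene_id`` are merged into a
single exon union per gene; duplicate exon coordinates collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ExonRecord",
    "ParseError",
    "merge_intervals",
    "read_gene_models",
    "read_bed6_reads",
    "read_alt_events",
]

CASSETTE_EVENT = "cassetteExon"


class ParseError(ValueError):
    """Malformed annotation or read line; carries the 1-based line number."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is '+', '-' or '.' (unstranded).  Reads and gene models must
    carry a defined strand; derived regions (exon unions, promoter windows)
    may be unstranded.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, disjoint, strand-agnostic, same chrom."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    if not ivs:
        return []
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


@dataclass(slots=True)
class GeneModel:
    """A gene as the union of its exons across isoforms.

    ``exons`` is the merged, start-sorted exon union; ``exonic_bp`` is the
    number of non-redundant exonic base pairs.  The TSS is the leftmost base
    for '+' genes and the rightmost base (``end - 1``) for '-' genes.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def exonic_bp(self) -> int:
        return sum(iv.length for iv in self.exons)

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(slots=True)
class ExonRecord:
    """One analyzable exon of a gene.

    ``ordinal`` is the 0-based position within the gene's exon union.
    ``klass`` is 'constitutive' or 'cassette'; first/last exons of a gene
    never become records.  ``inclusion`` (log2 exon/gene expression ratio)
    is filled once expression has been quantified; a negative inclusion
    flags the exon as alternatively spliced.
    """

    exon_id: str
    gene_id: str
    interval: GenomicInterval
    ordinal: int
    klass: str
    inclusion: float | None = None

    @property
    def is_alternative(self) -> bool:
        return self.inclusion is not None and self.inclusion < 0


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def _merge_gene_group(gene_id: str, entries: list[tuple[str, str, GenomicInterval]]) -> GeneModel | None:
    chroms = {c for c, _, _ in entries}
    strands = {s for _, s, _ in entries}
    if len(chroms) > 1 or len(strands) > 1:
        logger.warning("gene %s spans multiple chroms/strands; skipped", gene_id)
        return None
    exons = merge_intervals(iv for _, _, iv in entries)
    if not exons:
        logger.warning("gene %s has zero exons; skipped", gene_id)
        return None
    return GeneModel(gene_id, chroms.pop(), strands.pop(), exons)


def _parse_refflat(path: Path) -> dict[str, list[tuple[str, str, GenomicInterval]]]:
    groups: dict[str, list[tuple[str, str, GenomicInterval]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(f"{path}:{lineno}: refFlat line has {len(fields)} fields, need 11")
            gene_id, _tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                n_exons = int(fields[8])
                starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
                ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(starts) != n_exons or len(ends) != n_exons:
                raise ParseError(f"{path}:{lineno}: exon count mismatch")
            if n_exons == 0:
                logger.warning("%s:%d: zero-exon record for %s; skipped", path, lineno, gene_id)
                continue
            for s, e in zip(starts, ends):
                groups.setdefault(gene_id, []).append(
                    (chrom, strand, GenomicInterval(chrom, s, e, strand))
                )
    return groups


def _parse_bed12(path: Path) -> dict[str, list[tuple[str, str, GenomicInterval]]]:
    groups: dict[str, list[tuple[str, str, GenomicInterval]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 line has {len(fields)} fields, need 12")
            try:
                chrom, chrom_start = fields[0], int(fields[1])
                gene_id, strand = fields[3], fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",") if x]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != block_count or len(offsets) != block_count:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            if block_count == 0:
                logger.warning("%s:%d: zero-block record for %s; skipped", path, lineno, gene_id)
                continue
            for size, off in zip(sizes, offsets):
                s = chrom_start + off
                groups.setdefault(gene_id, []).append(
                    (chrom, strand, GenomicInterval(chrom, s, s + size, strand))
                )
    return groups


def _parse_gtf(path: Path) -> dict[str, list[tuple[str, str, GenomicInterval]]]:
    groups: dict[str, list[tuple[str, str, GenomicInterval]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: GTF line has {len(fields)} fields, need 9")
            if fields[2] != "exon":
                continue
            chrom, strand, attrs = fields[0], fields[6], fields[8]
            try:
                # GTF is 1-based inclusive; convert to 0-based half-open.
                start = int(fields[3]) - 1
                end = int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            gene_id = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('" ')
                    break
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            groups.setdefault(gene_id, []).append(
                (chrom, strand, GenomicInterval(chrom, start, end, strand))
            )
    return groups


_PARSERS = {"refFlat": _parse_refflat, "BED12": _parse_bed12, "GTF": _parse_gtf}


def read_gene_models(path: str | Path, format: str = "refFlat") -> list[GeneModel]:
    """Parse gene models and merge isoforms into one exon union per gene_id.

    Parameters
    ----------
    path
        Annotation file.
    format
        One of ``refFlat``, ``BED12``, ``GTF``.
    """
    if format not in _PARSERS:
        raise ValueError(f"unknown annotation format {format!r}; choose from {sorted(_PARSERS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    groups = _PARSERS[format](path)
    genes = []
    for gene_id, entries in groups.items():
        gm = _merge_gene_group(gene_id, entries)
        if gm is not None:
            genes.append(gm)
    genes.sort(key=lambda g: (g.chrom, g.exons[0].start, g.gene_id))
    return genes


def read_bed6_reads(path: str | Path) -> list[GenomicInterval]:
    """Parse aligned reads from BED6; every read must carry a strand."""
    reads = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 read line has {len(fields)} fields, need 6")
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: read {fields[3]!r} has no strand")
            try:
                reads.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return reads


def read_alt_events(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Parse a KnownAlt-style table: BED6 plus an event-type column.

    Returns (interval, event_type) pairs; cassette events carry the type
    ``"cassetteExon"``.
    """
    events = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ParseError(f"{path}:{lineno}: alt-event line has {len(fields)} fields, need 7")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            events.append((iv, fields[6]))
    return events
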