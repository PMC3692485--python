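"""Length-normalized, log2-transformed chromatin and expression signals.

The quantification follows one recipe for every region class (gene exon
union, single exon, promoter window):

1. extend every aligned read to 100 bp in the direction of its strand;
2. count the reads whose extended interval overlaps the region union by at
   least one base pair, each read at most once per region;
3. divide by the region's base-pair length (genes: non-redundant exonic bp),
   add a pseudocount of 0.01, and take log2.

Promoter signals use a 4,001 bp window centered on the strand-aware TSS;
there the raw read sum is logged rather than the density, with the same
pseudocount guarding log(0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    CASSETTE_EVENT,
    ExonRecord,
    GeneModel,
    GenomicInterval,
    merge_intervals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_EXTENSION",
    "DEFAULT_PROMOTER_WINDOW",
    "extend_reads",
    "ReadIndex",
    "region_signal",
    "gene_expression",
    "exon_expression",
    "feature_signal",
    "promoter_signal",
    "classify_exons",
    "inclusion_value",
    "build_signal_matrix",
    "quantify_dataset",
    "QuantifyResult",
]

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_EXTENSION = 100
DEFAULT_PROMOTER_WINDOW = 4001


def extend_reads(
    reads: Sequence[GenomicInterval], target_len: int = DEFAULT_EXTENSION
) -> list[GenomicInterval]:
    """Extend each read to ``target_len`` bp in the direction of its strand.

    '+' reads keep their start; '-' reads keep their end.  Extended reads
    are clipped at position 0.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    out = []
    for read in reads:
        if read.strand == "+":
            out.append(GenomicInterval(read.chrom, read.start, read.start + target_len, "+"))
        elif read.strand == "-":
            start = max(0, read.end - target_len)
            out.append(GenomicInterval(read.chrom, start, read.end, "-"))
        else:
            raise ValueError(f"read without strand: {read.chrom}:{read.start}-{read.end}")
    return out


class ReadIndex:
    """Per-chromosome sorted arrays of (extended) read intervals.

    Counting reads that overlap a disjoint, start-sorted region union is a
    two-searchsorted membership test: a read [s, e) overlaps the union iff
    some union interval has start < e, and the last such interval ends past
    s (union ends are increasing because the intervals are disjoint).
    """

    def __init__(self, reads: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.n_reads = 0
        for chrom, pairs in by_chrom.items():
            arr = np.array(pairs, dtype=np.int64)
            self._starts[chrom] = np.ascontiguousarray(arr[:, 0])
            self._ends[chrom] = np.ascontiguousarray(arr[:, 1])
            self.n_reads += len(pairs)

    def count_overlapping(self, region: Sequence[GenomicInterval]) -> int:
        """Number of reads overlapping the union of ``region`` by >= 1 bp.

        Each read is counted at most once even if it spans several intervals
        of the union.
        """
        merged = merge_intervals(region)
        if not merged:
            raise ValueError("empty region")
        total = 0
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            if chrom not in self._starts:
                continue
            rs, re = self._starts[chrom], self._ends[chrom]
            iv_starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            iv_ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            idx = np.searchsorted(iv_starts, re, side="left")
            hit = idx > 0
            hit[hit] &= iv_ends[idx[hit] - 1] > rs[hit]
            total += int(hit.sum())
        return total


def _as_index(reads) -> ReadIndex:
    return reads if isinstance(reads, ReadIndex) else ReadIndex(reads)


def region_signal(
    reads,
    region: Sequence[GenomicInterval],
    region_bp: int | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """log2 length-normalized read density over a region union.

    ``reads`` must already be strand-extended (a sequence or a prebuilt
    :class:`ReadIndex`).  ``region_bp`` defaults to the union length.
    """
    merged = merge_intervals(region)
    if not merged:
        raise ValueError("empty region")
    if region_bp is None:
        region_bp = sum(iv.length for iv in merged)
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    count = _as_index(reads).count_overlapping(merged)
    return math.log2(count / region_bp + pseudocount)


def gene_expression(rna_reads, gene: GeneModel, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Expression of a gene: read density over its exonic union."""
    return region_signal(rna_reads, gene.exons, gene.exonic_bp, pseudocount)


def exon_expression(rna_reads, exon: GenomicInterval, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Expression of a single exon: read density over its interval."""
    return region_signal(rna_reads, [exon], exon.length, pseudocount)


def feature_signal(chip_reads, target, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Chromatin-feature signal on a gene (exon union) or a single exon."""
    if isinstance(target, GeneModel):
        return region_signal(chip_reads, target.exons, target.exonic_bp, pseudocount)
    return region_signal(chip_reads, [target], target.length, pseudocount)


def promoter_signal(
    chip_reads,
    gene: GeneModel,
    window_bp: int = DEFAULT_PROMOTER_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """log2 read sum in a window of ``window_bp`` bases centered on the TSS.

    The window is strand-agnostic but centered at the strand-aware TSS;
    promoter signals log the raw read count (not the density), with the
    pseudocount guarding log(0).
    """
    if window_bp % 2 != 1:
        raise ValueError("window_bp must be odd so the window centers on the TSS")
    half = (window_bp - 1) // 2
    start = max(0, gene.tss - half)
    end = gene.tss + half + 1  # inclusive rightmost base -> half-open end
    count = _as_index(chip_reads).count_overlapping([GenomicInterval(gene.chrom, start, end)])
    return math.log2(count + pseudocount)


def classify_exons(
    genes: Sequence[GeneModel],
    alt_table: Sequence[tuple[GenomicInterval, str]],
) -> list[ExonRecord]:
    """Classify internal exons as constitutive or cassette.

    First and last exons of every gene are dropped (they are dominated by
    transcription initiation/termination effects).  An internal exon whose
    coordinates match a cassette event becomes a cassette record; an exon
    matching no alternative event is constitutive; exons matching only
    non-cassette events, or conflicting event types, are excluded.
    """
    events: dict[tuple[str, int, int], set[str]] = {}
    for iv, etype in alt_table:
        events.setdefault((iv.chrom, iv.start, iv.end), set()).add(etype)

    records: list[ExonRecord] = []
    seen: set[tuple[str, int, int]] = set()
    for gene in genes:
        for ordinal, exon in enumerate(gene.exons):
            if ordinal == 0 or ordinal == len(gene.exons) - 1:
                continue
            key = (exon.chrom, exon.start, exon.end)
            if key in seen:
                continue  # duplicate coordinates across isoforms collapse
            seen.add(key)
            etypes = events.get(key, set())
            if not etypes:
                klass = "constitutive"
            elif etypes == {CASSETTE_EVENT}:
                klass = "cassette"
            else:
                if len(etypes) > 1:
                    logger.warning(
                        "exon %s:%d-%d matches conflicting event types %s; excluded",
                        exon.chrom, exon.start, exon.end, sorted(etypes),
                    )
                continue
            exon_id = f"{gene.gene_id}:exon{ordinal}"
            records.append(ExonRecord(exon_id, gene.gene_id, exon, ordinal, klass))
    return records


def inclusion_value(exon_expr: float, gene_expr: float) -> float:
    """log2 fold change of exon over gene expression (difference of log2 densities)."""
    return exon_expr - gene_expr


def build_signal_matrix(
    read_sets: Mapping[str, Sequence[GenomicInterval] | ReadIndex],
    targets: Mapping[str, Sequence[GenomicInterval]],
    region_bp: Mapping[str, int] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Signal matrix: rows = target ids, columns = feature names.

    ``read_sets`` maps feature name -> extended reads; ``targets`` maps
    row id -> region union.  Values are log2(density + pseudocount).
    """
    indexes = {name: _as_index(reads) for name, reads in read_sets.items()}
    rows = {}
    for row_id, region in targets.items():
        bp = None if region_bp is None else region_bp[row_id]
        rows[row_id] = {
            name: region_signal(idx, region, bp, pseudocount)
            for name, idx in indexes.items()
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "row_id"
    return df


@dataclass(slots=True)
class QuantifyResult:
    """Quantified signals for one dataset.

    All matrices share the same normalization: log2 length-normalized read
    density with the common pseudocount.
    """

    gene_signals: pd.DataFrame       # genes x features, exon-union densities
    exon_signals: pd.DataFrame       # internal exons x features
    promoter_signals: pd.DataFrame   # genes x features, log2 read sums
    gene_expression: pd.Series       # per-gene RNA density
    exon_expression: pd.Series       # per-exon RNA density
    inclusion: pd.Series             # exon - gene, log2
    exons: list[ExonRecord]

    @property
    def gene_of_exon(self) -> dict[str, str]:
        return {e.exon_id: e.gene_id for e in self.exons}

    def exon_set(self, klass: str) -> list[str]:
        return [e.exon_id for e in self.exons if e.klass == klass]


def quantify_dataset(
    genes: Sequence[GeneModel],
    exons: Sequence[ExonRecord],
    chip_reads: Mapping[str, Sequence[GenomicInterval]],
    rna_reads: Sequence[GenomicInterval],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    extension: int = DEFAULT_EXTENSION,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> QuantifyResult:
    """Run the full quantification: extend reads, score genes, exons, promoters.

    ``chip_reads`` and ``rna_reads`` are raw (unextended) stranded reads.
    Exon records get their inclusion values set in place.
    """
    chip_idx = {
        name: ReadIndex(extend_reads(reads, extension)) for name, reads in chip_reads.items()
    }
    rna_idx = ReadIndex(extend_reads(rna_reads, extension))
    gene_map = {g.gene_id: g for g in genes}

    gene_targets = {g.gene_id: g.exons for g in genes}
    gene_bp = {g.gene_id: g.exonic_bp for g in genes}
    gene_signals = build_signal_matrix(chip_idx, gene_targets, gene_bp, pseudocount)
    gene_expr = pd.Series(
        {g.gene_id: gene_expression(rna_idx, g, pseudocount) for g in genes},
        name="gene_expression",
    )

    exon_targets = {e.exon_id: [e.interval] for e in exons}
    exon_bp = {e.exon_id: e.interval.length for e in exons}
    exon_signals = build_signal_matrix(chip_idx, exon_targets, exon_bp, pseudocount)
    exon_expr = pd.Series(
        {e.exon_id: exon_expression(rna_idx, e.interval, pseudocount) for e in exons},
        name="exon_expression",
    )

    promoter_signals = pd.DataFrame.from_dict(
        {
            g.gene_id: {
                name: promoter_signal(idx, g, promoter_window, pseudocount)
                for name, idx in chip_idx.items()
            }
            for g in genes
        },
        orient="index",
    )
    promoter_signals.index.name = "row_id"

    inclusion = {}
    for e in exons:
        e.inclusion = inclusion_value(exon_expr[e.exon_id], gene_expr[gene_map[e.gene_id].gene_id])
        inclusion[e.exon_id] = e.inclusion

    return QuantifyResult(
        gene_signals=gene_signals,
        exon_signals=exon_signals,
        promoter_signals=promoter_signals,
        gene_expression=gene_expr,
        exon_expression=exon_expr,
        inclusion=pd.Series(inclusion, name="inclusion"),
        exons=list(exons),
    )
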