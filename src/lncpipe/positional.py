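"""Positional classification of lncRNAs relative to the nearest coding gene.

Categories: antisense_exonic (opposite-strand exon overlap), divergent /
convergent (opposite strand, lncRNA 5' / 3' of the partner in partner
orientation), upstream_sense / downstream_sense (same strand), and
intergenic_unassigned when no coding gene lies within the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from .genomics import (
    AnnotationSet,
    GenomicInterval,
    TranscriptRecord,
    interval_gap,
    overlap_length,
)

CATEGORIES = (
    "antisense_exonic",
    "divergent",
    "convergent",
    "upstream_sense",
    "downstream_sense",
    "intergenic_unassigned",
)


class SenseOverlapError(ValueError):
    """A lncRNA overlapping a coding exon in sense should have been
    filtered out before classification."""


@dataclass
class PositionalCall:
    lnc_id: str
    partner_gene_id: Optional[str]
    category: str
    distance: int  # span gap to the partner, 0 if overlapping


def _lnc_is_five_prime(lnc: TranscriptRecord, partner: GenomicInterval) -> bool:
    """Is the lncRNA on the 5' side of the partner gene, in the partner's
    orientation?  For overlapping spans the call falls back to comparing
    transcription start positions."""
    if lnc.interval.end <= partner.start:
        left = True
    elif lnc.interval.start >= partner.end:
        left = False
    else:  # spans overlap (e.g. intronic antisense): compare TSS positions
        partner_tss = partner.start if partner.strand != "-" else partner.end - 1
        left = lnc.tss < partner_tss
    return left if partner.strand != "-" else not left


def classify_position(
    lnc: TranscriptRecord,
    coding: AnnotationSet,
    max_window: int = 10_000,
) -> PositionalCall:
    """Assign a single positional category to one lncRNA transcript."""
    if len(coding) == 0:
        raise ValueError("coding annotation is empty")

    # 1) exon-level overlap checks
    best_gene = None
    best_overlap = 0
    for t in coding:
        if t.chrom != lnc.chrom:
            continue
        for ce in t.exons:
            for le in lnc.exons:
                if overlap_length(le, ce, mode="same_strand") > 0:
                    raise SenseOverlapError(
                        f"{lnc.transcript_id} overlaps coding exon of "
                        f"{t.gene_id} in sense"
                    )
                ov = overlap_length(le, ce, mode="opposite_strand")
                if ov > best_overlap:
                    best_overlap = ov
                    best_gene = t.gene_id
    if best_gene is not None:
        return PositionalCall(lnc.transcript_id, best_gene, "antisense_exonic", 0)

    # 2) nearest coding gene within the window, by span gap
    nearest: Optional[str] = None
    nearest_gap = max_window + 1
    nearest_start = None
    for gid in coding.genes:
        span = coding.gene_span(gid)
        if span.chrom != lnc.chrom:
            continue
        gap = interval_gap(lnc.interval, span)
        if gap < nearest_gap or (gap == nearest_gap and (
            nearest_start is None or span.start < nearest_start
        )):
            if gap <= max_window:
                nearest, nearest_gap, nearest_start = gid, gap, span.start
    if nearest is None:
        return PositionalCall(lnc.transcript_id, None, "intergenic_unassigned", 0)

    span = coding.gene_span(nearest)
    five_prime = _lnc_is_five_prime(lnc, span)
    if lnc.strand == span.strand:
        category = "upstream_sense" if five_prime else "downstream_sense"
    else:
        category = "divergent" if five_prime else "convergent"
    return PositionalCall(lnc.transcript_id, nearest, category, nearest_gap)


def classify_all(
    lncs: AnnotationSet, coding: AnnotationSet, max_window: int = 10_000
) -> List[PositionalCall]:
    return [classify_position(t, coding, max_window) for t in lncs]


def category_counts(calls: List[PositionalCall]) -> Dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    return counts
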