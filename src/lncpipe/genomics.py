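"""Genomic data model, coordinate arithmetic and standard-format I/O.

Internal coordinates are 0-based, half-open throughout.  GTF input/output
converts to and from the 1-based inclusive convention of that format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class GtfParseError(ValueError):
    """Raised when a GTF/GFF line cannot be interpreted."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (N preserved, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: GenomicInterval, b: GenomicInterval, mode: str = "any") -> int:
    """Number of overlapping bases between two intervals.

    mode: 'same_strand' requires equal strands, 'opposite_strand' requires
    '+' vs '-', 'any' ignores strand.  Returns 0 on different chromosomes,
    unmet strand condition, or disjoint intervals.
    """
    if a.chrom != b.chrom:
        return 0
    if mode == "same_strand":
        if a.strand != b.strand:
            return 0
    elif mode == "opposite_strand":
        if {a.strand, b.strand} != {"+", "-"}:
            return 0
    elif mode != "any":
        raise ValueError(f"unknown overlap mode {mode!r}")
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap in bases between two intervals on the same chromosome (0 if they
    overlap or abut)."""
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass
class TranscriptRecord:
    """One transcript: span, ordered exons, and a biotype tag."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: List[GenomicInterval]
    biotype: str = "novel"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon chrom/strand differs from span"
                )
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"{self.transcript_id}: exon outside span")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start, as a 0-based base position."""
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @classmethod
    def from_exons(
        cls,
        transcript_id: str,
        gene_id: str,
        exons: Sequence[GenomicInterval],
        biotype: str = "novel",
    ) -> "TranscriptRecord":
        exons = sorted(exons, key=lambda e: e.start)
        span = GenomicInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
        )
        return cls(transcript_id, gene_id, span, list(exons), biotype)


@dataclass
class AnnotationSet:
    """A collection of transcripts indexed by gene, plus chromosome lengths."""

    transcripts: List[TranscriptRecord] = field(default_factory=list)
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {t.transcript_id: t for t in self.transcripts}
        if self.chrom_lengths:
            for t in self.transcripts:
                if t.chrom not in self.chrom_lengths:
                    raise ValueError(f"no length for chromosome {t.chrom!r}")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def get(self, transcript_id: str) -> TranscriptRecord:
        return self._by_id[transcript_id]

    @property
    def genes(self) -> Dict[str, List[TranscriptRecord]]:
        out: Dict[str, List[TranscriptRecord]] = {}
        for t in self.transcripts:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def gene_span(self, gene_id: str) -> GenomicInterval:
        """Hull of all transcripts of a gene."""
        ts = self.genes[gene_id]
        return GenomicInterval(
            ts[0].chrom,
            min(t.interval.start for t in ts),
            max(t.interval.end for t in ts),
            ts[0].strand,
        )

    def subset(self, biotypes: Iterable[str]) -> "AnnotationSet":
        wanted = set(biotypes)
        return AnnotationSet(
            [t for t in self.transcripts if t.biotype in wanted],
            dict(self.chrom_lengths),
        )

    def add(self, t: TranscriptRecord) -> None:
        if self.chrom_lengths and t.chrom not in self.chrom_lengths:
            raise ValueError(f"no length for chromosome {t.chrom!r}")
        self.transcripts.append(t)
        self._by_id[t.transcript_id] = t


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(raw: str, lineno: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_annotation(
    path: str,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    default_biotype: str = "novel",
) -> AnnotationSet:
    """Read a GTF file into an AnnotationSet.

    Exon features are grouped per transcript_id; the transcript span is the
    hull of its exons.  1-based inclusive GTF coordinates become 0-based
    half-open.  A ``gene_biotype`` or ``transcript_biotype`` attribute is
    honoured when present; otherwise ``default_biotype`` is used.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    gene_of: Dict[str, str] = {}
    biotype_of: Dict[str, str] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, raw = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: bad coordinates") from exc
            if strand not in STRANDS:
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            attrs = _parse_gtf_attributes(raw, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon lacks transcript_id")
            tid = attrs["transcript_id"]
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            exons[tid].append(GenomicInterval(chrom, start_i - 1, end_i, strand))
            gene_of[tid] = attrs.get("gene_id", tid)
            bt = attrs.get("transcript_biotype") or attrs.get("gene_biotype")
            if bt:
                biotype_of[tid] = bt
    transcripts = [
        TranscriptRecord.from_exons(
            tid, gene_of[tid], exons[tid], biotype_of.get(tid, default_biotype)
        )
        for tid in order
    ]
    return AnnotationSet(transcripts, dict(chrom_lengths or {}))


def write_annotation(annotation: AnnotationSet, path: str, source: str = "lncpipe") -> None:
    """Write transcripts as GTF (transcript + exon features, 1-based)."""
    with open(path, "w") as fh:
        for t in annotation:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            iv = t.interval
            fh.write(
                f"{iv.chrom}\t{source}\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


def write_bed6(intervals: Iterable[Tuple[GenomicInterval, str, float]], path: str) -> None:
    """Write (interval, name, score) triples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> Dict[str, str]:
    """Read a (multi-record, possibly line-wrapped) FASTA into a dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_transcript_sequence(t: TranscriptRecord, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence in 5'->3' transcript orientation."""
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} absent from genome")
    chrom_seq = genome[t.chrom]
    for e in t.exons:
        if e.end > len(chrom_seq):
            raise ValueError(
                f"{t.transcript_id}: exon {e.start}-{e.end} beyond end of "
                f"{t.chrom} (length {len(chrom_seq)})"
            )
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# Neighbour search
# ---------------------------------------------------------------------------

def nearest_neighbors(
    query: TranscriptRecord,
    targets: AnnotationSet,
    window: int,
    by_gene: bool = True,
) -> List[Tuple[str, int]]:
    """Targets whose span lies within ``window`` bases of the query span.

    Distance is the gap between spans (0 when overlapping), signed negative
    when the target lies upstream (lower genomic coordinates) of the query.
    Sorted by |distance|, ties by target start coordinate.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    spans: List[Tuple[str, GenomicInterval]]
    if by_gene:
        spans = [(gid, targets.gene_span(gid)) for gid in targets.genes]
    else:
        spans = [(t.transcript_id, t.interval) for t in targets]
    hits: List[Tuple[str, int, int]] = []
    q = query.interval
    for name, span in spans:
        if span.chrom != q.chrom:
            continue
        gap = interval_gap(q, span)
        if gap > window:
            continue
        signed = gap if span.start >= q.start else -gap
        hits.append((name, signed, span.start))
    hits.sort(key=lambda h: (abs(h[1]), h[2]))
    return [(name, signed) for name, signed, _ in hits]
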