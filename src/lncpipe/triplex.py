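"""RNA-DNA triplex prediction: TFO tracts in lncRNAs, TTS tracts in genomic
duplex DNA, TFO/TTS matching under the three canonical triplex motifs, and
hierarchical genomic-context assignment of target sites.

Motif alphabets and pairing rules (TFO base <-> TTS purine-strand base):

====== ============= ============ ===========
motif  TFO alphabet  orientation  pairing
====== ============= ============ ===========
R      G, A          antiparallel G<->G, A<->A
Y      C, T/U        parallel     C<->G, T<->A
M      G, T/U        antiparallel G<->G, T<->A
====== ============= ============ ===========

A *tract* (and a match window) is valid when: length >= ``min_length``;
errors / length <= ``max_error_rate``; no run of more than
``max_consecutive_errors`` errors; guanine fraction >= ``min_guanine``;
and it neither starts nor ends with an error.  Reported tracts/matches are
maximal (not contained in a longer valid window); when
``merge_overlapping`` is set, overlapping windows of the same motif are
reduced to their best representative (longest, then fewest errors, then
left-most).

Guanine fraction is measured on the TTS purine strand; for a free TFO
tract it is the fraction of positions that would occupy a G.C pair
(G for the R and M motifs, C for the Y motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genomics import (
    AnnotationSet,
    GenomicInterval,
    TranscriptRecord,
    extract_transcript_sequence,
    reverse_complement,
)

MOTIFS = ("R", "Y", "M")

# TFO alphabet membership and the TFO base that counts toward guanine
_TFO_ALPHABET = {"R": set("GA"), "Y": set("CTU"), "M": set("GTU")}
_TFO_G_EQUIV = {"R": set("G"), "Y": set("C"), "M": set("G")}
# pairing rule: motif -> {tfo_base: tts_purine_base}
PAIRING = {
    "R": {"G": "G", "A": "A"},
    "Y": {"C": "G", "T": "A", "U": "A"},
    "M": {"G": "G", "T": "A", "U": "A"},
}
ANTIPARALLEL = {"R": True, "Y": False, "M": True}

CONTEXT_CLASSES = ("intergenic", "intron", "exon", "promoter")  # ascending priority


@dataclass
class TriplexParams:
    min_length: int = 20
    max_error_rate: float = 0.05
    max_consecutive_errors: int = 2
    min_guanine: float = 0.20
    merge_overlapping: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.max_error_rate < 1):
            raise ValueError("max_error_rate must be in (0, 1)")
        if self.min_length < 10:
            raise ValueError("min_length must be >= 10")


@dataclass(frozen=True)
class Tract:
    """A candidate TFO or TTS tract on one sequence.

    ``motif`` is R/Y/M for TFOs; for TTS tracts it records the purine
    strand as '+' (the scanned strand) or '-' (its complement).
    """

    seq_id: str
    start: int
    end: int
    motif: str
    errors: int
    guanine: float
    sequence: str  # TFO: tract 5'->3'; TTS: purine strand 5'->3'


@dataclass
class TriplexInteraction:
    lnc_id: str
    tfo_start: int
    tfo_end: int
    motif: str
    tts: GenomicInterval  # strand field = purine strand
    length: int
    errors: int
    guanine: float
    context: Optional[str] = None
    linked_genes: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# window enumeration
# ---------------------------------------------------------------------------

def _valid_windows(
    err: np.ndarray, gua: np.ndarray, params: TriplexParams
) -> List[Tuple[int, int, int, float]]:
    """All maximal valid windows over an error mask.

    ``err``/``gua`` are 0/1 arrays.  Returns (start, end, n_errors,
    guanine_fraction) tuples.  Windows cannot contain an error run longer
    than ``max_consecutive_errors``, so the sequence is first cut into
    blocks at longer runs; windows are enumerated per block from
    non-error boundary positions.
    """
    n = len(err)
    if n < params.min_length:
        return []
    err_prefix = np.concatenate(([0], np.cumsum(err)))
    gua_prefix = np.concatenate(([0], np.cumsum(gua)))

    # cut at runs of > max_consecutive_errors errors
    blocks: List[Tuple[int, int]] = []
    run = 0
    block_start = 0
    for i in range(n):
        if err[i]:
            run += 1
            if run == params.max_consecutive_errors + 1:
                # block ends before this run began
                blocks.append((block_start, i - params.max_consecutive_errors))
        else:
            if run > params.max_consecutive_errors:
                block_start = i
            run = 0
    if run <= params.max_consecutive_errors:
        blocks.append((block_start, n))

    windows: List[Tuple[int, int, int, float]] = []
    for b0, b1 in blocks:
        if b1 - b0 < params.min_length:
            continue
        anchors = [i for i in range(b0, b1) if not err[i]]
        for ai, i in enumerate(anchors):
            for j in reversed(anchors[ai:]):
                length = j - i + 1
                if length < params.min_length:
                    break
                e = int(err_prefix[j + 1] - err_prefix[i])
                if e / length > params.max_error_rate:
                    continue
                g = (gua_prefix[j + 1] - gua_prefix[i]) / length
                if g < params.min_guanine:
                    continue
                windows.append((i, j + 1, e, g))
                break  # longest valid window from this start; shorter ones non-maximal
    # drop windows contained in a longer valid window (different starts)
    windows.sort(key=lambda w: (w[0], -w[1]))
    maximal: List[Tuple[int, int, int, float]] = []
    best_end = -1
    for w in windows:
        if w[1] > best_end:
            maximal.append(w)
            best_end = w[1]
    return maximal


def _merge_overlapping(
    windows: List[Tuple[int, int, int, float]]
) -> List[Tuple[int, int, int, float]]:
    """Reduce each group of mutually overlapping windows to its best
    representative (longest, then fewest errors, then left-most)."""
    if not windows:
        return []
    windows = sorted(windows, key=lambda w: (w[0], w[1]))
    groups: List[List[Tuple[int, int, int, float]]] = [[windows[0]]]
    cur_end = windows[0][1]
    for w in windows[1:]:
        if w[0] < cur_end:
            groups[-1].append(w)
            cur_end = max(cur_end, w[1])
        else:
            groups.append([w])
            cur_end = w[1]
    return [
        min(g, key=lambda w: (-(w[1] - w[0]), w[2], w[0]))
        for g in groups
    ]


# ---------------------------------------------------------------------------
# tract search
# ---------------------------------------------------------------------------

def find_tracts(
    seq: str,
    params: TriplexParams,
    kind: str,
    seq_id: str = "seq",
) -> List[Tract]:
    """Candidate TFO tracts on an RNA, or TTS tracts on duplex DNA.

    kind='TFO_on_rna': one search per motif alphabet (R, Y, M); positions
    outside the alphabet are errors.
    kind='TTS_on_duplex': purine tracts on either strand of the duplex;
    errors are pyrimidine interruptions on the purine strand.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    arr = np.frombuffer(s.encode(), dtype="S1")
    out: List[Tract] = []
    if kind == "TFO_on_rna":
        for motif in MOTIFS:
            alpha = _TFO_ALPHABET[motif]
            err = (~np.isin(arr, [a.encode() for a in alpha])).astype(np.int64)
            gua = np.isin(arr, [a.encode() for a in _TFO_G_EQUIV[motif]]).astype(np.int64)
            windows = _valid_windows(err, gua, params)
            if params.merge_overlapping:
                windows = _merge_overlapping(windows)
            for i, j, e, g in windows:
                out.append(Tract(seq_id, i, j, motif, e, g, s[i:j]))
    elif kind == "TTS_on_duplex":
        for purine_strand in ("+", "-"):
            if purine_strand == "+":
                err = (~np.isin(arr, [b"A", b"G"])).astype(np.int64)
                gua = (arr == b"G").astype(np.int64)
            else:
                # purine strand is the complement: C/T here are its G/A
                err = (~np.isin(arr, [b"C", b"T"])).astype(np.int64)
                gua = (arr == b"C").astype(np.int64)
            windows = _valid_windows(err, gua, params)
            if params.merge_overlapping:
                windows = _merge_overlapping(windows)
            for i, j, e, g in windows:
                sub = s[i:j]
                purine_seq = sub if purine_strand == "+" else reverse_complement(sub)
                out.append(Tract(seq_id, i, j, purine_strand, e, g, purine_seq))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    out.sort(key=lambda t: (t.start, t.end, t.motif))
    return out


# ---------------------------------------------------------------------------
# TFO / TTS matching
# ---------------------------------------------------------------------------

def _diagonal_matches(
    tfo_seq: str, tts_purine: str, motif: str, params: TriplexParams
) -> List[Tuple[int, int, int, float]]:
    """Maximal valid alignment windows of a TFO against a TTS purine
    strand, all offsets.  Returned coordinates are on the TTS purine
    strand; TFO coordinates follow from the diagonal and orientation."""
    rule = PAIRING[motif]
    tfo = tfo_seq.upper().replace("U", "T")
    if ANTIPARALLEL[motif]:
        tfo = tfo[::-1]
    L, M_ = len(tfo), len(tts_purine)
    results: List[Tuple[int, int, int, float]] = []  # (tts_start, tts_end, errors, gua)
    for offset in range(-(L - params.min_length), M_ - params.min_length + 1):
        lo = max(0, offset)
        hi = min(M_, offset + L)
        if hi - lo < params.min_length:
            continue
        err = np.empty(hi - lo, dtype=np.int64)
        gua = np.empty(hi - lo, dtype=np.int64)
        for k in range(lo, hi):
            tb = tfo[k - offset]
            db = tts_purine[k]
            err[k - lo] = 0 if rule.get(tb) == db else 1
            gua[k - lo] = 1 if db == "G" else 0
        for i, j, e, g in _valid_windows(err, gua, params):
            results.append((lo + i, lo + j, e, g, offset))
    return results


def match_triplexes(
    tfos: Sequence[Tract],
    ttss: Sequence[Tract],
    params: TriplexParams,
    tts_meta: Optional[Mapping[int, Tuple[str, int]]] = None,
) -> List[TriplexInteraction]:
    """Report every TFO/TTS alignment satisfying the triplex constraints.

    ``tts_meta`` maps TTS tract index -> (chrom, genome offset of tract
    position 0 on the scanned strand); defaults to the tract's own
    coordinates on its source sequence.
    """
    out: List[TriplexInteraction] = []
    for ti, tts in enumerate(ttss):
        chrom, base = (
            tts_meta[ti] if tts_meta is not None else (tts.seq_id, tts.start)
        )
        tts_len = tts.end - tts.start
        for tfo in tfos:
            if tfo.motif not in MOTIFS:
                raise ValueError(f"TFO tract has non-motif label {tfo.motif!r}")
            cands = _diagonal_matches(tfo.sequence, tts.sequence, tfo.motif, params)
            matches = []
            for ps, pe, e, g, offset in cands:
                # map purine-strand window back to scanned-strand genome coords
                if tts.motif == "-":
                    gs = base + (tts_len - pe)
                    ge = base + (tts_len - ps)
                else:
                    gs = base + ps
                    ge = base + pe
                # TFO window on the (possibly reversed) tfo sequence
                fs = ps - offset
                fe = pe - offset
                if ANTIPARALLEL[tfo.motif]:
                    L = len(tfo.sequence)
                    fs, fe = L - fe, L - fs
                matches.append(
                    (
                        gs,
                        ge,
                        e,
                        g,
                        tfo.start + fs,
                        tfo.start + fe,
                    )
                )
            if params.merge_overlapping and matches:
                matches = _merge_match_group(matches)
            for gs, ge, e, g, fs, fe in matches:
                out.append(
                    TriplexInteraction(
                        lnc_id=tfo.seq_id,
                        tfo_start=fs,
                        tfo_end=fe,
                        motif=tfo.motif,
                        tts=GenomicInterval(chrom, gs, ge, tts.motif if tts.motif in "+-" else "+"),
                        length=ge - gs,
                        errors=e,
                        guanine=g,
                    )
                )
    out.sort(key=lambda x: (x.tts.chrom, x.tts.start, x.tts.end, x.lnc_id, x.tfo_start))
    return out


def _merge_match_group(matches: List[tuple]) -> List[tuple]:
    """Collapse matches overlapping on both the TTS and TFO axes to the
    best representative (longest, fewest errors, left-most on TTS)."""
    remaining = sorted(matches, key=lambda m: (-(m[1] - m[0]), m[2], m[0], m[4]))
    kept: List[tuple] = []
    for m in remaining:
        redundant = False
        for k in kept:
            if m[0] < k[1] and k[0] < m[1] and m[4] < k[5] and k[4] < m[5]:
                redundant = True
                break
        if not redundant:
            kept.append(m)
    kept.sort(key=lambda m: (m[0], m[1], m[4]))
    return kept


def scan_genome(
    lncs: AnnotationSet,
    genome: Mapping[str, str],
    params: Optional[TriplexParams] = None,
) -> List[TriplexInteraction]:
    """Full search: TFO tracts in every lncRNA transcript sequence vs TTS
    tracts on every chromosome."""
    params = params or TriplexParams()
    tfos: List[Tract] = []
    for t in lncs:
        seq = extract_transcript_sequence(t, genome)
        tfos.extend(find_tracts(seq, params, "TFO_on_rna", seq_id=t.transcript_id))
    interactions: List[TriplexInteraction] = []
    for chrom, seq in genome.items():
        ttss = find_tracts(seq, params, "TTS_on_duplex", seq_id=chrom)
        meta = {i: (chrom, tr.start) for i, tr in enumerate(ttss)}
        interactions.extend(match_triplexes(tfos, ttss, params, tts_meta=meta))
    interactions.sort(
        key=lambda x: (x.tts.chrom, x.tts.start, x.tts.end, x.lnc_id, x.tfo_start)
    )
    return interactions


# ---------------------------------------------------------------------------
# genome context
# ---------------------------------------------------------------------------

@dataclass
class GenomeContextMap:
    """Strand-independent partition of every genomic base into exactly one
    of intergenic < intron < exon < promoter (ascending priority)."""

    classes: Dict[str, np.ndarray]  # chrom -> int8 array of class codes
    promoter_def: Tuple[int, int]

    def label_at(self, chrom: str, pos: int) -> str:
        return CONTEXT_CLASSES[self.classes[chrom][pos]]

    def fractions(self) -> Dict[str, float]:
        counts = np.zeros(len(CONTEXT_CLASSES), dtype=np.int64)
        for arr in self.classes.values():
            counts += np.bincount(arr, minlength=len(CONTEXT_CLASSES))
        total = counts.sum()
        return {c: counts[i] / total for i, c in enumerate(CONTEXT_CLASSES)}


def promoter_window(t: TranscriptRecord, upstream: int, downstream: int, chrom_len: int) -> Optional[GenomicInterval]:
    """Promoter window around a transcript's transcription start, clipped
    to the chromosome.  Covers ``upstream`` bases before the TSS and
    ``downstream`` bases from the TSS onward, in transcript orientation."""
    if t.strand == "-":
        start = t.interval.end - downstream
        end = t.interval.end + upstream
    else:
        start = t.interval.start - upstream
        end = t.interval.start + downstream
    start = max(0, start)
    end = min(chrom_len, end)
    if start >= end:
        return None
    return GenomicInterval(t.chrom, start, end, ".")


def classify_genome_context(
    annotation: AnnotationSet,
    promoter_def: Tuple[int, int] = (1000, 250),
) -> GenomeContextMap:
    """Priority-based per-base classification of the genome.

    Promoters are (upstream, downstream) windows around every transcript's
    transcription start; exons and transcript spans (introns) come from
    the annotation; everything else is intergenic.
    """
    if not annotation.chrom_lengths:
        raise ValueError("annotation must carry chromosome lengths")
    classes = {
        chrom: np.zeros(length, dtype=np.int8)
        for chrom, length in annotation.chrom_lengths.items()
    }
    intron, exon, promoter = 1, 2, 3
    for t in annotation:
        if t.chrom not in classes:
            raise ValueError(f"transcript {t.transcript_id} on unknown chrom {t.chrom}")
        arr = classes[t.chrom]
        span = t.interval
        np.maximum(arr[span.start : span.end], intron, out=arr[span.start : span.end])
        for e in t.exons:
            np.maximum(arr[e.start : e.end], exon, out=arr[e.start : e.end])
    for t in annotation:
        arr = classes[t.chrom]
        win = promoter_window(t, *promoter_def, len(arr))
        if win is not None:
            arr[win.start : win.end] = promoter
    return GenomeContextMap(classes, promoter_def)


def assign_interaction_context(
    interactions: Iterable[TriplexInteraction], context_map: GenomeContextMap
) -> List[TriplexInteraction]:
    """Label each interaction with the single highest-priority class its
    TTS overlaps."""
    out = []
    for x in interactions:
        arr = context_map.classes.get(x.tts.chrom)
        if arr is None or x.tts.end > len(arr):
            raise ValueError(f"TTS {x.tts} outside genome")
        cls = int(arr[x.tts.start : x.tts.end].max())
        out.append(replace(x, context=CONTEXT_CLASSES[cls]))
    return out


# ---------------------------------------------------------------------------
# interaction pairs
# ---------------------------------------------------------------------------

def interaction_pairs(
    interactions: Sequence[TriplexInteraction],
    annotation: AnnotationSet,
    promoter_def: Tuple[int, int] = (1500, 250),
) -> Dict[str, pd.DataFrame]:
    """Unique (lncRNA, gene) pairs per scope.

    Scopes: 'promoter' (TTS overlaps the gene's promoter windows),
    'exon' (TTS overlaps a gene exon) and 'gene_promoter' (TTS overlaps
    the gene span or its promoter).  Each frame has columns lnc_id,
    gene_id, n_interactions.
    """
    chrom_lengths = annotation.chrom_lengths
    gene_regions: Dict[str, Dict[str, List[GenomicInterval]]] = {
        "promoter": {},
        "exon": {},
        "gene": {},
    }
    for gid, transcripts in annotation.genes.items():
        proms, exons, spans = [], [], []
        for t in transcripts:
            clen = chrom_lengths.get(t.chrom, 10**12)
            win = promoter_window(t, *promoter_def, clen)
            if win is not None:
                proms.append(win)
            exons.extend(e for e in t.exons)
            spans.append(t.interval)
        gene_regions["promoter"][gid] = proms
        gene_regions["exon"][gid] = exons
        gene_regions["gene"][gid] = spans

    def _overlaps(tts: GenomicInterval, regions: List[GenomicInterval]) -> bool:
        return any(
            r.chrom == tts.chrom and r.start < tts.end and tts.start < r.end
            for r in regions
        )

    scopes = {
        "promoter": lambda gid, tts: _overlaps(tts, gene_regions["promoter"][gid]),
        "exon": lambda gid, tts: _overlaps(tts, gene_regions["exon"][gid]),
        "gene_promoter": lambda gid, tts: (
            _overlaps(tts, gene_regions["gene"][gid])
            or _overlaps(tts, gene_regions["promoter"][gid])
        ),
    }
    out: Dict[str, pd.DataFrame] = {}
    for scope, pred in scopes.items():
        counts: Dict[Tuple[str, str], int] = {}
        for x in interactions:
            for gid in annotation.genes:
                if pred(gid, x.tts):
                    counts[(x.lnc_id, gid)] = counts.get((x.lnc_id, gid), 0) + 1
        rows = [
            {"lnc_id": k[0], "gene_id": k[1], "n_interactions": v}
            for k, v in sorted(counts.items())
        ]
        out[scope] = pd.DataFrame(rows, columns=["lnc_id", "gene_id", "n_interactions"])
    return out


def interactions_to_frame(interactions: Sequence[TriplexInteraction]) -> pd.DataFrame:
    rows = []
    for x in interactions:
        rows.append(
            {
                "lnc_id": x.lnc_id,
                "tfo_start": x.tfo_start,
                "tfo_end": x.tfo_end,
                "motif": x.motif,
                "chrom": x.tts.chrom,
                "tts_start": x.tts.start,
                "tts_end": x.tts.end,
                "purine_strand": x.tts.strand,
                "length": x.length,
                "errors": x.errors,
                "guanine": x.guanine,
                "context": x.context,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lnc_id", "tfo_start", "tfo_end", "motif", "chrom", "tts_start",
            "tts_end", "purine_strand", "length", "errors", "guanine", "context",
        ],
    )
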