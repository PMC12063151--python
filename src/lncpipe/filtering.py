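"""Candidate-transcript filter cascade with per-filter bookkeeping.

Each filter returns a ``{transcript_id: bool}`` flag map (True = survives);
``intersect_filters`` combines them into a :class:`FilterReport` whose
retained set is the conjunction of all flags, independent of filter order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set

import numpy as np
import pandas as pd

from .genomics import AnnotationSet, overlap_length

FILTER_NAMES = (
    "length_ok",
    "no_sense_overlap",
    "noncoding_vote",
    "known_rna_ok",
    "domain_ok",
    "expressed",
)

HIT_CLASSES = ("RFAM", "RNAcentral", "SWISSPROT", "PFAM")


@dataclass
class HitPolicy:
    """Thresholds for the external-hit exclusion filters."""

    rfam_max_evalue: float = 1e-5
    rnacentral_min_identity: float = 90.0
    rnacentral_max_evalue: float = 1e-5
    protein_max_evalue: float = 1e-5
    strict_protein: bool = False  # exclude on SWISSPROT/PFAM hits when True
    descriptive_min_coverage: float = 50.0
    descriptive_max_evalue: float = 1e-2
    whitelist: Set[str] = field(default_factory=set)


@dataclass
class FilterReport:
    """Per-transcript flags for every filter stage plus the retained set."""

    flags: pd.DataFrame  # index transcript_id, columns FILTER_NAMES (bool)

    def __post_init__(self) -> None:
        missing = [c for c in FILTER_NAMES if c not in self.flags.columns]
        if missing:
            raise ValueError(f"missing filter columns: {missing}")
        self.flags = self.flags[list(FILTER_NAMES)].astype(bool)

    @property
    def retained(self) -> pd.Series:
        return self.flags.all(axis=1)

    @property
    def retained_ids(self) -> List[str]:
        return list(self.flags.index[self.retained])

    def sole_removals(self) -> pd.Series:
        """Per filter: transcripts that only this filter removes."""
        fails = ~self.flags
        sole = {}
        for col in FILTER_NAMES:
            others = fails.drop(columns=col).any(axis=1)
            sole[col] = int((fails[col] & ~others).sum())
        return pd.Series(sole)

    def to_frame(self) -> pd.DataFrame:
        out = self.flags.copy()
        out["retained"] = self.retained
        return out


def filter_length(
    candidates: AnnotationSet, min_len: int = 200
) -> Dict[str, bool]:
    """True iff the spliced (exon-sum) length is >= ``min_len``."""
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    return {t.transcript_id: t.spliced_length >= min_len for t in candidates}


def filter_sense_exon_overlap(
    candidates: AnnotationSet, reference: AnnotationSet
) -> Dict[str, bool]:
    """False iff any candidate exon overlaps a reference exon on the same
    strand by >= 1 base.  Opposite-strand (antisense) overlap passes."""
    if len(reference) == 0:
        raise ValueError("reference annotation is empty")
    # bucket reference exons per (chrom, strand) for a linear sweep
    ref_exons: Dict[tuple, list] = {}
    for t in reference:
        for e in t.exons:
            ref_exons.setdefault((e.chrom, e.strand), []).append(e)
    for key in ref_exons:
        ref_exons[key].sort(key=lambda e: e.start)
    flags: Dict[str, bool] = {}
    for t in candidates:
        clash = False
        for e in t.exons:
            for r in ref_exons.get((e.chrom, e.strand), ()):
                if r.start >= e.end:
                    break
                if overlap_length(e, r, mode="same_strand") > 0:
                    clash = True
                    break
            if clash:
                break
        flags[t.transcript_id] = not clash
    return flags


def compute_tpm(counts: pd.DataFrame, lengths: Mapping[str, float]) -> pd.DataFrame:
    """Transcripts-per-million from a transcripts x samples count matrix.

    TPM_ij = (count_ij / length_i) / sum_k(count_kj / length_k) * 1e6.
    Columns with no counts at all come back as zeros with a warning.
    """
    lens = pd.Series({t: float(lengths[t]) for t in counts.index})
    if (lens <= 0).any():
        raise ValueError("all effective lengths must be > 0")
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lens, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(
            f"samples with all-zero counts: {list(colsum.index[zero_cols])}",
            stacklevel=2,
        )
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1) * 1e6
    return tpm.fillna(0.0)


def filter_expression(
    tpm: pd.DataFrame, min_tpm: float = 1.0, min_samples: int = 1
) -> Dict[str, bool]:
    """True iff TPM strictly exceeds ``min_tpm`` in >= ``min_samples``
    samples."""
    if (tpm.values < 0).any():
        raise ValueError("TPM must be non-negative")
    ok = (tpm > min_tpm).sum(axis=1) >= min_samples
    return ok.to_dict()


def apply_hits_filters(
    hits: pd.DataFrame,
    candidates: Iterable[str],
    policy: Optional[HitPolicy] = None,
) -> tuple:
    """Known-RNA / protein-domain filters from an external hit table.

    ``hits`` columns: query_id, subject_id, subject_class, identity, evalue,
    coverage.  Returns ``(known_rna_ok, domain_ok, annotations)`` where the
    first two are flag maps over all candidates and ``annotations`` is a
    DataFrame of retained-hit descriptions: significant protein hits plus a
    descriptive pass at relaxed thresholds (coverage > 50 %, E < 1e-2) that
    never filters anything.
    """
    policy = policy or HitPolicy()
    candidates = list(candidates)
    required = {"query_id", "subject_id", "subject_class", "identity", "evalue", "coverage"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table lacks columns: {sorted(missing)}")
    bad = set(hits["subject_class"]) - set(HIT_CLASSES)
    if bad:
        raise ValueError(f"unknown subject_class values: {sorted(bad)}")

    known_rna_ok = {q: True for q in candidates}
    domain_ok = {q: True for q in candidates}
    notes = []
    for row in hits.itertuples(index=False):
        q = row.query_id
        if q not in known_rna_ok:
            continue
        cls = row.subject_class
        excluded = False
        if cls == "RFAM" and row.evalue < policy.rfam_max_evalue:
            excluded = True
        elif (
            cls == "RNAcentral"
            and row.identity > policy.rnacentral_min_identity
            and row.evalue < policy.rnacentral_max_evalue
        ):
            excluded = True
        if excluded and q not in policy.whitelist:
            known_rna_ok[q] = False
        if cls in ("SWISSPROT", "PFAM") and row.evalue < policy.protein_max_evalue:
            notes.append((q, row.subject_id, cls, "significant_protein_hit"))
            if policy.strict_protein:
                domain_ok[q] = False
        if (
            row.coverage > policy.descriptive_min_coverage
            and row.evalue < policy.descriptive_max_evalue
        ):
            notes.append((q, row.subject_id, cls, "descriptive_hit"))
    annotations = pd.DataFrame(
        notes, columns=["query_id", "subject_id", "subject_class", "note"]
    )
    return known_rna_ok, domain_ok, annotations


def intersect_filters(flag_maps: Mapping[str, Mapping[str, bool]]) -> FilterReport:
    """Combine per-filter flag maps into a FilterReport.

    All maps must cover exactly the same transcript set; missing filters
    default to all-True columns.
    """
    ids: Optional[Set[str]] = None
    for name, flags in flag_maps.items():
        if name not in FILTER_NAMES:
            raise ValueError(f"unknown filter name {name!r}")
        if ids is None:
            ids = set(flags)
        elif set(flags) != ids:
            raise ValueError(f"filter {name!r} covers a different transcript set")
    if ids is None:
        raise ValueError("no filters supplied")
    index = sorted(ids)
    data = {}
    for name in FILTER_NAMES:
        if name in flag_maps:
            data[name] = [bool(flag_maps[name][i]) for i in index]
        else:
            data[name] = [True] * len(index)
    return FilterReport(pd.DataFrame(data, index=pd.Index(index, name="transcript_id")))
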