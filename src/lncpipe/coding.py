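"""Transparent coding-potential scoring and benchmarking.

A deliberately simple, auditable classifier built from three classic
signals — longest ORF, Fickett TESTCODE statistic and a hexamer-usage
log-likelihood ratio — combined by an all-must-agree "noncoding" vote that
also accepts label columns from external tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

STOP_CODONS = {"TAA", "TAG", "TGA"}

# --------------------------------------------------------------------------
# ORF search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Orf:
    start: int  # 0-based, position of the A of ATG
    end: int    # exclusive, includes the stop codon
    aa_length: int  # peptide length excluding the stop


@dataclass
class CodingFeatures:
    longest_orf: Optional[Orf]
    orf_coverage: float
    fickett: float
    hexamer: float


def find_longest_orf(seq: str, min_aa: int = 100) -> Optional[Orf]:
    """Longest ATG-initiated, stop-terminated ORF on the sense strand.

    Searches all three frames; the peptide must be strictly longer than
    ``min_aa`` residues.  Ties go to the 5'-most start.
    """
    seq = seq.upper().replace("U", "T")
    best: Optional[Orf] = None
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                aa = (i - start) // 3  # includes the initiator Met
                cand = Orf(start, i + 3, aa)
                if best is None or aa > best.aa_length or (
                    aa == best.aa_length and cand.start < best.start
                ):
                    best = cand
                start = None
    if best is not None and best.aa_length > min_aa:
        return best
    return None


# --------------------------------------------------------------------------
# Fickett TESTCODE
# --------------------------------------------------------------------------
# Published lookup tables of the TESTCODE statistic: per-base positional
# asymmetry and composition intervals mapped to coding probabilities, then
# combined with per-base weights.

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.61, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for thr, prob in zip(thresholds, probs):
        if value >= thr:
            return prob
    return probs[-1]


def fickett_score(seq: str, warn_short: bool = True) -> float:
    """Fickett TESTCODE score of a nucleotide sequence.

    Ns (and any non-ACGT letter) are ignored in the tallies.  Case
    insensitive; deterministic.
    """
    seq = seq.upper().replace("U", "T")
    if warn_short and len(seq) < 200:
        warnings.warn("fickett_score on a sequence < 200 nt", stacklevel=2)
    total = 0
    pos_counts = {b: [0, 0, 0] for b in "ACGT"}
    for i, ch in enumerate(seq):
        if ch in pos_counts:
            pos_counts[ch][i % 3] += 1
            total += 1
    if total == 0:
        return 0.0
    score = 0.0
    for base in "ACGT":
        c = pos_counts[base]
        position_value = max(c) / (min(c) + 1)
        content = sum(c) / total
        score += (
            _lookup(position_value, _POSITION_PARA, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        score += (
            _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return score


# --------------------------------------------------------------------------
# Hexamer usage model
# --------------------------------------------------------------------------

_BASES = "ACGT"
ALL_HEXAMERS = [
    a + b + c + d + e + f
    for a in _BASES for b in _BASES for c in _BASES
    for d in _BASES for e in _BASES for f in _BASES
]
_HEX_INDEX = {h: i for i, h in enumerate(ALL_HEXAMERS)}


@dataclass
class HexamerModel:
    """Smoothed hexamer frequency tables for coding and noncoding corpora."""

    coding: np.ndarray     # length 4096, sums to 1
    noncoding: np.ndarray  # length 4096, sums to 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hexamer": ALL_HEXAMERS, "coding": self.coding, "noncoding": self.noncoding}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HexamerModel":
        df = df.set_index("hexamer").loc[ALL_HEXAMERS]
        return cls(df["coding"].to_numpy(), df["noncoding"].to_numpy())


def _count_hexamers(seq: str, step: int, counts: np.ndarray) -> None:
    seq = seq.upper().replace("U", "T")
    for i in range(0, len(seq) - 5, step):
        idx = _HEX_INDEX.get(seq[i : i + 6])
        if idx is not None:  # skip hexamers containing N etc.
            counts[idx] += 1


def train_hexamer_model(
    coding_seqs: Iterable[str], noncoding_seqs: Iterable[str]
) -> HexamerModel:
    """Hexamer tables with add-one smoothing.

    Coding sequences are counted in frame (step 3, frame 0 — callers should
    pass ORF-trimmed sequences); noncoding sequences in all frames (step 1).
    Sequences shorter than 6 nt are skipped with a warning.
    """
    coding_counts = np.zeros(4096)
    noncoding_counts = np.zeros(4096)
    n_cod = n_non = 0
    for seq in coding_seqs:
        n_cod += 1
        if len(seq) < 6:
            warnings.warn("skipping coding sequence shorter than 6 nt", stacklevel=2)
            continue
        _count_hexamers(seq, 3, coding_counts)
    for seq in noncoding_seqs:
        n_non += 1
        if len(seq) < 6:
            warnings.warn("skipping noncoding sequence shorter than 6 nt", stacklevel=2)
            continue
        _count_hexamers(seq, 1, noncoding_counts)
    if n_cod == 0 or n_non == 0:
        raise ValueError("both training sets must be non-empty")
    coding_counts += 1.0
    noncoding_counts += 1.0
    return HexamerModel(
        coding_counts / coding_counts.sum(),
        noncoding_counts / noncoding_counts.sum(),
    )


def hexamer_score(seq: str, model: HexamerModel, step: int = 1) -> float:
    """Mean log(f_coding / f_noncoding) over sliding hexamers.

    ``step=1`` slides over every position; ``step=3`` scores in-frame
    hexamers only (use with an ORF-trimmed sequence)."""
    seq = seq.upper().replace("U", "T")
    if len(seq) < 6:
        raise ValueError("sequence shorter than 6 nt")
    ratios = []
    for i in range(0, len(seq) - 5, step):
        idx = _HEX_INDEX.get(seq[i : i + 6])
        if idx is not None:
            ratios.append(math.log(model.coding[idx] / model.noncoding[idx]))
    if not ratios:
        raise ValueError("no scorable hexamers (all contain ambiguous bases)")
    return float(np.mean(ratios))


# --------------------------------------------------------------------------
# Classification and benchmarking
# --------------------------------------------------------------------------

@dataclass
class VoteThresholds:
    min_orf_aa: int = 100
    fickett_cutoff: float = 0.95
    hexamer_cutoff: float = 0.0


def compute_features(
    seq: str, model: Optional[HexamerModel] = None, min_aa: int = 100
) -> CodingFeatures:
    orf = find_longest_orf(seq, min_aa=0)  # report even short ORFs as features
    coverage = (orf.end - orf.start) / len(seq) if orf else 0.0
    if model is None or len(seq) < 6:
        hexa = 0.0
    elif orf is not None and orf.end - orf.start >= 6:
        # score in the reading frame of the longest ORF
        hexa = hexamer_score(seq[orf.start : orf.end], model, step=3)
    else:
        hexa = hexamer_score(seq, model)
    return CodingFeatures(
        longest_orf=orf,
        orf_coverage=coverage,
        fickett=fickett_score(seq, warn_short=False),
        hexamer=hexa,
    )


def builtin_label(features: CodingFeatures, thresholds: Optional[VoteThresholds] = None) -> str:
    """Built-in classifier: coding iff (ORF > min aa AND hexamer > cutoff)
    OR fickett above its cutoff."""
    thr = thresholds or VoteThresholds()
    orf_aa = features.longest_orf.aa_length if features.longest_orf else 0
    coding = (orf_aa > thr.min_orf_aa and features.hexamer > thr.hexamer_cutoff) or (
        features.fickett > thr.fickett_cutoff
    )
    return "coding" if coding else "noncoding"


def classify_and_vote(
    features: CodingFeatures,
    thresholds: Optional[VoteThresholds] = None,
    votes: Sequence[str] = (),
) -> str:
    """Final label: noncoding only if every participating classifier
    (built-in plus any external label columns) says noncoding."""
    labels = [builtin_label(features, thresholds)] + list(votes)
    if not labels:
        raise ValueError("empty vote set")
    for lab in labels:
        if lab not in ("coding", "noncoding"):
            raise ValueError(f"invalid label {lab!r}")
    return "noncoding" if all(lab == "noncoding" for lab in labels) else "coding"


@dataclass
class BenchmarkResult:
    tp: int
    tn: int
    fp: int
    fn: int
    recall: float
    specificity: float
    precision: float
    balanced_accuracy: float
    f1: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "recall": self.recall, "specificity": self.specificity,
            "precision": self.precision,
            "balanced_accuracy": self.balanced_accuracy, "f1": self.f1,
        }


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
        return float("nan")
    return num / den


def benchmark_metrics(
    predicted: Mapping[str, str], truth: Mapping[str, str]
) -> BenchmarkResult:
    """Confusion counts and derived metrics with 'coding' as the positive
    class.  Undefined ratios come back as NaN with a warning."""
    if set(predicted) != set(truth):
        raise ValueError("predicted and true label sets cover different ids")
    tp = tn = fp = fn = 0
    for key, pred in predicted.items():
        true = truth[key]
        for lab in (pred, true):
            if lab not in ("coding", "noncoding"):
                raise ValueError(f"invalid label {lab!r}")
        if true == "coding":
            if pred == "coding":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "coding":
                fp += 1
            else:
                tn += 1
    recall = _safe_ratio(tp, tp + fn, "recall")
    specificity = _safe_ratio(tn, tn + fp, "specificity")
    precision = _safe_ratio(tp, tp + fp, "precision")
    balanced = (recall + specificity) / 2
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        warnings.warn("F1 undefined", stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return BenchmarkResult(tp, tn, fp, fn, recall, specificity, precision, balanced, f1)
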