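"""Independent brute-force oracles used by the test suite.

These re-derive expected results by naive enumeration over all windows and
offsets, deliberately sharing no code with the package implementations.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

TFO_ALPHABET = {"R": set("GA"), "Y": set("CTU"), "M": set("GTU")}
TFO_G = {"R": {"G"}, "Y": {"C"}, "M": {"G"}}
PAIRING = {
    "R": {"G": "G", "A": "A"},
    "Y": {"C": "G", "T": "A", "U": "A"},
    "M": {"G": "G", "T": "A", "U": "A"},
}
ANTIPARALLEL = {"R": True, "Y": False, "M": True}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT.get(c, "N") for c in reversed(seq))


def enumerate_valid_windows(err, gua, params) -> List[Tuple[int, int, int, float]]:
    """All (start, end, errors, guanine) windows satisfying the triplex
    constraints, by direct enumeration with cumulative sums."""
    err = np.asarray(err, dtype=np.int64)
    gua = np.asarray(gua, dtype=np.int64)
    n = len(err)
    ep = np.concatenate(([0], np.cumsum(err)))
    gp = np.concatenate(([0], np.cumsum(gua)))
    # triple[k] = 1 when positions k-2, k-1, k are all errors (for the
    # default max_consecutive_errors = 2); generalised to any run length
    runlen = params.max_consecutive_errors + 1
    over = np.zeros(n, dtype=np.int64)
    for k in range(runlen - 1, n):
        if err[k - runlen + 1 : k + 1].all():
            over[k] = 1
    op = np.concatenate(([0], np.cumsum(over)))
    out = []
    for i in range(n):
        if err[i]:
            continue
        for j in range(i + params.min_length, n + 1):
            if err[j - 1]:
                continue
            length = j - i
            e = int(ep[j] - ep[i])
            if e / length > params.max_error_rate:
                continue
            lo = min(j, i + runlen - 1)
            if op[j] - op[lo] > 0:  # an error run entirely inside the window
                continue
            g = float(gp[j] - gp[i]) / length
            if g < params.min_guanine:
                continue
            out.append((i, j, e, g))
    return out


def maximal(windows: List[Tuple[int, int, int, float]]) -> List[Tuple[int, int, int, float]]:
    """Drop windows contained in another valid window."""
    out = []
    for w in windows:
        if not any(
            v is not w and v[0] <= w[0] and w[1] <= v[1] and (v[0], v[1]) != (w[0], w[1])
            for v in windows
        ):
            out.append(w)
    # de-duplicate identical coordinates
    seen = set()
    uniq = []
    for w in out:
        key = (w[0], w[1])
        if key not in seen:
            seen.add(key)
            uniq.append(w)
    return sorted(uniq)


def merge_overlapping(windows):
    """Best representative (longest, fewest errors, left-most) per group of
    mutually-overlapping windows."""
    if not windows:
        return []
    windows = sorted(windows)
    groups = [[windows[0]]]
    cur_end = windows[0][1]
    for w in windows[1:]:
        if w[0] < cur_end:
            groups[-1].append(w)
            cur_end = max(cur_end, w[1])
        else:
            groups.append([w])
            cur_end = w[1]
    return [min(g, key=lambda w: (-(w[1] - w[0]), w[2], w[0])) for g in groups]


def oracle_tfo_tracts(seq: str, params) -> Dict[str, List[Tuple[int, int, int, float]]]:
    """Per-motif maximal (merged) TFO tracts by brute force."""
    s = seq.upper()
    out = {}
    for motif, alpha in TFO_ALPHABET.items():
        err = [0 if c in alpha else 1 for c in s]
        gua = [1 if c in TFO_G[motif] else 0 for c in s]
        wins = maximal(enumerate_valid_windows(err, gua, params))
        if params.merge_overlapping:
            wins = merge_overlapping(wins)
        out[motif] = wins
    return out


def oracle_tts_tracts(seq: str, params) -> Dict[str, List[Tuple[int, int, int, float]]]:
    """Per-purine-strand maximal (merged) TTS tracts by brute force."""
    s = seq.upper()
    out = {}
    for strand in "+-":
        if strand == "+":
            err = [0 if c in "AG" else 1 for c in s]
            gua = [1 if c == "G" else 0 for c in s]
        else:
            err = [0 if c in "CT" else 1 for c in s]
            gua = [1 if c == "C" else 0 for c in s]
        wins = maximal(enumerate_valid_windows(err, gua, params))
        if params.merge_overlapping:
            wins = merge_overlapping(wins)
        out[strand] = wins
    return out


def oracle_matches(
    tfo_seq: str, tfo_motif: str, tts_purine: str, params
) -> List[Tuple[int, int, int, int, int, float]]:
    """Brute-force TFO-vs-TTS alignment windows.

    Returns (tts_start, tts_end, tfo_start, tfo_end, errors, guanine) on
    the purine strand / original TFO coordinates, maximal per diagonal and
    reduced by the both-axes overlap merge rule when requested.
    """
    rule = PAIRING[tfo_motif]
    tfo = tfo_seq.upper().replace("U", "T")
    anti = ANTIPARALLEL[tfo_motif]
    aligned = tfo[::-1] if anti else tfo
    L, M = len(aligned), len(tts_purine)
    per_diag: List[List[Tuple[int, int, int, float]]] = []
    results = []
    for offset in range(-L + 1, M):
        lo, hi = max(0, offset), min(M, offset + L)
        if hi - lo < params.min_length:
            continue
        err = [0 if rule.get(aligned[k - offset]) == tts_purine[k] else 1
               for k in range(lo, hi)]
        gua = [1 if tts_purine[k] == "G" else 0 for k in range(lo, hi)]
        wins = maximal(enumerate_valid_windows(err, gua, params))
        for i, j, e, g in wins:
            ts, te = lo + i, lo + j
            fs, fe = ts - offset, te - offset
            if anti:
                fs, fe = L - fe, L - fs
            results.append((ts, te, fs, fe, e, g))
    if params.merge_overlapping:
        remaining = sorted(
            results, key=lambda m: (-(m[1] - m[0]), m[4], m[0], m[2])
        )
        kept = []
        for m in remaining:
            if not any(
                m[0] < k[1] and k[0] < m[1] and m[2] < k[3] and k[2] < m[3]
                for k in kept
            ):
                kept.append(m)
        results = kept
    return sorted(results)


def oracle_genome_context(
    annotation, promoter_def: Tuple[int, int]
) -> Dict[str, List[str]]:
    """Per-base context labels by direct per-base checks."""
    up, down = promoter_def
    out = {}
    for chrom, length in annotation.chrom_lengths.items():
        labels = ["intergenic"] * length
        for t in annotation:
            if t.chrom != chrom:
                continue
            for p in range(t.interval.start, t.interval.end):
                if labels[p] == "intergenic":
                    labels[p] = "intron"
            for e in t.exons:
                for p in range(e.start, e.end):
                    if labels[p] in ("intergenic", "intron"):
                        labels[p] = "exon"
        for t in annotation:
            if t.chrom != chrom:
                continue
            if t.strand == "-":
                lo, hi = t.interval.end - down, t.interval.end + up
            else:
                lo, hi = t.interval.start - up, t.interval.start + down
            for p in range(max(0, lo), min(length, hi)):
                labels[p] = "promoter"
        out[chrom] = labels
    return out


# --- independent Fickett TESTCODE re-implementation (same published tables,
#     different code path) -------------------------------------------------

_FICKETT_DATA = {
    "position": {
        "A": ([1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
              [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22], 0.26),
        "C": ([1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
              [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23], 0.18),
        "G": ([1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
              [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08], 0.31),
        "T": ([1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0],
              [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09], 0.33),
    },
    "content": {
        "A": ([0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0],
              [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21], 0.11),
        "C": ([0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0],
              [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31], 0.12),
        "G": ([0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0],
              [0.40, 0.54, 0.47, 0.64, 0.61, 0.73, 0.41, 0.41, 0.33, 0.29], 0.15),
        "T": ([0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0],
              [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58], 0.14),
    },
}


def oracle_fickett(seq: str) -> float:
    s = [c for c in seq.upper().replace("U", "T") if c in "ACGT"]
    if not s:
        return 0.0
    total = len(s)
    score = 0.0
    for base in "ACGT":
        frame_counts = [sum(1 for k, c in enumerate(s) if c == base and k % 3 == f)
                        for f in range(3)]
        posval = max(frame_counts) / (min(frame_counts) + 1)
        content = sum(frame_counts) / total
        for kind, value in (("position", posval), ("content", content)):
            thresholds, probs, weight = _FICKETT_DATA[kind][base]
            prob = probs[-1]
            for t, p in zip(thresholds, probs):
                if value >= t:
                    prob = p
                    break
            score += prob * weight
    return score
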