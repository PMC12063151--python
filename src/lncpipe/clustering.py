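"""Soft clustering of expression profiles: replicate-median +
z-standardisation, fuzzy c-means, and Dmin-based survey of cluster counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class FuzzyClustering:
    centers: np.ndarray      # c x n_points
    membership: pd.DataFrame # genes x c, rows sum to 1
    m: float
    cutoff: float

    @property
    def assigned(self) -> pd.Series:
        """Cluster index per gene, or -1 when max membership < cutoff."""
        u = self.membership.to_numpy()
        best = u.argmax(axis=1)
        best_val = u.max(axis=1)
        out = np.where(best_val >= self.cutoff, best, -1)
        return pd.Series(out, index=self.membership.index, name="cluster")


def standardize_profiles(
    transformed: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Median across replicates per sampling point, then per-gene z-score
    across sampling points.  Zero-variance genes are dropped with a
    warning.

    ``design`` must be indexed by sample name with a ``condition`` column;
    sampling points keep their first-appearance order.
    """
    if "condition" not in design.columns:
        raise ValueError("design needs a 'condition' column")
    conditions = list(dict.fromkeys(design["condition"]))
    if len(conditions) < 2:
        raise ValueError("need >= 2 sampling points")
    medians = pd.DataFrame(index=transformed.index)
    for cond in conditions:
        samples = design.index[design["condition"] == cond]
        medians[cond] = transformed[list(samples)].median(axis=1)
    vals = medians.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"dropping {(~keep).sum()} constant profile(s)", stacklevel=2
        )
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    return pd.DataFrame(z, index=medians.index[keep], columns=conditions)


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    cutoff: float = 0.7,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FuzzyClustering:
    """Standard fuzzy c-means (Euclidean) with seeded initialization.

    Iterates membership/center updates until the largest center shift is
    below ``tol`` or ``max_iter`` is reached.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if c > n:
        raise ValueError(f"c={c} exceeds number of profiles ({n})")
    rng = np.random.default_rng(seed)
    # initialize with random membership rows
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)
    centers = np.zeros((c, X.shape[1]))
    for _ in range(max_iter):
        um = u ** m
        new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - new_centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        # membership: u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = d2[:, :, None] / d2[:, None, :]
            u_new = 1.0 / (ratio ** (1.0 / (m - 1.0))).sum(axis=2)
        # points coinciding with a center: full membership there
        any_zero = zero.any(axis=1)
        if any_zero.any():
            u_new[any_zero] = 0.0
            rows = np.where(any_zero)[0]
            for r in rows:
                hits = np.where(zero[r])[0]
                u_new[r, hits] = 1.0 / len(hits)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        u = u_new
        if shift < tol:
            break
    membership = pd.DataFrame(
        u, index=profiles.index, columns=[f"cluster_{i}" for i in range(c)]
    )
    return FuzzyClustering(centers, membership, m, cutoff)


def min_center_distance(centers: np.ndarray) -> float:
    c = centers.shape[0]
    dmin = np.inf
    for i in range(c):
        for j in range(i + 1, c):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            dmin = min(dmin, d)
    return dmin


def select_k_dmin(
    profiles: pd.DataFrame,
    c_range: Sequence[int],
    repeats: int = 10,
    seeds: Optional[Sequence[int]] = None,
    m: float = 2.0,
) -> pd.DataFrame:
    """Dmin curve: for each c, the mean (over repeated seeded runs) of the
    minimum pairwise distance between cluster centers."""
    if seeds is None:
        seeds = list(range(repeats))
    if len(seeds) != repeats:
        raise ValueError("need one seed per repeat")
    rows = []
    for c in c_range:
        dmins = [
            min_center_distance(fuzzy_cmeans(profiles, c, m=m, seed=s).centers)
            for s in seeds
        ]
        rows.append({"c": c, "dmin": float(np.mean(dmins)),
                     "dmin_sd": float(np.std(dmins))})
    return pd.DataFrame(rows)
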