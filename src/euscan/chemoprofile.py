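"""Perfume-profile processing and community dissimilarity statistics.

Implements the peak/individual/compound filter cascade used for GC-MS
abundance tables, Bray-Curtis dissimilarities, the rank-based ANOSIM test
of between- vs within-species dissimilarity, the SIMPER decomposition of
between-group dissimilarity into per-compound contributions, and the
spike-rate correction used for single-sensillum recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .synthsim import PerfumeMatrix

__all__ = [
    "AnosimResult",
    "filter_profiles",
    "bray_curtis",
    "anosim",
    "simper",
    "ssr_corrected_rate",
]


@dataclass
class AnosimResult:
    r: float
    n_permutations: int
    n_ge_observed: int
    p: float
    exhaustive: bool


def filter_profiles(m: PerfumeMatrix, min_peak_frac: float = 0.01,
                    min_compounds_per_ind: int = 10,
                    min_inds_per_compound: int = 3) -> tuple[PerfumeMatrix, dict]:
    """Apply the profile filter cascade and renormalise to relative shares.

    Steps, in order: zero peaks below ``min_peak_frac`` of the individual's
    largest peak; drop individuals with fewer than ``min_compounds_per_ind``
    non-zero compounds; drop compounds non-zero in fewer than
    ``min_inds_per_compound`` individuals; renormalise rows to sum to 1.
    Returns the filtered matrix and a report of removals per step.
    """
    x = m.abundances.to_numpy(dtype=float).copy()
    report = {}
    peak = x.max(axis=1, keepdims=True)
    small = x < min_peak_frac * peak
    report["peaks_zeroed"] = int((small & (x > 0)).sum())
    x[small] = 0.0

    keep_ind = (x > 0).sum(axis=1) >= min_compounds_per_ind
    report["individuals_removed"] = int((~keep_ind).sum())
    x = x[keep_ind]

    keep_comp = (x > 0).sum(axis=0) >= min_inds_per_compound
    report["compounds_removed"] = int((~keep_comp).sum())
    x = x[:, keep_comp]
    if x.size == 0 or (x.sum(axis=1) == 0).any():
        raise ValueError("filtering removed all usable profile content")

    x = x / x.sum(axis=1, keepdims=True)
    df = pd.DataFrame(x, index=m.abundances.index[keep_ind],
                      columns=m.abundances.columns[keep_comp])
    out = PerfumeMatrix(df, m.species[keep_ind], normalized=True)
    return out, report


def bray_curtis(m: PerfumeMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity matrix between individuals.

    BC(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik).
    """
    df = m.abundances if isinstance(m, PerfumeMatrix) else m
    x = df.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero profile")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _anosim_r(dvec: np.ndarray, between: np.ndarray) -> float:
    ranks = rankdata(dvec)  # mid-rank ties
    m_pairs = len(dvec)
    rb = ranks[between].mean()
    rw = ranks[~between].mean()
    return float((rb - rw) / (m_pairs / 2))


def anosim(d: pd.DataFrame | np.ndarray, labels, n_permutations: int = 999,
           seed: int | None = None, exhaustive: bool | None = None) -> AnosimResult:
    """ANOSIM: are between-group dissimilarities larger than within-group?

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairs and mid-rank ties.  The p-value permutes group
    labels with the add-one convention, or enumerates every distinct
    labelling exactly when ``exhaustive`` is set (auto-enabled when the
    number of distinct labellings is at most ``n_permutations``).
    """
    dmat = d.to_numpy() if isinstance(d, pd.DataFrame) else np.asarray(d)
    labels = np.asarray(labels)
    n = len(labels)
    if dmat.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or counts.min() < 2:
        raise ValueError("need at least two groups with two members each")
    iu = np.triu_indices(n, k=1)
    dvec = dmat[iu]
    between = labels[iu[0]] != labels[iu[1]]
    observed = _anosim_r(dvec, between)

    # number of distinct assignments of labels to positions
    n_distinct = comb(n, int(counts[0])) if len(groups) == 2 else None
    if exhaustive is None:
        exhaustive = n_distinct is not None and n_distinct <= n_permutations
    if exhaustive:
        if len(groups) != 2:
            raise ValueError("exhaustive mode supports two groups")
        count = 0
        vals = []
        for combo in combinations(range(n), int(counts[0])):
            lab = np.full(n, groups[1], dtype=object)
            lab[list(combo)] = groups[0]
            between_p = lab[iu[0]] != lab[iu[1]]
            vals.append(_anosim_r(dvec, between_p))
        vals = np.array(vals)
        count = int((vals >= observed - 1e-12).sum())
        return AnosimResult(observed, len(vals), count, count / len(vals), True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        lab = rng.permutation(labels)
        between_p = lab[iu[0]] != lab[iu[1]]
        if _anosim_r(dvec, between_p) >= observed - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AnosimResult(observed, n_permutations, count, p, False)


def simper(m: PerfumeMatrix, group_a: str, group_b: str) -> pd.DataFrame:
    """SIMPER: per-compound percentage contribution to the mean between-group
    Bray-Curtis dissimilarity, sorted descending with cumulative percent.

    For each between-group pair (j, k), compound i contributes
    |x_ij - x_ik| / sum_i (x_ij + x_ik); contributions are averaged over
    pairs and expressed as percent of their sum (so they total 100).
    """
    df = m.abundances
    xa = df.to_numpy(dtype=float)[m.species == group_a]
    xb = df.to_numpy(dtype=float)[m.species == group_b]
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("both groups must be non-empty")
    contrib = np.zeros(df.shape[1])
    for j in range(len(xa)):
        diff = np.abs(xa[j][None, :] - xb)          # (nb, ncomp)
        denom = (xa[j][None, :] + xb).sum(axis=1)   # (nb,)
        contrib += (diff / denom[:, None]).sum(axis=0)
    contrib /= len(xa) * len(xb)
    pct = 100 * contrib / contrib.sum()
    out = pd.DataFrame({"compound": df.columns, "mean_dissimilarity": contrib,
                        "contribution_pct": pct})
    out = out.sort_values("contribution_pct", ascending=False).reset_index(drop=True)
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    return out


def ssr_corrected_rate(spikes_pre: int, spikes_post: int) -> float:
    """Corrected spikes-per-second response of a sensillum to an odour puff.

    Spikes are counted in the 0.5 s windows before and after puff onset;
    the corrected rate is (post - pre) * 2 (negative values indicate
    inhibition).
    """
    if spikes_pre < 0 or spikes_post < 0:
        raise ValueError("spike counts must be non-negative")
    return float((spikes_post - spikes_pre) * 2)
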