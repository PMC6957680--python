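"""Windowed differentiation statistics and the net-differentiation outlier scan.

Implements per-window nucleotide diversity (pi), absolute divergence (Dxy),
Hudson-type Fst (ratio of per-site averages), within-window LD, the
z-transformed net interspecific differentiation track (delta Fst') with its
companion diversity differential (delta pi), percentile outlier flagging with
peak clustering, track correlations, the f4 "treeness" test with a block
jackknife, and label-permutation tests for window statistics.

Windows are 0-based half-open.  All per-bp statistics divide by the window
length in bp, so monomorphic (and invariant, uncalled) positions contribute
zero to the numerator.  "No data" is reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .variantio import MISSING, GenomeWindows, HaplotypeMatrix

__all__ = [
    "F4Result",
    "PermutationResult",
    "window_pi",
    "window_dxy",
    "window_fst",
    "window_ld",
    "compute_window_stats",
    "differentiation_tracks",
    "find_outlier_peaks",
    "track_correlation",
    "f4_test",
    "window_permutation_test",
]


# ---------------------------------------------------------------------------
# per-window statistics
# ---------------------------------------------------------------------------

def _counts(m: HaplotypeMatrix, pop, window):
    chrom, start, end = window
    sites = m.site_mask(chrom, start, end)
    alt, called = m.allele_counts(pop=pop, sites=sites)
    return alt.astype(float), called.astype(float), end - start


def _pi_sum(alt: np.ndarray, called: np.ndarray) -> float:
    """Summed per-site unbiased haploid heterozygosity over sites with >=2 calls."""
    ok = called >= 2
    if not ok.any():
        return 0.0
    a, n = alt[ok], called[ok]
    p = a / n
    return float((n / (n - 1) * 2 * p * (1 - p)).sum())


def window_pi(m: HaplotypeMatrix, pop, window) -> float:
    """Per-bp nucleotide diversity of ``pop`` in ``window`` = (chrom, start, end).

    pi = sum over sites of [n/(n-1)] 2 p (1-p) divided by window length.
    Returns NaN when the population sample cannot yield a pairwise comparison
    (fewer than two individuals, or sites present but none with two calls).
    """
    if m.pop_mask(pop).sum() < 2:
        return float("nan")
    alt, called, L = _counts(m, pop, window)
    if len(alt) and not (called >= 2).any():
        return float("nan")
    return _pi_sum(alt, called) / L


def window_dxy(m: HaplotypeMatrix, popA, popB, window) -> float:
    """Per-bp absolute divergence: sum over sites of pA(1-pB)+pB(1-pA), / length.

    Sites lacking a call in either population are skipped; a window whose
    sites all lack cross-population data returns NaN.
    """
    altA, nA, L = _counts(m, popA, window)
    altB, nB, _ = _counts(m, popB, window)
    ok = (nA > 0) & (nB > 0)
    if len(altA) and not ok.any():
        return float("nan")
    pA = np.divide(altA, nA, out=np.zeros_like(altA), where=nA > 0)
    pB = np.divide(altB, nB, out=np.zeros_like(altB), where=nB > 0)
    d = pA * (1 - pB) + pB * (1 - pA)
    return float(d[ok].sum()) / L


def _fst_sums(altA, nA, altB, nB):
    ok = (nA >= 2) & (nB >= 2)
    if not ok.any():
        return 0.0, 0.0
    aA, cA, aB, cB = altA[ok], nA[ok], altB[ok], nB[ok]
    pA, pB = aA / cA, aB / cB
    hA = cA / (cA - 1) * 2 * pA * (1 - pA)
    hB = cB / (cB - 1) * 2 * pB * (1 - pB)
    hw = 0.5 * (hA + hB)
    hb = pA * (1 - pB) + pB * (1 - pA)
    return float(hw.sum()), float(hb.sum())


def window_fst(m: HaplotypeMatrix, popA, popB, window) -> float:
    """Hudson-type window Fst as a ratio of per-site sums.

    Fst = 1 - sum(Hw) / sum(Hb) with Hw the mean unbiased within-population
    heterozygosity and Hb the between-population heterozygosity.  Windows
    with sum(Hb) = 0 carry no differentiation information and return NaN.
    """
    altA, nA, _ = _counts(m, popA, window)
    altB, nB, _ = _counts(m, popB, window)
    hw, hb = _fst_sums(altA, nA, altB, nB)
    if hb == 0.0:
        return float("nan")
    return 1.0 - hw / hb


def window_ld(m: HaplotypeMatrix, pop, window, min_pair_distance: int = 1000,
              min_call_rate: float = 0.9) -> float:
    """Mean haploid composite r^2 over qualifying within-window SNP pairs.

    Only SNPs called in at least ``min_call_rate`` of the population qualify,
    and only pairs at least ``min_pair_distance`` bp apart are averaged.
    Returns NaN with fewer than two qualifying SNPs or no qualifying pair.
    """
    chrom, start, end = window
    sites = np.flatnonzero(m.site_mask(chrom, start, end))
    mask = m.pop_mask(pop)
    calls = m.calls[mask][:, sites]
    called = (calls != MISSING).mean(axis=0)
    good = called >= min_call_rate
    sites, calls = sites[good], calls[:, good]
    if len(sites) < 2:
        return float("nan")
    pos = m.pos[sites]
    vals = []
    for i, j in combinations(range(len(sites)), 2):
        if abs(pos[j] - pos[i]) < min_pair_distance:
            continue
        r2 = _r2(calls[:, i], calls[:, j])
        if np.isfinite(r2):
            vals.append(r2)
    return float(np.mean(vals)) if vals else float("nan")


def _r2(x, y):
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return np.nan
    c = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return c * c / (vx * vy)


# ---------------------------------------------------------------------------
# the scan table
# ---------------------------------------------------------------------------

def compute_window_stats(m: HaplotypeMatrix, windows: GenomeWindows,
                         species: dict[str, list[str]] | None = None,
                         inter_pair: tuple = ("Ev", "Ed"),
                         intra_pair: tuple = ("Ed_north", "Ed_south"),
                         ld_pop=None, gene_counts=None) -> pd.DataFrame:
    """Build the per-window statistics table for the divergence scan.

    ``species`` maps a species label to the population labels pooled into it
    (default: Ev as-is; Ed pools Ed_north and Ed_south).  The interspecific
    contrast is computed between the two species groups, the intraspecific
    contrast between the populations in ``intra_pair``.
    """
    if species is None:
        species = {"Ev": ["Ev"], "Ed": ["Ed_north", "Ed_south"]}
    groups = dict(species)
    for p in set(np.unique(m.populations)):
        groups.setdefault(p, [p])
    rows = []
    for chrom, start, end in windows:
        w = (chrom, start, end)
        row = {"chrom": chrom, "start": start, "end": end}
        for name, pops in groups.items():
            row[f"pi_{name}"] = window_pi(m, pops, w)
        row["dxy_inter"] = window_dxy(m, groups[inter_pair[0]], groups[inter_pair[1]], w)
        row["fst_inter"] = window_fst(m, groups[inter_pair[0]], groups[inter_pair[1]], w)
        row["fst_intra"] = window_fst(m, groups[intra_pair[0]], groups[intra_pair[1]], w)
        if ld_pop is not None:
            row["mean_r2"] = window_ld(m, groups.get(ld_pop, [ld_pop]), w)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["partial"] = windows.partial
    if gene_counts is not None:
        df["gene_count"] = np.asarray(gene_counts)
    return df


def differentiation_tracks(table: pd.DataFrame, inter_col: str = "fst_inter",
                           intra_col: str = "fst_intra",
                           pi_first: str = "pi_Ev",
                           pi_second: str = "pi_Ed") -> pd.DataFrame:
    """Add Fst', delta Fst' and delta pi columns to a window table.

    Each Fst track is z-transformed over all windows with data
    ((x - mean)/sd); delta Fst' is the interspecific minus the intraspecific
    z-score, and delta pi is ``pi_first - pi_second`` (by default
    pi_Ev - pi_Ed with Ed pooled across its two populations).
    """
    out = table.copy()
    for col, zcol in ((inter_col, "fst_prime_inter"), (intra_col, "fst_prime_intra")):
        x = out[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        sd = x[ok].std(ddof=0) if ok.any() else 0.0
        if sd <= 1e-12 * max(1.0, np.abs(x[ok]).max() if ok.any() else 0.0):
            raise ValueError(f"degenerate track {col}: zero standard deviation")
        z = np.full_like(x, np.nan)
        z[ok] = (x[ok] - x[ok].mean()) / sd
        out[zcol] = z
    out["dfst_prime"] = out["fst_prime_inter"] - out["fst_prime_intra"]
    out["dpi"] = out[pi_first] - out[pi_second]
    return out


def find_outlier_peaks(table: pd.DataFrame, quantile: float = 0.99,
                       max_gap_bp: int = 100_000,
                       exclude_partial: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag windows with delta Fst' strictly above the empirical quantile and
    merge flagged windows into peaks.

    Flagged windows on the same scaffold whose gap (start of the next minus
    end of the previous) is at most ``max_gap_bp`` join one peak.  Returns
    the annotated window table and a per-peak summary.
    """
    out = table.copy()
    vals = out["dfst_prime"].to_numpy(dtype=float)
    consider = np.isfinite(vals)
    if exclude_partial and "partial" in out:
        consider &= ~out["partial"].to_numpy(dtype=bool)
    thr = np.quantile(vals[consider], quantile)
    out["outlier"] = consider & (vals > thr)
    out["peak_id"] = -1
    peak = 0
    prev = None  # (chrom, end) of last flagged window
    order = out.sort_values(["chrom", "start"]).index
    for i in order:
        if not out.at[i, "outlier"]:
            continue
        c, s, e = out.at[i, "chrom"], out.at[i, "start"], out.at[i, "end"]
        if prev is None or prev[0] != c or s - prev[1] > max_gap_bp:
            peak += 1
        out.at[i, "peak_id"] = peak
        prev = (c, e)
    flagged = out[out["outlier"]]
    peaks = (flagged.groupby("peak_id")
             .agg(chrom=("chrom", "first"), start=("start", "min"),
                  end=("end", "max"), n_windows=("start", "size"))
             .reset_index()) if len(flagged) else pd.DataFrame(
        columns=["peak_id", "chrom", "start", "end", "n_windows"])
    return out, peaks


def track_correlation(table: pd.DataFrame, track1: str, track2: str) -> tuple[float, float]:
    """Pairwise-complete Pearson correlation between two window tracks."""
    x = table[track1].to_numpy(dtype=float)
    y = table[track2].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 windows with both tracks")
    if x[ok].std() == 0 or y[ok].std() == 0:
        raise ValueError("constant track")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# f4 test
# ---------------------------------------------------------------------------

@dataclass
class F4Result:
    f4: float
    se: float
    z: float
    p: float
    n_snps: int
    n_blocks: int


def f4_test(m: HaplotypeMatrix, popA, popB, popC, popD,
            block_size_snps: int = 100) -> F4Result:
    """f4(A, B; C, D) with a delete-one block jackknife standard error.

    f4 is the mean over SNPs of (pA - pB)(pC - pD); SNPs lacking a call in
    any of the four groups are skipped.  The SE comes from a delete-one
    jackknife over contiguous blocks of ``block_size_snps`` SNPs.
    """
    freqs = []
    for pop in (popA, popB, popC, popD):
        alt, called = m.allele_counts(pop=pop)
        freqs.append((alt.astype(float), called.astype(float)))
    ok = np.ones(m.n_sites, dtype=bool)
    for _, called in freqs:
        ok &= called > 0
    ps = [np.divide(a, c, out=np.zeros_like(a), where=c > 0)[ok] for a, c in freqs]
    vals = (ps[0] - ps[1]) * (ps[2] - ps[3])
    n = len(vals)
    nb = n // block_size_snps + (1 if n % block_size_snps else 0)
    if nb < 2:
        raise ValueError("fewer than 2 jackknife blocks; reduce block_size_snps")
    f4 = float(vals.mean())
    loo = np.array([np.delete(vals, slice(b * block_size_snps,
                                          min((b + 1) * block_size_snps, n))).mean()
                    for b in range(nb)])
    se = float(np.sqrt((nb - 1) / nb * ((loo - loo.mean()) ** 2).sum()))
    z = f4 / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return F4Result(f4=f4, se=se, z=float(z), p=p, n_snps=n, n_blocks=nb)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    statistic: str
    n_permutations: int
    n_ge_observed: int
    p: float
    exhaustive: bool


def _stat_arrays(calls):
    C = (calls == 1).astype(float)
    M = (calls != MISSING).astype(float)
    return C, M


def _perm_stat(statistic, memA, C, M, L):
    """Vectorised window statistic for a stack of group-A membership rows."""
    altA = memA @ C
    calledA = memA @ M
    altB = C.sum(axis=0) - altA
    calledB = M.sum(axis=0) - calledA
    if statistic == "dxy":
        ok = (calledA > 0) & (calledB > 0)
        pA = np.divide(altA, calledA, out=np.zeros_like(altA), where=calledA > 0)
        pB = np.divide(altB, calledB, out=np.zeros_like(altB), where=calledB > 0)
        d = pA * (1 - pB) + pB * (1 - pA)
        return np.where(ok, d, 0.0).sum(axis=1) / L
    if statistic == "dpi":
        out = []
        for alt, called in ((altA, calledA), (altB, calledB)):
            ok = called >= 2
            p = np.divide(alt, called, out=np.zeros_like(alt), where=ok)
            h = np.where(ok, called / np.maximum(called - 1, 1) * 2 * p * (1 - p), 0.0)
            out.append(h.sum(axis=1) / L)
        return out[0] - out[1]
    if statistic == "fst":
        ok = (calledA >= 2) & (calledB >= 2)
        pA = np.divide(altA, calledA, out=np.zeros_like(altA), where=ok)
        pB = np.divide(altB, calledB, out=np.zeros_like(altB), where=ok)
        hA = calledA / np.maximum(calledA - 1, 1) * 2 * pA * (1 - pA)
        hB = calledB / np.maximum(calledB - 1, 1) * 2 * pB * (1 - pB)
        hw = np.where(ok, 0.5 * (hA + hB), 0.0).sum(axis=1)
        hb = np.where(ok, pA * (1 - pB) + pB * (1 - pA), 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(hb > 0, 1.0 - hw / hb, np.nan)
    raise ValueError(f"unknown statistic {statistic!r}; use 'fst', 'dxy' or 'dpi'")


def window_permutation_test(m: HaplotypeMatrix, window, statistic: str,
                            labelsA, labelsB, B: int = 10_000,
                            seed: int | None = None,
                            exhaustive: bool = False) -> PermutationResult:
    """Label-permutation test of a window statistic between two groups.

    Individual-to-group assignment is permuted preserving group sizes; the
    reported p-value uses the add-one convention (count + 1)/(B + 1) for
    Monte-Carlo permutations.  With ``exhaustive=True`` every distinct
    assignment is enumerated and the exact p-value count/total (observed
    assignment included) is returned instead.
    """
    chrom, start, end = window
    maskA, maskB = m.pop_mask(labelsA), m.pop_mask(labelsB)
    if (maskA & maskB).any():
        raise ValueError("groups overlap")
    union = maskA | maskB
    sites = m.site_mask(chrom, start, end)
    calls = m.calls[union][:, sites]
    L = end - start
    inA = maskA[union]
    n, nA = int(union.sum()), int(inA.sum())
    n_assign = comb(n, nA) if nA != n - nA else comb(n, nA) // 2
    if nA == 0 or nA == n or n_assign < 2:
        raise ValueError("only one distinct assignment; nothing to permute")
    C, M = _stat_arrays(calls)
    observed = float(_perm_stat(statistic, inA.astype(float)[None, :], C, M, L)[0])
    if not np.isfinite(observed):
        raise ValueError(f"observed {statistic} is undefined in this window")

    if exhaustive:
        combos = list(combinations(range(n), nA))
        memA = np.zeros((len(combos), n))
        for i, cset in enumerate(combos):
            memA[i, list(cset)] = 1.0
        vals = _perm_stat(statistic, memA, C, M, L)
        count = int(np.nansum(vals >= observed - 1e-12))
        p = count / len(combos)
        return PermutationResult(observed, statistic, len(combos), count, p, True)

    rng = np.random.default_rng(seed)
    count = 0
    chunk = 2000
    done = 0
    while done < B:
        b = min(chunk, B - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        memA = np.zeros((b, n))
        np.put_along_axis(memA, order[:, :nA], 1.0, axis=1)
        vals = _perm_stat(statistic, memA, C, M, L)
        count += int(np.nansum(vals >= observed - 1e-12))
        done += b
    p = (count + 1) / (B + 1)
    return PermutationResult(observed, statistic, B, count, p, False)
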