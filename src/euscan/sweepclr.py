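"""Composite-likelihood-ratio selective-sweep scan on the folded SFS.

The scan contrasts, at each grid position, a hitchhiking model against the
genome-wide ("background") folded site-frequency spectrum.  In the sweep
model a lineage at distance ``d`` from the swept site escapes the sweep with
probability ``1 - exp(-alpha * d)`` (alpha is the sweep-strength parameter,
per bp).  The lineages that fail to escape coalesce into the single sweeping
haplotype, so a site's ancestral sample behaves as ``k + 1`` draws from the
background spectrum: the ``k`` escapees plus one lineage whose allele is
copied onto all ``n - k`` hitchhikers.  Monomorphic outcomes are excluded
and the class distribution renormalised, since the scan conditions on
polymorphism.  CLR(x) = 2 (max_alpha lnCL - lnCL0) is floored at zero.

Significance thresholds come from neutral forward simulations under the
fitted demography: the threshold for a lineage is the top (maximum) CLR
observed across all simulated neutral regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .variantio import HaplotypeMatrix
from . import synthsim

__all__ = [
    "FoldedSFS",
    "CLRGrid",
    "folded_sfs",
    "sweep_site_probability",
    "clr_scan",
    "null_clr_threshold",
    "CalibrationResult",
    "call_sweeps",
]


# ---------------------------------------------------------------------------
# folded SFS
# ---------------------------------------------------------------------------

@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum: counts per minor-allele class 1..n//2.

    ``span_bp`` optionally records how many bp were surveyed to obtain the
    spectrum, which gives the per-bp polymorphic-site density used by the
    invariant-site term of the CLR scan.
    """

    n: int
    counts: np.ndarray
    span_bp: float | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n < 4:
            raise ValueError("sample size below 4: spectrum too small")
        if len(self.counts) != self.n // 2:
            raise ValueError(f"expected {self.n // 2} classes for n={self.n}")
        if (self.counts < 0).any():
            raise ValueError("negative class count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def site_density(self) -> float | None:
        """Polymorphic sites per surveyed bp (None without span information)."""
        if self.span_bp is None or self.span_bp <= 0:
            return None
        return self.total / self.span_bp

    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("all-zero folded spectrum")
        return self.counts / self.total

    def __add__(self, other: "FoldedSFS") -> "FoldedSFS":
        if other.n != self.n:
            raise ValueError("cannot add spectra with different sample sizes")
        span = (self.span_bp + other.span_bp
                if self.span_bp is not None and other.span_bp is not None else None)
        return FoldedSFS(self.n, self.counts + other.counts, span)


def _project_unfolded(q: np.ndarray, n_from: int, n_to: int) -> np.ndarray:
    """Hypergeometric projection of a derived-count distribution (length
    n_from+1) to sample size n_to (length n_to+1)."""
    out = np.zeros(n_to + 1)
    for j in range(n_from + 1):
        if q[j] == 0:
            continue
        i = np.arange(n_to + 1)
        out += q[j] * hypergeom.pmf(i, n_from, j, n_to)
    return out


def _unfold(b: np.ndarray, n: int) -> np.ndarray:
    """Symmetric unfolding of folded class probabilities to derived counts."""
    q = np.zeros(n + 1)
    for c in range(1, n // 2 + 1):
        if c == n - c:
            q[c] = b[c - 1]
        else:
            q[c] += b[c - 1] / 2
            q[n - c] += b[c - 1] / 2
    return q


def _fold(q: np.ndarray, n: int) -> np.ndarray:
    """Fold derived-count probabilities to minor classes 1..n//2 (class 0
    i.e. monomorphic mass is dropped, not renormalised here)."""
    out = np.zeros(n // 2)
    for i in range(1, n):
        out[min(i, n - i) - 1] += q[i]
    return out


def folded_sfs(m: HaplotypeMatrix, pop, region=None,
               project_to: int | None = None) -> FoldedSFS:
    """Folded SFS of ``pop`` over ``region`` (or all sites).

    Sites with missing calls are down-projected to ``project_to`` haploid
    samples by hypergeometric projection (fractional class mass); sites with
    fewer called samples than the target are dropped.  Without
    ``project_to`` the target is the population sample size.
    """
    if region is None:
        sites = np.ones(m.n_sites, dtype=bool)
    else:
        sites = m.site_mask(*region)
    alt, called = m.allele_counts(pop=pop, sites=sites)
    n = int(project_to or m.pop_mask(pop).sum())
    if n < 4:
        raise ValueError("sample size below 4: spectrum too small")
    counts = np.zeros(n // 2)
    for a, c in zip(alt, called):
        if c < n or a == 0 or a == c:
            continue
        if c == n:
            counts[min(a, n - a) - 1] += 1.0
        else:
            i = np.arange(n + 1)
            pj = hypergeom.pmf(i, int(c), int(a), n)
            counts += _fold(pj, n)
    if region is not None:
        span = float(region[2] - region[1])
    else:
        span = float(sum(int(m.pos[m.chrom == c].max()) + 1
                         for c in dict.fromkeys(m.chrom))) if m.n_sites else None
    return FoldedSFS(n, counts, span)


# ---------------------------------------------------------------------------
# the sweep model
# ---------------------------------------------------------------------------

class _SweepModel:
    """Cached per-(n, background) machinery for sweep class probabilities."""

    def __init__(self, n: int, background_probs: np.ndarray):
        self.n = n
        b = np.asarray(background_probs, dtype=float)
        if b.sum() <= 0:
            raise ValueError("all-zero background spectrum")
        self.b = b / b.sum()
        q = _unfold(self.b, n)
        # A[k, m] = P(final derived count m | k escapees), k = 0..n
        A = np.zeros((n + 1, n + 1))
        for k in range(n + 1):
            if k == n:
                A[k] = q
                continue
            mm = k + 1
            proj = _project_unfolded(q, n, mm)
            for i in range(mm + 1):
                if proj[i] == 0:
                    continue
                w_der = i / mm
                if w_der > 0:
                    A[k, (i - 1) + (n - k)] += proj[i] * w_der
                if 1 - w_der > 0:
                    A[k, i] += proj[i] * (1 - w_der)
        self.A = A

    def _folded_mix(self, p_escape: float) -> np.ndarray:
        p = min(max(p_escape, 1e-12), 1.0)
        w = binom.pmf(np.arange(self.n + 1), self.n, p)
        return _fold(w @ self.A, self.n)

    def poly_retention(self, p_escape: float) -> float:
        """P(site still polymorphic under the sweep | polymorphic in the
        background sample): the mass not pushed into the monomorphic class."""
        return float(self._folded_mix(p_escape).sum())

    def class_probs(self, p_escape: float) -> np.ndarray:
        """Folded polymorphic-class probabilities at escape probability p."""
        folded = self._folded_mix(p_escape)
        tot = folded.sum()
        if tot < 1e-300:
            # all-hitchhiking limit: only singleton classes survive
            folded = np.zeros(self.n // 2)
            folded[0] = 1.0
            return folded
        return folded / tot

    def logprob_table(self, u_grid: np.ndarray) -> np.ndarray:
        """ln class probabilities for a grid of u = alpha * d values."""
        out = np.empty((len(u_grid), self.n // 2))
        for i, u in enumerate(u_grid):
            out[i] = np.log(np.maximum(self.class_probs(-np.expm1(-u)), 1e-300))
        return out

    def retention_table(self, u_grid: np.ndarray) -> np.ndarray:
        """Polymorphism-retention factor phi for a grid of u = alpha * d."""
        return np.array([self.poly_retention(-np.expm1(-u)) for u in u_grid])


def sweep_site_probability(j: int, n: int, background: FoldedSFS,
                           alpha: float, d: float) -> float:
    """P(minor class j) at distance ``d`` bp from a sweep of strength ``alpha``.

    The background spectrum is projected to sample size ``n`` if necessary.
    ``j`` must be a valid polymorphic minor class for ``n``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not 1 <= j <= n // 2:
        raise ValueError(f"class {j} invalid for n={n}")
    b = _background_for_n(background, n)
    model = _SweepModel(n, b)
    p_e = -np.expm1(-alpha * d)
    return float(model.class_probs(p_e)[j - 1])


def _background_for_n(background: FoldedSFS, n: int) -> np.ndarray:
    """Folded background probabilities projected to sample size n."""
    if background.n == n:
        return background.probabilities()
    if background.n < n:
        raise ValueError("background sample size smaller than scan sample size")
    q = _unfold(background.probabilities(), background.n)
    qn = _project_unfolded(q, background.n, n)
    folded = _fold(qn, n)
    return folded / folded.sum()


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

@dataclass
class CLRGrid:
    """CLR scan result on a regular grid of positions."""

    chrom: str
    positions: np.ndarray
    clr: np.ndarray
    alpha_hat: np.ndarray
    grid_spacing: int
    lineage: str | None = None
    threshold: float | None = None
    significant: np.ndarray | None = None

    @property
    def max_clr(self) -> float:
        return float(self.clr.max())

    @property
    def argmax_position(self) -> int:
        return int(self.positions[int(np.argmax(self.clr))])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions, "clr": self.clr,
                           "alpha_hat": self.alpha_hat})
        if self.significant is not None:
            df["significant"] = self.significant
        return df


_U_GRID = np.concatenate([[0.0], np.geomspace(1e-8, 80.0, 700)])


def _interp_u(tab: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Linear interpolation of per-u tables at u values.

    ``tab`` is (n_u,) for a shared column or (n_u, k) with one column per
    site; ``u`` is (n_x, k)."""
    nu = tab.shape[0]
    idx = np.clip(np.searchsorted(_U_GRID, u) - 1, 0, nu - 2)
    lo = _U_GRID[idx]
    w = (u - lo) / np.maximum(_U_GRID[idx + 1] - lo, 1e-300)
    if tab.ndim == 1:
        v, v2 = tab[idx], tab[idx + 1]
    else:
        cols = np.broadcast_to(np.arange(u.shape[1]), idx.shape)
        v, v2 = tab[idx, cols], tab[idx + 1, cols]
    return v * (1 - w) + v2 * w


_INVARIANT_BIN = 250  # bp resolution of the invariant-site integral


def clr_scan(m: HaplotypeMatrix, pop, region, background: FoldedSFS,
             grid_spacing: int = 1000,
             alpha_bounds: tuple[float, float] = (1e-7, 1e-1),
             n_alpha: int = 25, refine: bool = True,
             min_sites: int = 5, include_invariant: bool = True) -> CLRGrid:
    """Composite-likelihood-ratio sweep scan over ``region`` for one lineage.

    At each grid position x the composite likelihood combines, per position
    in the region, whether the position is polymorphic and (if so) its
    folded frequency class.  Under the background, each bp is polymorphic
    with probability lambda (the background per-bp SNP density) with class
    probabilities from the background spectrum; under the sweep model at
    distance d the polymorphism probability is multiplied by the retention
    factor phi(alpha d) and the class distribution is the renormalised sweep
    spectrum.  CLR(x) = 2 max_alpha [lnCL(alpha) - lnCL0], floored at zero;
    alpha is maximised over a log-spaced grid with optional golden-section
    refinement.

    The invariant-site term requires ``background.site_density`` (a spectrum
    accumulated with span information); without it, or with
    ``include_invariant=False``, the scan uses the polymorphic sites alone.
    Sites with missing calls enter at their own called sample size.
    """
    chrom, start, end = region
    sites = m.site_mask(chrom, start, end)
    alt, called = m.allele_counts(pop=pop, sites=sites)
    pos = m.pos[sites]
    poly = (alt > 0) & (alt < called) & (called >= 4)
    if poly.sum() < min_sites:
        raise ValueError(f"only {int(poly.sum())} polymorphic sites in region "
                         f"(need >= {min_sites})")
    alt, called, pos = alt[poly], called[poly], pos[poly]
    cls = np.minimum(alt, called - alt)  # minor class, 1-based

    lam = background.site_density if include_invariant else None
    if lam is not None:
        lam = float(np.clip(lam, 1e-6, 0.5))

    # per-sample-size model tables and background log-probs
    class_tab: dict[int, np.ndarray] = {}
    lnb: dict[int, np.ndarray] = {}
    lnphi: dict[int, np.ndarray] = {}
    g_tab = None
    n_modal = int(pd.Series(called).mode().iat[0])
    for n in np.unique(called):
        b = _background_for_n(background, int(n))
        model = _SweepModel(int(n), b)
        class_tab[int(n)] = model.logprob_table(_U_GRID)
        lnb[int(n)] = np.log(np.maximum(b, 1e-300))
        if lam is not None:
            phi = model.retention_table(_U_GRID)
            lnphi[int(n)] = np.log(np.maximum(phi, 1e-12))
            if int(n) == n_modal:
                g_tab = np.log1p(-lam * phi) - np.log1p(-lam)

    # per-site gain column: ln of (sweep / background) likelihood for the
    # observed class, plus the retention term and minus the invariant-bin
    # double count at the site's own position; far sites contribute zero
    site_cols = []
    for a, c in zip(cls, called):
        col = class_tab[int(c)][:, a - 1] - lnb[int(c)][a - 1]
        if lam is not None:
            col = col + lnphi[int(c)] - g_tab
        site_cols.append(col)
    site_tab = np.stack(site_cols, axis=1)  # (n_u, n_sites)

    grid = np.arange(start + grid_spacing // 2, end, grid_spacing, dtype=np.int64)
    dist = np.abs(pos[None, :] - grid[:, None]).astype(float)  # (n_x, n_sites)
    if lam is not None:
        edges = np.arange(start, end + _INVARIANT_BIN, _INVARIANT_BIN, dtype=float)
        edges[-1] = min(edges[-1], end)
        centers = (edges[:-1] + edges[1:]) / 2
        bin_w = np.diff(edges)
        dist_bins = np.abs(centers[None, :] - grid[:, None])

    def gains(alpha_per_x: np.ndarray) -> np.ndarray:
        """ln CL(x, alpha_x) - ln CL0 for every grid position at once."""
        total = _interp_u(site_tab, alpha_per_x[:, None] * dist).sum(axis=1)
        if lam is not None:
            total = total + (_interp_u(g_tab, alpha_per_x[:, None] * dist_bins)
                             * bin_w).sum(axis=1)
        return total

    n_x = len(grid)
    alphas = np.geomspace(alpha_bounds[0], alpha_bounds[1], n_alpha)
    vals = np.stack([gains(np.full(n_x, a)) for a in alphas])  # (n_alpha, n_x)
    best_i = np.argmax(vals, axis=0)
    best_v = vals[best_i, np.arange(n_x)]
    best_a = alphas[best_i]
    if refine:
        invphi_c = (np.sqrt(5) - 1) / 2
        lo = np.log(alphas[np.maximum(best_i - 1, 0)])
        hi = np.log(alphas[np.minimum(best_i + 1, n_alpha - 1)])
        c_ = hi - invphi_c * (hi - lo)
        d_ = lo + invphi_c * (hi - lo)
        fc, fd = gains(np.exp(c_)), gains(np.exp(d_))
        for _ in range(6):
            take = fc >= fd
            hi = np.where(take, d_, hi)
            lo = np.where(take, lo, c_)
            c_ = hi - invphi_c * (hi - lo)
            d_ = lo + invphi_c * (hi - lo)
            fc, fd = gains(np.exp(c_)), gains(np.exp(d_))
        mid = np.exp((lo + hi) / 2)
        fm = gains(mid)
        better = fm > best_v
        best_v = np.where(better, fm, best_v)
        best_a = np.where(better, mid, best_a)
    clr = np.maximum(2.0 * best_v, 0.0)
    return CLRGrid(chrom=chrom, positions=grid, clr=clr, alpha_hat=best_a,
                   grid_spacing=grid_spacing)


# ---------------------------------------------------------------------------
# calibration and calling
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    thresholds: dict[str, float]
    max_clr: pd.DataFrame           # one row per simulation, column per lineage
    backgrounds: dict[str, FoldedSFS]
    n_redrawn: int = 0


def null_clr_threshold(demography: "synthsim.ForwardDemography",
                       generations: int, n_sims: int = 1000, L: int = 50_000,
                       mu: float = 3.5e-9,
                       rec_range: tuple[float, float] = (4.7e-8, 2.6e-7),
                       sample_males: int = 10, grid_spacing: int = 1000,
                       seed: int = 0, lineages=None,
                       quantile: float | None = None,
                       initial_state: str = "coalescent") -> CalibrationResult:
    """Simulate neutral regions under the fitted demography and return the
    per-lineage CLR significance threshold (the top CLR value over all
    simulations; set ``quantile`` to use an upper quantile instead).

    Recombination rates are drawn uniformly from ``rec_range`` per region.
    Backgrounds are the folded spectra pooled over all simulated regions
    (per lineage).  Simulations with fewer than 5 polymorphic sites in any
    lineage are re-drawn (counted in the result).
    """
    rng = np.random.default_rng(seed)
    sims = []
    n_redrawn = 0
    while len(sims) < n_sims:
        rec = rng.uniform(*rec_range)
        cfg = synthsim.SimulationConfig(
            region_length_bp=L, mu=mu, rec=rec, generations=generations,
            seed=int(rng.integers(2 ** 31)), demography=demography,
            sample_males=sample_males, initial_state=initial_state)
        m = synthsim.simulate_region(cfg)
        if lineages is None:
            lineages = sorted(set(m.populations))
        ok = True
        for lin in lineages:
            alt, called = m.allele_counts(pop=lin)
            if int(((alt > 0) & (alt < called)).sum()) < 5:
                ok = False
                break
        if not ok:
            n_redrawn += 1
            continue
        sims.append(m)
    backgrounds = {}
    for lin in lineages:
        sfs = None
        for m in sims:
            s = folded_sfs(m, lin)
            sfs = s if sfs is None else sfs + s
        backgrounds[lin] = sfs
    rows = []
    for m in sims:
        row = {}
        for lin in lineages:
            g = clr_scan(m, lin, (m.chrom[0], 0, L), backgrounds[lin],
                         grid_spacing=grid_spacing)
            row[lin] = g.max_clr
        rows.append(row)
    tab = pd.DataFrame(rows)
    if quantile is None:
        thresholds = {lin: float(tab[lin].max()) for lin in lineages}
    else:
        thresholds = {lin: float(tab[lin].quantile(quantile)) for lin in lineages}
    return CalibrationResult(thresholds=thresholds, max_clr=tab,
                             backgrounds=backgrounds, n_redrawn=n_redrawn)


def call_sweeps(grids: dict[str, CLRGrid], thresholds: dict[str, float],
                ed_lineages: tuple[str, str] = ("Ed_north", "Ed_south"),
                ev_lineage: str = "Ev") -> dict:
    """Mark significant grid positions per lineage and classify the region.

    Classification: "Ed-specific" (significant in both Ed lineages, not in
    Ev), "Ev-specific" (significant in Ev only), "shared" (all three),
    otherwise "none".
    """
    lineages = list(grids)
    ref = grids[lineages[0]].positions
    for lin in lineages[1:]:
        if not np.array_equal(grids[lin].positions, ref):
            raise ValueError("CLR grids are not on common coordinates")
    sig = {}
    for lin in lineages:
        g = grids[lin]
        g.threshold = float(thresholds[lin])
        g.significant = g.clr > g.threshold
        sig[lin] = bool(g.significant.any())
    edn, eds = ed_lineages
    if sig.get(edn) and sig.get(eds) and sig.get(ev_lineage):
        cls = "shared"
    elif sig.get(edn) and sig.get(eds):
        cls = "Ed-specific"
    elif sig.get(ev_lineage) and not sig.get(edn) and not sig.get(eds):
        cls = "Ev-specific"
    else:
        cls = "none"
    return {"classification": cls, "significant": sig, "grids": grids}
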