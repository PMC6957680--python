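"""Forward-in-time haplodiploid Wright-Fisher simulation and perfume synthesis.

The genetic simulator models haplodiploid inheritance explicitly: males are
haploid and develop from unfertilised eggs (a male receives a single
recombined maternal gamete), females are diploid (a recombined maternal
gamete plus the father's haplotype, transmitted without recombination since
males are haploid).  Mutation follows the infinite-sites model (continuous
positions internally, integerised on output); recombination happens only in
female meiosis, with a Poisson
number of crossovers per transmitted gamete.  Selection on a sweep allele is
multiplicative: hemizygous males have fitness 1 + s, females 1 + hs
(heterozygous) or 1 + s (homozygous).  Population splits and per-generation
migrant-fraction exchange follow an explicit forward-time demography.

The chemical simulator draws individual perfume profiles as compositions
over shared minor compounds plus one species-specific major compound, with
configurable mean major share, compositional noise and zero-inflation.

The module-level ``orchid_*`` helpers encode the scaled study conditions
used throughout the test-suite and the acceptance analyses (see
docs/methods.md for the scaling rationale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .variantio import HaplotypeMatrix

__all__ = [
    "Split",
    "Migration",
    "ForwardDemography",
    "haplodiploid_ne",
    "SimulationConfig",
    "SweepConfig",
    "SweepLostError",
    "simulate_region",
    "PerfumeSimConfig",
    "PerfumeMatrix",
    "simulate_perfume",
    "orchid_demography",
    "orchid_config",
    "orchid_sweep",
    "ORCHID",
]


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------

@dataclass
class Split:
    """Forward-time population split: at ``generation`` the parent population
    is replaced by two children founded by resampling its individuals."""

    generation: int
    parent: str
    children: tuple[str, str]


@dataclass
class Migration:
    """Symmetric per-generation migrant exchange between two populations.

    Each generation in which both populations exist, a Binomial(N, rate)
    number of individuals of each sex in each population is replaced by
    copies of random individuals from the other (backward-fraction
    replacement)."""

    pops: tuple[str, str]
    rate: float
    start: int = 0
    end: int | None = None


@dataclass
class ForwardDemography:
    """Explicit forward-time demography over named populations.

    ``sizes`` maps every population name (ancestral and derived) to census
    counts (n_males, n_females)."""

    root: str
    sizes: dict[str, tuple[int, int]]
    splits: list[Split] = field(default_factory=list)
    migrations: list[Migration] = field(default_factory=list)

    def __post_init__(self):
        for name, (nm, nf) in self.sizes.items():
            if nm <= 0 or nf <= 0:
                raise ValueError(f"census counts must be positive for {name}")
        for sp in self.splits:
            for child in sp.children:
                if child not in self.sizes:
                    raise ValueError(f"no census size for split child {child}")

    @classmethod
    def single_population(cls, n_males: int, n_females: int,
                          name: str = "pop0") -> "ForwardDemography":
        return cls(root=name, sizes={name: (n_males, n_females)})

    def descendants(self, names) -> set[str]:
        """Closure of ``names`` under the split tree."""
        out = set(names)
        changed = True
        while changed:
            changed = False
            for sp in self.splits:
                if sp.parent in out and not set(sp.children) <= out:
                    out |= set(sp.children)
                    changed = True
        return out


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Forward-simulation configuration.

    ``initial_state`` selects how the root population starts: "monomorphic"
    (all haplotypes identical; reach equilibrium via a long burn-in) or
    "coalescent" (haplotypes drawn from a neutral coalescent at the
    haplodiploid effective size, so the forward phase can start at mutation-
    drift equilibrium without a burn-in).
    """

    region_length_bp: int
    mu: float
    rec: float
    generations: int
    seed: int
    demography: ForwardDemography | None = None
    n_males: int = 50
    n_females: int = 50
    sample_males: int = 10
    chrom: str = "region1"
    initial_state: str = "monomorphic"

    def __post_init__(self):
        if self.region_length_bp <= 0:
            raise ValueError("region_length_bp must be positive")
        if self.mu < 0 or self.rec < 0:
            raise ValueError("mu and rec must be non-negative")
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        if self.demography is None:
            self.demography = ForwardDemography.single_population(
                self.n_males, self.n_females)
        last = max((sp.generation for sp in self.demography.splits), default=0)
        if last >= self.generations:
            raise ValueError("demography split times exceed total generations")
        if self.initial_state not in ("monomorphic", "coalescent"):
            raise ValueError("initial_state must be 'monomorphic' or 'coalescent'")


@dataclass
class SweepConfig:
    s: float
    position_bp: int
    origin_generation: int
    target_populations: tuple[str, ...]
    h: float = 0.5
    max_restarts: int = 100

    def validate(self, cfg: SimulationConfig) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be non-negative")
        if not 0 <= self.h <= 1:
            raise ValueError("dominance must lie in [0, 1]")
        if not 0 <= self.position_bp < cfg.region_length_bp:
            raise ValueError("sweep position outside the region")
        if not 0 <= self.origin_generation < cfg.generations:
            raise ValueError("sweep origin outside the simulated time span")
        known = set(cfg.demography.sizes)
        unknown = set(self.target_populations) - known
        if unknown:
            raise ValueError(f"unknown sweep target population(s): {sorted(unknown)}")


class SweepLostError(RuntimeError):
    """Raised when the beneficial allele is lost more than max_restarts times."""


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

class _PopState:
    __slots__ = ("male", "femA", "femB")

    def __init__(self, male, femA, femB):
        self.male = male    # (Nm, S) uint8
        self.femA = femA    # (Nf, S) uint8
        self.femB = femB    # (Nf, S) uint8

    def arrays(self):
        return (self.male, self.femA, self.femB)


def _recombine(femA, femB, mothers, pos, L, rec, rng):
    """Maternal gametes for the given mother indices (Poisson crossovers).

    Gametes with 0 crossovers copy one parental haplotype; the common 1- and
    2-crossover cases are handled as vectorised segment swaps, anything
    rarer by an explicit parity scan.
    """
    k = len(mothers)
    start = rng.integers(0, 2, size=k)
    gam = np.empty((k, femA.shape[1]), dtype=np.uint8)
    sel0 = start == 0
    gam[sel0] = femA[mothers[sel0]]
    gam[~sel0] = femB[mothers[~sel0]]
    if rec <= 0 or pos.size == 0:
        return gam
    n_x = rng.poisson(rec * L, size=k)
    rec_rows = np.flatnonzero(n_x)
    if len(rec_rows) == 0:
        return gam

    def other_hap(rows):
        return np.where((start[rows] == 0)[:, None],
                        femB[mothers[rows]], femA[mothers[rows]])

    one = rec_rows[n_x[rec_rows] == 1]
    if len(one):
        cuts = rng.uniform(0, L, size=len(one))
        mask = pos[None, :] >= cuts[:, None]
        gam[one] = np.where(mask, other_hap(one), gam[one])
    two = rec_rows[n_x[rec_rows] == 2]
    if len(two):
        c = np.sort(rng.uniform(0, L, size=(len(two), 2)), axis=1)
        mask = (pos[None, :] >= c[:, :1]) & (pos[None, :] < c[:, 1:])
        gam[two] = np.where(mask, other_hap(two), gam[two])
    for i in rec_rows[n_x[rec_rows] >= 3]:
        cuts = np.sort(rng.uniform(0, L, n_x[i]))
        parity = (start[i] + np.searchsorted(cuts, pos)) % 2
        gam[i] = np.where(parity == 0, femA[mothers[i]], femB[mothers[i]])
    return gam


def _fitness_probs(weights):
    tot = weights.sum()
    return weights / tot


def haplodiploid_ne(n_males: int, n_females: int) -> float:
    """X-linked / haplodiploid effective size: 9 Nm Nf / (4 Nm + 2 Nf)."""
    return 9 * n_males * n_females / (4 * n_males + 2 * n_females)


def _coalescent_init(cfg: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium haplotypes for the root population from a neutral
    coalescent at the haplodiploid effective size.

    Recombination is female-limited, so a lineage recombines at 2/3 of the
    per-meiosis rate (the fraction of time an X-like lineage spends in
    females).  Returns (positions, haplotypes) with one row per gene copy
    (n_males + 2 n_females rows).
    """
    nm, nf = cfg.demography.sizes[cfg.demography.root]
    n_copies = nm + 2 * nf
    size = 2 * haplodiploid_ne(nm, nf)  # ploidy-1 size giving E[T2] = 2 Ne_hd
    ts = msprime.sim_ancestry(
        samples=n_copies, ploidy=1,
        population_size=size,
        sequence_length=cfg.region_length_bp,
        recombination_rate=cfg.rec * 2 / 3,
        discrete_genome=False,
        random_seed=int(rng.integers(1, 2 ** 31)))
    ts = msprime.sim_mutations(
        ts, rate=cfg.mu, discrete_genome=False,
        random_seed=int(rng.integers(1, 2 ** 31)))
    if ts.num_sites == 0:
        return np.empty(0, np.float64), np.zeros((n_copies, 0), np.uint8)
    geno = ts.genotype_matrix().T.astype(np.uint8)  # copies x sites
    pos = np.array([s.position for s in ts.sites()])
    keep = geno.max(axis=0) <= 1  # infinite-sites: keep biallelic columns
    return pos[keep], geno[:, keep]


def simulate_region(cfg: SimulationConfig,
                    sweep: SweepConfig | None = None) -> HaplotypeMatrix:
    """Simulate one region forward in time and sample haploid males.

    Returns a :class:`~euscan.variantio.HaplotypeMatrix` of the sampled males
    of every terminal population, containing the sites segregating or fixed
    for the derived allele among the sampled haplotypes.

    Raises
    ------
    SweepLostError
        If the beneficial allele is lost more than ``sweep.max_restarts``
        times (the simulation restarts from the sweep origin on each loss,
        conditioning on establishment).
    """
    if sweep is not None:
        sweep.validate(cfg)
    rng = np.random.default_rng(cfg.seed)
    dem = cfg.demography
    L = cfg.region_length_bp

    def new_pop(nm, nf, S=0):
        return _PopState(np.zeros((nm, S), np.uint8),
                         np.zeros((nf, S), np.uint8),
                         np.zeros((nf, S), np.uint8))

    if cfg.initial_state == "coalescent" and cfg.mu > 0:
        pos, hap = _coalescent_init(cfg, rng)
        nm, nf = dem.sizes[dem.root]
        pops = {dem.root: _PopState(hap[:nm].copy(),
                                    hap[nm:nm + nf].copy(),
                                    hap[nm + nf:nm + 2 * nf].copy())}
    else:
        pops = {dem.root: new_pop(*dem.sizes[dem.root])}
        pos = np.empty(0, np.float64)
    splits = sorted(dem.splits, key=lambda s: s.generation)
    sweep_targets = dem.descendants(sweep.target_populations) if sweep else set()
    sweep_col = -1          # column index of the sweep allele, -1 = not present
    sweep_state = None      # pre-introduction snapshot for establishment conditioning
    sweep_done = False
    restarts = 0
    gen = 0

    def sweep_count() -> int:
        if sweep_col < 0:
            return 0
        tot = 0
        for name, st in pops.items():
            if name in sweep_targets:
                tot += int(st.male[:, sweep_col].sum()
                           + st.femA[:, sweep_col].sum()
                           + st.femB[:, sweep_col].sum())
        return tot

    def introduce_sweep():
        nonlocal pos, pops, sweep_col
        present = [p for p in pops if p in sweep_targets]
        if not present:
            raise ValueError("no sweep target population exists at the origin "
                             "generation")
        target = present[rng.integers(len(present))]
        bp = float(sweep.position_bp)
        while (pos == bp).any():
            bp += 1.0  # nudge off an occupied position (infinite sites)
        col = len(pos)
        pos = np.append(pos, bp)
        for st in pops.values():
            zm = np.zeros((st.male.shape[0], 1), np.uint8)
            zf = np.zeros((st.femA.shape[0], 1), np.uint8)
            st.male = np.concatenate([st.male, zm], axis=1)
            st.femA = np.concatenate([st.femA, zf.copy()], axis=1)
            st.femB = np.concatenate([st.femB, zf.copy()], axis=1)
        st = pops[target]
        nhap = st.male.shape[0] + 2 * st.femA.shape[0]
        pick = int(rng.integers(nhap))
        if pick < st.male.shape[0]:
            st.male[pick, col] = 1
        elif pick < st.male.shape[0] + st.femA.shape[0]:
            st.femA[pick - st.male.shape[0], col] = 1
        else:
            st.femB[pick - st.male.shape[0] - st.femA.shape[0], col] = 1
        sweep_col = col

    while gen < cfg.generations:
        # --- demographic events scheduled at this generation ----------------
        for sp in splits:
            if sp.generation == gen and sp.parent in pops:
                parent = pops.pop(sp.parent)
                nm_p = parent.male.shape[0]
                nf_p = parent.femA.shape[0]
                for child in sp.children:
                    nm, nf = dem.sizes[child]
                    mi = rng.integers(nm_p, size=nm)
                    fi = rng.integers(nf_p, size=nf)
                    pops[child] = _PopState(parent.male[mi].copy(),
                                            parent.femA[fi].copy(),
                                            parent.femB[fi].copy())
        if sweep is not None and gen == sweep.origin_generation and not sweep_done:
            # snapshot the pre-introduction state so a lost allele can be
            # re-seeded from the same starting conditions
            sweep_state = ({k: _PopState(*map(np.copy, v.arrays()))
                            for k, v in pops.items()}, pos.copy())
            introduce_sweep()

        # --- reproduction ----------------------------------------------------
        new_pops: dict[str, _PopState] = {}
        mut_jobs = []  # (state, attr, n_rows) for mutation assignment
        for name, st in pops.items():
            nm, nf = dem.sizes[name]
            selected = sweep is not None and name in sweep_targets and sweep_col >= 0
            if selected:
                g_f = st.femA[:, sweep_col].astype(np.int64) + st.femB[:, sweep_col]
                w_f = np.choose(g_f, [1.0, 1.0 + sweep.h * sweep.s, 1.0 + sweep.s])
                w_m = np.where(st.male[:, sweep_col] > 0, 1.0 + sweep.s, 1.0)
                pf, pm = _fitness_probs(w_f), _fitness_probs(w_m)
            else:
                pf = pm = None
            nf_cur = st.femA.shape[0]
            nm_cur = st.male.shape[0]
            moms_m = rng.choice(nf_cur, size=nm, p=pf)
            moms_f = rng.choice(nf_cur, size=nf, p=pf)
            dads_f = rng.choice(nm_cur, size=nf, p=pm)
            male_new = _recombine(st.femA, st.femB, moms_m, pos, L, cfg.rec, rng)
            femA_new = _recombine(st.femA, st.femB, moms_f, pos, L, cfg.rec, rng)
            femB_new = st.male[dads_f].copy()
            new_pops[name] = _PopState(male_new, femA_new, femB_new)

        # --- mutation ---------------------------------------------------------
        if cfg.mu > 0:
            rows = []
            for name, st in new_pops.items():
                for arr in st.arrays():
                    rows.append(arr)
            counts = [rng.poisson(cfg.mu * L, size=a.shape[0]) for a in rows]
            total = int(sum(c.sum() for c in counts))
            if total:
                newpos = rng.uniform(0, L, size=total)
                # append one zero column per new mutation (columns stay in
                # insertion order; positions are sorted only at output)
                carrier = np.concatenate(
                    [np.repeat(np.arange(a.shape[0]), c) + off
                     for (a, c, off) in zip(rows, counts,
                                            np.cumsum([0] + [a.shape[0] for a in rows])[:-1])])
                offs = np.cumsum([0] + [a.shape[0] for a in rows])
                blocks = []
                for bi, a in enumerate(rows):
                    block = np.zeros((a.shape[0], total), np.uint8)
                    sel = (carrier >= offs[bi]) & (carrier < offs[bi + 1])
                    block[carrier[sel] - offs[bi], np.flatnonzero(sel)] = 1
                    blocks.append(block)
                i = 0
                for st in new_pops.values():
                    st.male = np.concatenate([st.male, blocks[i]], axis=1)
                    st.femA = np.concatenate([st.femA, blocks[i + 1]], axis=1)
                    st.femB = np.concatenate([st.femB, blocks[i + 2]], axis=1)
                    i += 3
                pos = np.concatenate([pos, newpos])
        pops = new_pops

        # --- migration ---------------------------------------------------------
        for mig in dem.migrations:
            a, b = mig.pops
            if a not in pops or b not in pops or mig.rate <= 0:
                continue
            if gen < mig.start or (mig.end is not None and gen >= mig.end):
                continue
            snapshot = {n: _PopState(*map(np.copy, pops[n].arrays())) for n in (a, b)}
            for recv, src in ((a, b), (b, a)):
                r, s = pops[recv], snapshot[src]
                nmig_m = rng.binomial(r.male.shape[0], mig.rate)
                if nmig_m:
                    tgt = rng.choice(r.male.shape[0], nmig_m, replace=False)
                    origin = rng.integers(s.male.shape[0], size=nmig_m)
                    r.male[tgt] = s.male[origin]
                nmig_f = rng.binomial(r.femA.shape[0], mig.rate)
                if nmig_f:
                    tgt = rng.choice(r.femA.shape[0], nmig_f, replace=False)
                    origin = rng.integers(s.femA.shape[0], size=nmig_f)
                    r.femA[tgt] = s.femA[origin]
                    r.femB[tgt] = s.femB[origin]

        # --- sweep loss (restart from the pre-introduction snapshot) ----------
        if sweep is not None and sweep_col >= 0 and not sweep_done:
            if sweep_count() == 0:
                restarts += 1
                if restarts > sweep.max_restarts:
                    raise SweepLostError(
                        f"sweep allele lost {restarts} times (> max_restarts)")
                saved, saved_pos = sweep_state
                pops = {k: _PopState(*map(np.copy, v.arrays()))
                        for k, v in saved.items()}
                pos = saved_pos.copy()
                sweep_col = -1
                gen = sweep.origin_generation
                continue  # re-enters the loop at the origin generation

        # --- compaction: drop columns lost or globally fixed -------------------
        if pos.size:
            tot_hap = sum(a.shape[0] for st in pops.values() for a in st.arrays())
            cnt = np.zeros(pos.size, np.int64)
            for st in pops.values():
                for a in st.arrays():
                    cnt += a.sum(axis=0, dtype=np.int64)
            keep = (cnt > 0) & (cnt < tot_hap)
            if sweep_col >= 0:
                if keep[sweep_col]:
                    sweep_col = int(keep[:sweep_col].sum())
                else:  # globally fixed: sweep complete (loss was handled above)
                    sweep_col = -1
                    sweep_done = True
                    sweep_state = None
            if not keep.all():
                pos = pos[keep]
                for st in pops.values():
                    st.male = st.male[:, keep]
                    st.femA = st.femA[:, keep]
                    st.femB = st.femB[:, keep]
        gen += 1

    # --- sample haploid males ------------------------------------------------
    calls, samples, poplabels = [], [], []
    for name in sorted(pops):
        st = pops[name]
        nm = st.male.shape[0]
        k = min(cfg.sample_males, nm)
        idx = rng.choice(nm, size=k, replace=False)
        calls.append(st.male[idx])
        samples += [f"{name}_m{i}" for i in range(k)]
        poplabels += [name] * k
    calls = np.concatenate(calls, axis=0).astype(np.int8)
    seg = calls.sum(axis=0) > 0
    calls, outpos = calls[:, seg], pos[seg]
    order = np.argsort(outpos, kind="stable")
    calls, outpos = calls[:, order], outpos[order]
    outpos = np.floor(outpos).astype(np.int64)
    uniq = np.ones(len(outpos), bool)
    uniq[1:] = np.diff(outpos) > 0  # integerisation collisions: keep first
    calls, outpos = calls[:, uniq], outpos[uniq]
    return HaplotypeMatrix(
        chrom=np.array([cfg.chrom] * len(outpos), dtype=object),
        pos=outpos, calls=calls, samples=samples,
        populations=np.array(poplabels, dtype=object))


# ---------------------------------------------------------------------------
# scaled orchid-bee study conditions
# ---------------------------------------------------------------------------

#: Scaled forward-simulation study conditions.  Census and rate parameters
#: are chosen so that per-bp pairwise diversity (~3e-3), interspecific and
#: intraspecific differentiation (Fst ~ 0.19 and ~0.03), and the physical
#: extent of a hard-sweep footprint (tens of kb at s = 0.1, 2*Ne*s = 75) are
#: all at realistic magnitudes while one region simulates in seconds; see
#: docs/methods.md for the scaling rationale.
ORCHID = {
    "n_males": 250,         # per population
    "n_females": 250,       # Ne_hd = 9*Nm*Nf/(4*Nm+2*Nf) = 375
    "mu": 2e-6,             # per bp per generation (scaled; 4*Ne_hd*mu ~ 3e-3)
    "rec": 1e-6,            # per bp per female meiosis (scaled)
    "rec_range": (7e-7, 1.4e-6),
    "t_split1": 5,          # ancestral -> (Ev, Ed); root starts at equilibrium
    "t_sweep": 6,           # sweep allele origin (in Ed)
    "t_split2": 120,        # Ed -> (Ed_north, Ed_south)
    "generations": 140,
    "sample_males": 10,
    "s": 0.1,
    "h": 0.6,
}


def orchid_demography(two_level: bool = True,
                      migrations: list[Migration] | None = None) -> ForwardDemography:
    """The three-population scan demography at scaled study conditions:
    ancestral -> (Ev, Ed) at t_split1, Ed -> (Ed_north, Ed_south) at t_split2."""
    nm, nf = ORCHID["n_males"], ORCHID["n_females"]
    sizes = {p: (nm, nf) for p in
             ("anc", "Ev", "Ed", "Ed_north", "Ed_south")}
    splits = [Split(ORCHID["t_split1"], "anc", ("Ev", "Ed"))]
    if two_level:
        splits.append(Split(ORCHID["t_split2"], "Ed", ("Ed_north", "Ed_south")))
    return ForwardDemography(root="anc", sizes=sizes, splits=splits,
                             migrations=migrations or [])


def orchid_config(region_length_bp: int, seed: int, rec: float | None = None,
                  **kw) -> SimulationConfig:
    """A SimulationConfig at the scaled orchid study conditions."""
    return SimulationConfig(
        region_length_bp=region_length_bp,
        mu=kw.pop("mu", ORCHID["mu"]),
        rec=ORCHID["rec"] if rec is None else rec,
        generations=kw.pop("generations", ORCHID["generations"]),
        seed=seed,
        demography=kw.pop("demography", orchid_demography()),
        sample_males=kw.pop("sample_males", ORCHID["sample_males"]),
        initial_state=kw.pop("initial_state", "coalescent"),
        **kw)


def orchid_sweep(position_bp: int, targets=("Ed",), s: float | None = None) -> SweepConfig:
    """A hard sweep at the scaled study conditions (defaults to the Ed branch)."""
    return SweepConfig(s=ORCHID["s"] if s is None else s, position_bp=position_bp,
                       origin_generation=ORCHID["t_sweep"],
                       target_populations=tuple(targets), h=ORCHID["h"])


# ---------------------------------------------------------------------------
# perfume simulation
# ---------------------------------------------------------------------------

@dataclass
class PerfumeSimConfig:
    """Two-species perfume matrix generator configuration.

    Each individual's profile is a composition over ``n_shared_compounds``
    minor compounds shared between species plus exactly one species-specific
    major compound whose mean relative share is set per species (defaults:
    0.55 for species A's major, 0.37 for species B's).  ``concentration``
    controls Beta/Dirichlet compositional noise (larger = less variable);
    ``zero_inflation`` is the probability that a minor compound goes
    undetected in an individual (applied before renormalisation).
    """

    n_individuals: tuple[int, int] = (20, 20)
    n_shared_compounds: int = 30
    major_means: tuple[float, float] = (0.55, 0.37)
    concentration: float = 30.0
    zero_inflation: float = 0.1
    species: tuple[str, str] = ("Ed", "Ev")
    seed: int = 0

    def validate(self):
        if self.n_shared_compounds < 1:
            raise ValueError("need at least one shared compound")
        if not all(0 < m < 1 for m in self.major_means):
            raise ValueError("major-compound means must lie in (0, 1)")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if min(self.n_individuals) < 1:
            raise ValueError("need at least one individual per species")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class PerfumeMatrix:
    """Individuals x compounds abundance table with species labels."""

    abundances: pd.DataFrame   # rows = individuals, columns = compounds
    species: np.ndarray        # per-individual species label
    normalized: bool = True

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype=object)
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.normalized:
            tot = self.abundances.sum(axis=1).to_numpy()
            if not np.allclose(tot, 1.0, atol=1e-9):
                raise ValueError("normalized matrix rows must sum to 1")

    def to_tsv(self, path) -> None:
        out = self.abundances.copy()
        out.insert(0, "species", self.species)
        out.to_csv(path, sep="\t", index_label="individual")

    @classmethod
    def from_tsv(cls, path, normalized=True) -> "PerfumeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        species = df.pop("species").to_numpy()
        return cls(df, species, normalized=normalized)


def simulate_perfume(cfg: PerfumeSimConfig) -> PerfumeMatrix:
    """Draw a two-species perfume matrix with lineage-specific major compounds.

    The species-specific major compound share is Beta-distributed around the
    configured mean; the remainder is split across shared minor compounds by
    a symmetric Dirichlet.  Minor compounds drop out independently with the
    zero-inflation probability, after which each profile renormalises to 1.
    The major compound of one species is identically zero in the other.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    minors = [f"minor_{i + 1:02d}" for i in range(cfg.n_shared_compounds)]
    majors = [f"major_{sp}" for sp in cfg.species]
    cols = majors + minors
    rows, labels = [], []
    for si, sp in enumerate(cfg.species):
        mean = cfg.major_means[si]
        a, b = cfg.concentration * mean, cfg.concentration * (1 - mean)
        for _ in range(cfg.n_individuals[si]):
            major_share = rng.beta(a, b)
            mino = rng.dirichlet(np.full(cfg.n_shared_compounds, 2.0))
            mino *= (1.0 - major_share)
            if cfg.zero_inflation > 0:
                drop = rng.random(cfg.n_shared_compounds) < cfg.zero_inflation
                mino[drop] = 0.0
            profile = np.zeros(len(cols))
            profile[si] = major_share
            profile[2:] = mino
            tot = profile.sum()
            if tot == 0:
                profile[si] = 1.0
                tot = 1.0
            rows.append(profile / tot)
            labels.append(sp)
    df = pd.DataFrame(rows, columns=cols,
                      index=[f"{sp}_{i + 1:03d}" for i, sp in enumerate(labels)])
    return PerfumeMatrix(df, np.array(labels, dtype=object), normalized=True)
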