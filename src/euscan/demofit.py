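"""Three-population demographic model space, joint-AFS fitting and AIC ranking.

The model space covers all 96 combinations of six ordered three-population
branching patterns with 16 bidirectional gene-flow configurations.  A
topology is the choice of the first-diverging (outgroup) population (3
ways) times which of the two sister populations' size parameters continues
through the internal branch between the two splits (2 ways, the "budding"
ambiguity).  Gene flow is any subset of four bidirectional vertices: m1-m3
between the three terminal population pairs (active while all terminals
coexist) and m4 between the two lineages extant between the splits.

Every model has a single static size per terminal population (n1, n2, n3,
relative to the ancestral size of 1), two split times (t1 >= t2), and one
rate per active migration vertex — 5 to 9 free parameters.

The expected joint allele-frequency spectrum is estimated by Monte-Carlo
coalescent simulation of unlinked genealogies (msprime, branch-length mode),
the likelihood is the multinomial composite likelihood of the observed
spectrum given the model spectrum (the overall scale is profiled out), and
models are compared by AIC / Akaike weights.

Units: times are in N_ref generations of the ancestral population
(haploid-lineage coalescent units: two lineages in a population of relative
size nu coalesce at rate 1/nu per time unit); migration rates are per
lineage per time unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import msprime
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "ModelSpec",
    "ModelParams",
    "PARAM_BOUNDS",
    "JointAFS",
    "FitResult",
    "enumerate_models",
    "expected_afs",
    "simulate_joint_afs",
    "composite_loglik",
    "fit_model",
    "model_selection",
]

MIGRATION_VERTICES = ("m1", "m2", "m3", "m4")

#: parameter bounds: relative sizes, split times, migration rates
PARAM_BOUNDS = {
    "size": (0.001, 100.0),
    "time": (0.0, 10.0),
    "migration": (0.0, 20.0),
}


# ---------------------------------------------------------------------------
# model space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One demographic model structure.

    ``topology`` is 1..6: outgroup index = (topology - 1) // 2 into the
    population tuple, and (topology - 1) % 2 selects which sister
    population's size parameter extends through the internal branch.
    ``migration`` is the subset of active vertices ("m1".."m4").
    """

    topology: int
    migration: tuple[str, ...] = ()
    populations: tuple[str, str, str] = ("Ev", "Ed_north", "Ed_south")

    def __post_init__(self):
        if not 1 <= self.topology <= 6:
            raise ValueError("topology code must be 1..6")
        bad = set(self.migration) - set(MIGRATION_VERTICES)
        if bad:
            raise ValueError(f"unknown migration vertices: {sorted(bad)}")

    @property
    def outgroup_index(self) -> int:
        return (self.topology - 1) // 2

    @property
    def size_carrier_index(self) -> int:
        """Index (0 or 1, within the sister pair) of the population whose
        size parameter continues through the internal branch."""
        return (self.topology - 1) % 2

    @property
    def sister_indices(self) -> tuple[int, int]:
        return tuple(i for i in range(3) if i != self.outgroup_index)

    @property
    def k(self) -> int:
        """Free-parameter count: 3 sizes + 2 times + active migration rates."""
        return 5 + len(self.migration)

    def describe(self) -> str:
        o = self.populations[self.outgroup_index]
        s = [self.populations[i] for i in self.sister_indices]
        carrier = s[self.size_carrier_index]
        mig = "+".join(self.migration) if self.migration else "none"
        return (f"(({s[0]},{s[1]}),{o}) internal-branch size from {carrier}, "
                f"gene flow: {mig}")


@dataclass
class ModelParams:
    """Parameter values for a ModelSpec (see module docstring for units)."""

    sizes: tuple[float, float, float]
    t1: float
    t2: float
    migration: dict[str, float] = field(default_factory=dict)

    def validate(self, spec: ModelSpec | None = None) -> None:
        lo, hi = PARAM_BOUNDS["size"]
        if not all(lo <= n <= hi for n in self.sizes):
            raise ValueError(f"sizes out of bounds {PARAM_BOUNDS['size']}")
        tlo, thi = PARAM_BOUNDS["time"]
        if not (tlo <= self.t2 <= self.t1 <= thi):
            raise ValueError("need 0 <= t2 <= t1 <= 10")
        mlo, mhi = PARAM_BOUNDS["migration"]
        for v, m in self.migration.items():
            if not mlo <= m <= mhi:
                raise ValueError(f"migration {v} out of bounds")
        if spec is not None and set(self.migration) != set(spec.migration):
            raise ValueError("migration rates do not match the model's vertices")


def enumerate_models(populations=("Ev", "Ed_north", "Ed_south")) -> list[ModelSpec]:
    """All 96 model structures in deterministic canonical order:
    topology 1..6, migration subsets by size then lexicographic order."""
    subsets = [()]
    for r in range(1, 5):
        subsets += list(combinations(MIGRATION_VERTICES, r))
    return [ModelSpec(topology=t, migration=sub, populations=tuple(populations))
            for t in range(1, 7) for sub in subsets]


# ---------------------------------------------------------------------------
# joint AFS container
# ---------------------------------------------------------------------------

@dataclass
class JointAFS:
    """Three-population joint allele-frequency spectrum.

    ``counts[i, j, k]`` is the number (or expected proportion) of sites with
    derived-allele counts i, j, k in the three samples.  The all-ancestral
    and all-derived corners are masked.
    """

    counts: np.ndarray
    sample_sizes: tuple[int, int, int]
    populations: tuple[str, str, str] = ("Ev", "Ed_north", "Ed_south")
    folded: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        expect = tuple(n + 1 for n in self.sample_sizes)
        if self.counts.shape != expect:
            raise ValueError(f"spectrum shape {self.counts.shape} != {expect}")
        if (self.counts < 0).any():
            raise ValueError("negative spectrum entry")

    @property
    def mask(self) -> np.ndarray:
        """True where entries are valid (polymorphic overall)."""
        m = np.ones(self.counts.shape, dtype=bool)
        m[0, 0, 0] = False
        m[-1, -1, -1] = False
        return m

    @property
    def total(self) -> float:
        return float(self.counts[self.mask].sum())

    def normalized(self) -> np.ndarray:
        """Masked-normalised proportions."""
        out = np.where(self.mask, self.counts, 0.0)
        tot = out.sum()
        if tot == 0:
            raise ValueError("empty spectrum")
        return out / tot

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# joint AFS; sample sizes: %s; populations: %s; folded: %s\n"
                     % (",".join(map(str, self.sample_sizes)),
                        ",".join(self.populations), self.folded))
            fh.write(" ".join(repr(float(v)) for v in self.counts.ravel()) + "\n")

    @classmethod
    def from_text(cls, path) -> "JointAFS":
        with open(path) as fh:
            header = fh.readline()
            body = fh.readline()
        fields = dict(part.strip().split(": ") for part in header.split(";")
                      if ": " in part)
        sizes = tuple(int(x) for x in fields["sample sizes"].split(","))
        pops = tuple(fields["populations"].split(","))
        folded = fields["folded"].strip() == "True"
        counts = np.array([float(x) for x in body.split()])
        return cls(counts.reshape([n + 1 for n in sizes]), sizes, pops, folded)


# ---------------------------------------------------------------------------
# expected AFS by Monte-Carlo coalescent
# ---------------------------------------------------------------------------

def _build_demography(spec: ModelSpec, params: ModelParams) -> msprime.Demography:
    p = spec.populations
    o = spec.outgroup_index
    s0, s1 = spec.sister_indices
    carrier = (s0, s1)[spec.size_carrier_index]
    dem = msprime.Demography()
    for i, name in enumerate(p):
        dem.add_population(name=name, initial_size=params.sizes[i])
    dem.add_population(name="mid", initial_size=params.sizes[carrier])
    dem.add_population(name="anc", initial_size=1.0)
    t2 = max(params.t2, 1e-9)
    t1 = max(params.t1, t2 * (1 + 1e-9))
    dem.add_population_split(time=t2, derived=[p[s0], p[s1]], ancestral="mid")
    dem.add_population_split(time=t1, derived=[p[o], "mid"], ancestral="anc")
    pair_by_vertex = {"m1": (p[0], p[1]), "m2": (p[0], p[2]), "m3": (p[1], p[2])}
    for v, rate in params.migration.items():
        if rate <= 0:
            continue
        if v == "m4":
            dem.add_symmetric_migration_rate_change(
                time=t2, populations=[p[o], "mid"], rate=rate)
        else:
            dem.set_symmetric_migration_rate(pair_by_vertex[v], rate)
            dem.add_symmetric_migration_rate_change(
                time=t2, populations=pair_by_vertex[v], rate=0.0)
    dem.sort_events()
    return dem


def expected_afs(spec: ModelSpec, params: ModelParams,
                 sample_sizes: tuple[int, int, int] = (10, 10, 10),
                 mc_reps: int = 300, seed: int = 1) -> JointAFS:
    """Expected joint AFS under the model, by Monte-Carlo coalescent.

    Simulates ``mc_reps`` independent (unlinked) genealogies and accumulates
    branch lengths by the number of sampled lineages subtended in each
    population; the result is proportional to the expected spectrum of
    unlinked polymorphic sites and is returned masked-normalised.
    """
    params.validate(spec)
    dem = _build_demography(spec, params)
    samples = {name: n for name, n in zip(spec.populations, sample_sizes)}
    afs = np.zeros([n + 1 for n in sample_sizes])
    reps = msprime.sim_ancestry(samples=samples, demography=dem, ploidy=1,
                                num_replicates=mc_reps,
                                random_seed=max(int(seed) % (2 ** 31), 1))
    sets = None
    for ts in reps:
        if sets is None:
            sets = [ts.samples(population=i) for i in range(3)]
        afs += ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True,
            span_normalise=False)
    out = JointAFS(afs, tuple(sample_sizes), spec.populations)
    out.counts = out.normalized()
    return out


def simulate_joint_afs(spec: ModelSpec, params: ModelParams, n_sites: int,
                       sample_sizes: tuple[int, int, int] = (10, 10, 10),
                       seed: int = 1, mc_reps: int = 3000) -> JointAFS:
    """A synthetic observed spectrum: ``n_sites`` unlinked segregating sites
    drawn multinomially from a high-precision expected spectrum."""
    rng = np.random.default_rng(seed)
    exp = expected_afs(spec, params, sample_sizes, mc_reps=mc_reps,
                       seed=int(rng.integers(1, 2 ** 31)))
    p = exp.normalized().ravel()
    draw = rng.multinomial(n_sites, p / p.sum()).reshape(exp.counts.shape)
    return JointAFS(draw.astype(float), tuple(sample_sizes), spec.populations)


# ---------------------------------------------------------------------------
# likelihood, fitting, selection
# ---------------------------------------------------------------------------

def composite_loglik(observed: JointAFS, expected: JointAFS | np.ndarray,
                     eps: float = 1e-12) -> float:
    """Multinomial composite log-likelihood sum(obs * ln p_model).

    Model proportions are floored at ``eps`` and renormalised over the
    unmasked entries, so zero-probability cells cannot produce -inf.
    """
    exp_counts = expected.counts if isinstance(expected, JointAFS) else expected
    if exp_counts.shape != observed.counts.shape:
        raise ValueError("spectrum shape mismatch")
    mask = observed.mask
    p = np.where(mask, np.maximum(exp_counts, eps), 0.0)
    p = p / p.sum()
    obs = np.where(mask, observed.counts, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnp = np.where(mask, np.log(np.where(mask, p, 1.0)), 0.0)
    return float((obs * lnp).sum())


@dataclass
class FitResult:
    spec: ModelSpec
    params: ModelParams
    loglik: float            # mean of the replicate likelihood estimates
    logliks: list[float]     # the replicate estimates at the best parameters
    restart_optima: list[float]
    k: int
    aic: float
    n_restarts: int
    delta_aic: float | None = None
    akaike_weight: float | None = None


def _pack(params: ModelParams, spec: ModelSpec) -> np.ndarray:
    z = [np.log(n) for n in params.sizes]
    z.append(np.log(max(params.t1, 1e-6)))
    z.append(logit(np.clip(params.t2 / max(params.t1, 1e-12), 1e-6, 1 - 1e-6)))
    for v in spec.migration:
        z.append(np.log(max(params.migration[v], 1e-6)))
    return np.array(z)


def _unpack(z: np.ndarray, spec: ModelSpec) -> ModelParams:
    slo, shi = PARAM_BOUNDS["size"]
    tlo, thi = PARAM_BOUNDS["time"]
    mlo, mhi = PARAM_BOUNDS["migration"]
    sizes = tuple(float(np.clip(np.exp(v), slo, shi)) for v in z[:3])
    t1 = float(np.clip(np.exp(z[3]), 1e-4, thi))
    t2 = float(np.clip(expit(z[4]) * t1, tlo, t1))
    mig = {v: float(np.clip(np.exp(z[5 + i]), mlo, mhi))
           for i, v in enumerate(spec.migration)}
    return ModelParams(sizes=sizes, t1=t1, t2=t2, migration=mig)


def _random_start(rng, spec: ModelSpec) -> ModelParams:
    sizes = tuple(float(np.exp(rng.uniform(np.log(0.1), np.log(10)))) for _ in range(3))
    t1 = float(np.exp(rng.uniform(np.log(0.05), np.log(5.0))))
    t2 = t1 * float(rng.uniform(0.05, 0.95))
    mig = {v: float(np.exp(rng.uniform(np.log(0.01), np.log(5.0))))
           for v in spec.migration}
    return ModelParams(sizes=sizes, t1=t1, t2=t2, migration=mig)


def fit_model(observed: JointAFS, spec: ModelSpec, restarts: int = 5,
              seed: int = 0, mc_reps: int = 150, maxiter: int = 80,
              n_candidate_starts: int = 8, final_mc_reps: int = 2000) -> FitResult:
    """Fit one model to an observed joint AFS by bounded derivative-free
    optimisation (Nelder-Mead on transformed parameters) from ``restarts``
    starting points.

    Each restart screens ``n_candidate_starts`` random draws (the first
    restart also screens a neutral-ish default) and polishes the best with
    Nelder-Mead; the Monte-Carlo seed of the expected-AFS engine is fixed
    within a restart (common random numbers), so each objective is
    deterministic.  The likelihood of the best parameters is then
    re-estimated ``restarts`` times at ``final_mc_reps`` genealogies and
    the mean of these replicate estimates is reported and used for the AIC
    — fitting all candidate models with the same ``seed`` makes the
    replicate seeds, and hence the model comparison, share random numbers.
    """
    if observed.total <= 0:
        raise ValueError("observed spectrum is empty")
    rng = np.random.default_rng(seed)
    best_v, best_p, optima = -np.inf, None, []
    failures = 0
    for r in range(restarts):
        mc_seed = int(rng.integers(1, 2 ** 31))

        def nll(z):
            p = _unpack(z, spec)
            exp = expected_afs(spec, p, observed.sample_sizes,
                               mc_reps=mc_reps, seed=mc_seed)
            return -composite_loglik(observed, exp)

        cands = [_random_start(rng, spec) for _ in range(n_candidate_starts)]
        if r == 0:
            cands[0] = ModelParams(sizes=(1.0, 1.0, 1.0), t1=1.0, t2=0.3,
                                   migration={v: 0.5 for v in spec.migration})
        try:
            zs = [_pack(c, spec) for c in cands]
            scores = [nll(z) for z in zs]
            z0 = zs[int(np.argmin(scores))]
            # explicit initial simplex: scipy's default degenerates when a
            # coordinate is exactly zero (e.g. log-size of 1.0)
            simplex = np.vstack([z0] + [z0 + 0.6 * e
                                        for e in np.eye(len(z0))])
            res = minimize(nll, z0, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 1e-3,
                                    "fatol": 0.05, "adaptive": True,
                                    "initial_simplex": simplex})
        except Exception:
            failures += 1
            continue
        lnl = -float(res.fun)
        optima.append(lnl)
        if lnl > best_v:
            best_v, best_p = lnl, _unpack(res.x, spec)
    if best_p is None:
        raise RuntimeError(f"optimizer failed on all {restarts} restarts")
    final_seeds = [int(rng.integers(1, 2 ** 31)) for _ in range(restarts)]
    finals = [composite_loglik(
        observed, expected_afs(spec, best_p, observed.sample_sizes,
                               mc_reps=final_mc_reps, seed=s))
        for s in final_seeds]
    mean_lnl = float(np.mean(finals))
    aic = 2 * spec.k - 2 * mean_lnl
    return FitResult(spec=spec, params=best_p, loglik=mean_lnl, logliks=finals,
                     restart_optima=optima, k=spec.k, aic=aic,
                     n_restarts=restarts - failures)


def model_selection(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits by AIC; attach delta-AIC and Akaike weights.

    weight_i = exp(-dAIC_i / 2) / sum_j exp(-dAIC_j / 2).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2)
    w = w / w.sum()
    for f, d, wi in zip(fits, delta, w):
        f.delta_aic = float(d)
        f.akaike_weight = float(wi)
    rows = [{
        "topology": f.spec.topology,
        "migration": "+".join(f.spec.migration) if f.spec.migration else "none",
        "description": f.spec.describe(),
        "k": f.k,
        "loglik": f.loglik,
        "aic": f.aic,
        "delta_aic": f.delta_aic,
        "akaike_weight": f.akaike_weight,
    } for f in fits]
    return (pd.DataFrame(rows).sort_values("aic").reset_index(drop=True))
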