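"""Window statistics against brute-force pairwise oracles, the
net-differentiation tracks, outlier peaks, f4 and permutation tests."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from euscan import scanstats as st
from euscan.variantio import make_windows

from tests.conftest import toy_matrix

W = ("s1", 0, 100)


def pairwise_pi_oracle(calls, L):
    """Mean pairwise Hamming distance per bp over complete pairs."""
    n = len(calls)
    tot = cnt = 0
    for i, j in combinations(range(n), 2):
        ok = (calls[i] != -1) & (calls[j] != -1)
        tot += (calls[i][ok] != calls[j][ok]).sum()
        cnt += 1
    return tot / cnt / L


def cross_pi_oracle(callsA, callsB, L):
    tot = cnt = 0
    for a in callsA:
        for b in callsB:
            ok = (a != -1) & (b != -1)
            tot += (a[ok] != b[ok]).sum()
            cnt += 1
    return tot / cnt / L


# ---------------------------------------------------------------------------
# pi / dxy / fst
# ---------------------------------------------------------------------------

def test_pi_two_haploids_one_difference():
    m = toy_matrix([[0], [1]], positions=[5])
    assert st.window_pi(m, "p1", W) == pytest.approx(1 / 100)


def test_pi_monomorphic_is_zero_and_empty_is_nan():
    m = toy_matrix([[0, 0], [0, 0]], positions=[5, 6])
    assert st.window_pi(m, "p1", W) == 0.0
    single = toy_matrix([[0]], positions=[5])
    assert np.isnan(st.window_pi(single, "p1", W))


def test_pi_matches_pairwise_oracle_no_missing(rng):
    calls = rng.integers(0, 2, size=(6, 30)).astype(np.int8)
    m = toy_matrix(calls, positions=np.arange(30))
    assert st.window_pi(m, "p1", W) == pytest.approx(
        pairwise_pi_oracle(calls, 100), abs=1e-12)


def test_dxy_examples_and_oracle(rng):
    a = toy_matrix([[1], [1], [0], [0]], pops=["A", "A", "B", "B"], positions=[3])
    assert st.window_dxy(a, "A", "B", W) == pytest.approx(1 / 100)
    mono = toy_matrix([[0], [0], [0], [0]], pops=["A", "A", "B", "B"], positions=[3])
    assert st.window_dxy(mono, "A", "B", W) == 0.0
    calls = rng.integers(0, 2, size=(8, 40)).astype(np.int8)
    m = toy_matrix(calls, pops=["A"] * 4 + ["B"] * 4, positions=np.arange(40))
    assert st.window_dxy(m, "A", "B", W) == pytest.approx(
        cross_pi_oracle(calls[:4], calls[4:], 100), abs=1e-12)
    assert st.window_dxy(m, "A", "B", W) == st.window_dxy(m, "B", "A", W)


def hudson_fst_oracle(callsA, callsB):
    hw = hb = 0.0
    for j in range(callsA.shape[1]):
        a, b = callsA[:, j], callsB[:, j]
        a, b = a[a != -1], b[b != -1]
        na, nb = len(a), len(b)
        if na < 2 or nb < 2:
            continue
        pa, pb = a.mean(), b.mean()
        hw += 0.5 * (na / (na - 1) * 2 * pa * (1 - pa)
                     + nb / (nb - 1) * 2 * pb * (1 - pb))
        hb += pa * (1 - pb) + pb * (1 - pa)
    return 1 - hw / hb if hb > 0 else np.nan


def test_fst_reciprocally_fixed_is_one():
    m = toy_matrix([[1], [1], [0], [0]], pops=["A", "A", "B", "B"], positions=[3])
    assert st.window_fst(m, "A", "B", W) == pytest.approx(1.0)


def test_fst_equal_frequencies_near_zero(rng):
    # 10 per population, both exactly at p = 0.5: the unbiased Hudson
    # estimator gives 1 - (n/(n-1)) = -1/9, comfortably below 0.05
    calls = np.array([[0, 1] * 5 + [1, 0] * 5] * 12, dtype=np.int8).T[:20, :12]
    m = toy_matrix(calls, pops=["A"] * 10 + ["B"] * 10, positions=np.arange(12))
    f = st.window_fst(m, "A", "B", W)
    assert f <= 0.05
    assert f == pytest.approx(1 - 10 / 9, abs=1e-12)


def test_fst_matches_oracle(rng):
    calls = (rng.random((12, 50)) < np.r_[np.full(25, 0.2), np.full(25, 0.6)]
             ).astype(np.int8)
    m = toy_matrix(calls, pops=["A"] * 6 + ["B"] * 6, positions=np.arange(50))
    assert st.window_fst(m, "A", "B", W) == pytest.approx(
        hudson_fst_oracle(calls[:6], calls[6:]), abs=1e-12)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def test_window_ld_examples():
    col = np.array([0, 1, 0, 1, 1, 0], dtype=np.int8)
    m = toy_matrix(np.column_stack([col, col]), positions=[0, 2000])
    assert st.window_ld(m, "p1", ("s1", 0, 5000)) == pytest.approx(1.0)
    m2 = toy_matrix(np.column_stack([col, col]), positions=[0, 500])
    assert np.isnan(st.window_ld(m2, "p1", ("s1", 0, 5000)))


def test_window_ld_matches_allpairs_oracle(rng):
    calls = rng.integers(0, 2, size=(10, 10)).astype(np.int8)
    pos = np.arange(10) * 1500
    m = toy_matrix(calls, positions=pos)
    got = st.window_ld(m, "p1", ("s1", 0, 20_000))
    vals = []
    for i, j in combinations(range(10), 2):
        if pos[j] - pos[i] < 1000:
            continue
        x, y = calls[:, i].astype(float), calls[:, j].astype(float)
        if x.var() == 0 or y.var() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        vals.append(r * r)
    assert got == pytest.approx(np.mean(vals), abs=1e-12)


# ---------------------------------------------------------------------------
# tracks, outliers, correlations
# ---------------------------------------------------------------------------

def make_track_table(rng, n=200):
    return pd.DataFrame({
        "chrom": ["s1"] * n,
        "start": np.arange(n) * 50_000,
        "end": (np.arange(n) + 1) * 50_000,
        "pi_Ev": rng.random(n) * 1e-3,
        "pi_Ed": rng.random(n) * 1e-3,
        "fst_inter": rng.random(n),
        "fst_intra": rng.random(n),
        "partial": [False] * n,
    })


def test_differentiation_tracks_properties(rng):
    t = make_track_table(rng)
    out = st.differentiation_tracks(t)
    assert out["fst_prime_inter"].mean() == pytest.approx(0, abs=1e-12)
    assert out["fst_prime_inter"].std(ddof=0) == pytest.approx(1)
    # identical tracks give a zero net differentiation
    t2 = t.copy()
    t2["fst_intra"] = t2["fst_inter"]
    assert st.differentiation_tracks(t2)["dfst_prime"].abs().max() < 1e-12
    # shifting the intra track by a constant leaves the net track unchanged
    t3 = t.copy()
    t3["fst_intra"] = t3["fst_intra"] + 0.17
    pd.testing.assert_series_equal(
        st.differentiation_tracks(t)["dfst_prime"],
        st.differentiation_tracks(t3)["dfst_prime"])
    # a constant track is degenerate
    t4 = t.copy()
    t4["fst_intra"] = 0.3
    with pytest.raises(ValueError, match="degenerate"):
        st.differentiation_tracks(t4)
    assert (out["dpi"] == out["pi_Ev"] - out["pi_Ed"]).all()


def test_outlier_flagging_count_and_merging(rng):
    t = make_track_table(rng, n=1000)
    out = st.differentiation_tracks(t)
    flagged, peaks = st.find_outlier_peaks(out, quantile=0.99)
    assert flagged["outlier"].sum() == 10  # forced by the empirical quantile
    # two flagged windows separated by a 50 kb gap merge at max_gap 50 kb
    t2 = make_track_table(rng, n=6)
    t2["dfst_prime"] = [10.0, 0, 10.0, 0, 0, 0]
    t2.loc[1, ["start", "end"]] = [50_000, 100_000]
    f2, p2 = st.find_outlier_peaks(t2, quantile=0.5, max_gap_bp=50_000)
    flagged_rows = f2[f2["outlier"]]
    assert flagged_rows["peak_id"].nunique() == 1
    assert len(p2) == 1 and p2.iloc[0]["n_windows"] == 2


def test_outlier_peaks_order_independent(rng):
    t = st.differentiation_tracks(make_track_table(rng, n=300))
    base, _ = st.find_outlier_peaks(t)
    shuffled = t.sample(frac=1, random_state=1)
    flagged, _ = st.find_outlier_peaks(shuffled)
    merged = flagged.sort_index()
    pd.testing.assert_series_equal(base["outlier"], merged["outlier"])
    pd.testing.assert_series_equal(base["peak_id"], merged["peak_id"])


def test_track_correlation(rng):
    t = make_track_table(rng)
    r, p = st.track_correlation(t, "fst_inter", "fst_inter")
    assert r == pytest.approx(1.0)
    t["neg"] = -t["fst_inter"]
    r, _ = st.track_correlation(t, "fst_inter", "neg")
    assert r == pytest.approx(-1.0)
    # 20-point check against the textbook formula
    x, y = rng.random(20), rng.random(20)
    t20 = pd.DataFrame({"x": x, "y": y})
    r, _ = st.track_correlation(t20, "x", "y")
    rx = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    assert r == pytest.approx(rx, abs=1e-12)
    t20["const"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        st.track_correlation(t20, "x", "const")


# ---------------------------------------------------------------------------
# f4
# ---------------------------------------------------------------------------

def test_f4_zero_when_c_equals_d(rng):
    calls = rng.integers(0, 2, size=(16, 400)).astype(np.int8)
    pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 8
    m = toy_matrix(calls, pops=pops, positions=np.arange(400) * 100)
    r = st.f4_test(m, "A", "B", "C", "C", block_size_snps=50)
    assert r.f4 == pytest.approx(0.0, abs=1e-15)


def test_f4_antisymmetric(rng):
    calls = rng.integers(0, 2, size=(16, 400)).astype(np.int8)
    pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4 + ["D"] * 4
    m = toy_matrix(calls, pops=pops, positions=np.arange(400) * 100)
    r1 = st.f4_test(m, "A", "B", "C", "D", block_size_snps=50)
    r2 = st.f4_test(m, "B", "A", "C", "D", block_size_snps=50)
    assert r1.f4 == pytest.approx(-r2.f4, abs=1e-15)
    with pytest.raises(ValueError, match="blocks"):
        st.f4_test(m, "A", "B", "C", "D", block_size_snps=400)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def test_permutation_p_is_one_for_invariant_statistic(rng):
    # all individuals identical: every relabelling gives the same statistic
    calls = np.tile(rng.integers(0, 2, size=50).astype(np.int8), (8, 1))
    m = toy_matrix(calls, pops=["A"] * 4 + ["B"] * 4, positions=np.arange(50))
    r = st.window_permutation_test(m, ("s1", 0, 100), "dxy", ["A"], ["B"],
                                   B=200, seed=0)
    assert r.p == 1.0


def test_permutation_exhaustive_matches_enumeration(rng):
    calls = rng.integers(0, 2, size=(6, 60)).astype(np.int8)
    m = toy_matrix(calls, pops=["A"] * 3 + ["B"] * 3, positions=np.arange(60))
    r = st.window_permutation_test(m, ("s1", 0, 100), "dxy", ["A"], ["B"],
                                   exhaustive=True)
    assert r.n_permutations == comb(6, 3) == 20
    # independent enumeration
    vals = []
    idx = list(range(6))
    for combo in combinations(idx, 3):
        A = list(combo)
        B = [i for i in idx if i not in combo]
        tot = 0
        for a in A:
            for b in B:
                tot += (calls[a] != calls[b]).sum()
        vals.append(tot / 9 / 100)
    observed = vals[0]  # identity assignment is the first combination
    expected_p = np.mean([v >= observed - 1e-12 for v in vals])
    assert r.p == pytest.approx(expected_p)


def test_permutation_requires_two_assignments(rng):
    calls = rng.integers(0, 2, size=(2, 10)).astype(np.int8)
    m = toy_matrix(calls, pops=["A", "B"], positions=np.arange(10))
    with pytest.raises(ValueError, match="permute"):
        st.window_permutation_test(m, ("s1", 0, 100), "dxy", ["A"], ["B"], B=10)


def test_permutation_null_is_superuniform(rng):
    """On label-exchangeable data the permutation p-values must not be
    anticonservative: fraction with p <= 0.05 stays below 0.08."""
    n_windows = 400
    hits = 0
    for w in range(n_windows):
        calls = (rng.random((12, 40)) < 0.3).astype(np.int8)
        m = toy_matrix(calls, pops=["A"] * 6 + ["B"] * 6,
                       positions=np.arange(40))
        r = st.window_permutation_test(m, ("s1", 0, 100), "dxy", ["A"], ["B"],
                                       B=99, seed=int(rng.integers(2 ** 31)))
        hits += r.p <= 0.05
    assert hits / n_windows <= 0.08


def test_window_stats_table_and_windows(rng):
    from euscan.synthsim import orchid_config, simulate_region
    m = simulate_region(orchid_config(100_000, seed=77))
    windows = make_windows({"region1": 100_000}, 50_000)
    t = st.compute_window_stats(m, windows)
    t = st.differentiation_tracks(t)
    assert len(t) == 2
    for col in ("pi_Ev", "pi_Ed", "dxy_inter", "fst_inter", "fst_intra",
                "dfst_prime", "dpi"):
        assert np.isfinite(t[col]).all(), col
    assert ((t["pi_Ev"] >= 0) & (t["pi_Ev"] <= 1)).all()
    assert (t["fst_inter"] <= 1).all()


def test_planted_sweep_window_recovered_end_to_end():
    """End-to-end recovery: in a 21-window dataset (independent 20 kb
    scaffolds) with a hard Ed-restricted sweep in the middle window, the
    net-differentiation scan flags the sweep window and its delta pi is
    the most Ed-skewed, in >= 80% of 20 replicates."""
    from euscan.synthsim import SweepConfig, orchid_config, simulate_region
    from euscan.variantio import HaplotypeMatrix

    W = 20_000

    def replicate(rep_seed):
        rng = np.random.default_rng(rep_seed)
        mats = []
        for w in range(21):
            cfg = orchid_config(W, seed=int(rng.integers(1, 2 ** 31)),
                                rec=2.5e-6)
            cfg.chrom = f"win{w:02d}"
            sweep = None
            if w == 10:
                sweep = SweepConfig(s=0.5, position_bp=10_000,
                                    origin_generation=15,
                                    target_populations=("Ed",), h=0.6)
            mats.append(simulate_region(cfg, sweep))
        m0 = mats[0]
        m = HaplotypeMatrix(
            chrom=np.concatenate([x.chrom for x in mats]),
            pos=np.concatenate([x.pos for x in mats]),
            calls=np.concatenate([x.calls for x in mats], axis=1),
            samples=m0.samples, populations=m0.populations)
        t = st.compute_window_stats(
            m, make_windows({f"win{w:02d}": W for w in range(21)}, W))
        t = st.differentiation_tracks(t)
        t, _ = st.find_outlier_peaks(t, quantile=0.9)
        return bool(t.loc[10, "outlier"]) and int(t["dpi"].idxmax()) == 10

    hits = sum(replicate(3000 + rep) for rep in range(20))
    assert hits >= 16
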