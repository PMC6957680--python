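"""Genotype I/O, the filter cascade, LD pruning, windows, annotations."""

import numpy as np
import pytest

from euscan import variantio as vio


# ---------------------------------------------------------------------------
# VCF round trip and GT validation
# ---------------------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=s1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
"""


def write_vcf_text(tmp_path, records):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
    return path


def test_read_vcf_drops_multiallelic_and_loads_biallelic(tmp_path):
    path = write_vcf_text(tmp_path, [
        "s1\t11\t.\tA\tT\t.\tPASS\t.\tGT\t0\t1\t.",
        "s1\t21\t.\tG\tC,T\t.\tPASS\t.\tGT\t0\t1\t2",   # multiallelic: dropped
        "s1\t31\t.\tC\tG\t.\tPASS\t.\tGT\t1\t1\t0",
    ])
    m = vio.read_vcf(path)
    assert m.n_sites == 2
    assert list(m.pos) == [10, 30]  # 0-based
    assert m.calls[2, 0] == vio.MISSING


def test_read_vcf_accepts_homozygous_diploid_rejects_het(tmp_path):
    ok = write_vcf_text(tmp_path, ["s1\t11\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t1/1\t0"])
    m = vio.read_vcf(ok)
    assert list(m.calls[:, 0]) == [0, 1, 0]
    bad = write_vcf_text(tmp_path, ["s1\t11\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1\t0"])
    with pytest.raises(ValueError, match="heterozygous"):
        vio.read_vcf(bad)


def test_vcf_round_trip_identity(tmp_path, random_matrix):
    out = tmp_path / "rt.vcf"
    vio.write_vcf(random_matrix, out)
    back = vio.read_vcf(out)
    np.testing.assert_array_equal(back.calls, random_matrix.calls)
    np.testing.assert_array_equal(back.pos, random_matrix.pos)
    assert back.samples == random_matrix.samples


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

def test_site_call_rate_threshold(make_matrix):
    # one site called in 2 of 4 individuals
    m = make_matrix([[0], [1], [-1], [-1]])
    kept, _ = vio.filter_genotypes(m, min_call_rate=0.5)
    assert kept.n_sites == 1
    dropped, _ = vio.filter_genotypes(m, min_call_rate=0.75)
    assert dropped.n_sites == 0


def test_individual_snp_count_filter(make_matrix):
    calls = np.zeros((3, 10), dtype=np.int8)
    calls[2, :8] = -1  # individual 2 has only 2 called SNPs
    m = make_matrix(calls)
    kept, rep = vio.filter_genotypes(m, min_snps_per_individual=5)
    assert kept.n_individuals == 2
    assert "ind2" not in kept.samples
    assert rep.individuals_removed == 1


def test_all_individuals_removed_raises(make_matrix):
    m = make_matrix(np.full((2, 5), -1, dtype=np.int8))
    with pytest.raises(ValueError, match="all individuals"):
        vio.filter_genotypes(m, min_snps_per_individual=1)


def brute_force_filter(calls, depth, min_call_rate, min_depth, min_snps, maf):
    """Independent reimplementation of the cascade for the oracle check."""
    calls = calls.copy()
    calls[(depth < min_depth) & (calls != -1)] = -1
    keep_sites = (calls != -1).mean(axis=0) >= min_call_rate
    calls = calls[:, keep_sites]
    keep_ind = (calls != -1).sum(axis=1) >= min_snps
    calls = calls[keep_ind]
    keep_sites = (calls != -1).mean(axis=0) >= min_call_rate
    calls = calls[:, keep_sites]
    alt = (calls == 1).sum(axis=0)
    called = (calls != -1).sum(axis=0)
    p = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
    keep = (np.minimum(p, 1 - p) >= maf) & (called > 0)
    return calls[:, keep].shape


def test_filter_cascade_matches_bruteforce_oracle(random_matrix):
    kept, _ = vio.filter_genotypes(random_matrix, min_call_rate=0.6,
                                   min_depth=2, min_snps_per_individual=200,
                                   maf=0.05)
    expected = brute_force_filter(random_matrix.calls, random_matrix.depth,
                                  0.6, 2, 200, 0.05)
    assert (kept.n_individuals, kept.n_sites) == expected


def test_filtering_is_idempotent(random_matrix):
    kw = dict(min_call_rate=0.6, min_snps_per_individual=100, maf=0.05)
    once, _ = vio.filter_genotypes(random_matrix, **kw)
    twice, _ = vio.filter_genotypes(once, **kw)
    np.testing.assert_array_equal(once.calls, twice.calls)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_ld_prune_examples(make_matrix, rng):
    # two perfectly correlated SNPs: one survives
    col = rng.integers(0, 2, size=8).astype(np.int8)
    while col.var() == 0:
        col = rng.integers(0, 2, size=8).astype(np.int8)
    m = vio.ld_prune(make_matrix(np.column_stack([col, col])), r2_max=0.2)
    assert m.n_sites == 1
    # independent SNPs (r2 = 0 by construction) all survive
    a = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=np.int8)
    b = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=np.int8)
    m = vio.ld_prune(make_matrix(np.column_stack([a, b])), r2_max=0.2)
    assert m.n_sites == 2


def test_ld_prune_matches_exhaustive_oracle(rng):
    # block-structured 50-SNP panel
    from tests.conftest import toy_matrix
    base = rng.integers(0, 2, size=(30, 10)).astype(np.int8)
    cols = []
    for j in range(50):
        src = base[:, j % 10].copy()
        flip = rng.random(30) < 0.1
        src[flip] = 1 - src[flip]
        cols.append(src)
    m = toy_matrix(np.column_stack(cols))
    pruned = vio.ld_prune(m, r2_max=0.2, comparison_window=50)

    kept = []
    for j in range(50):
        drop = False
        for k in kept[-50:]:
            r2 = vio.haploid_r2(m.calls[:, j], m.calls[:, k])
            if np.isfinite(r2) and r2 >= 0.2:
                drop = True
                break
        if not drop:
            kept.append(j)
    assert pruned.n_sites == len(kept)
    np.testing.assert_array_equal(pruned.pos, m.pos[kept])
    # invariant: no retained pair within the window reaches the threshold
    for i in range(pruned.n_sites):
        for j in range(max(0, i - 50), i):
            r2 = vio.haploid_r2(pruned.calls[:, i], pruned.calls[:, j])
            assert not (np.isfinite(r2) and r2 >= 0.2)


# ---------------------------------------------------------------------------
# windows and gene density
# ---------------------------------------------------------------------------

def test_make_windows_tiling():
    w = vio.make_windows({"sc1": 120_000}, 50_000)
    assert list(zip(w.chrom, w.start, w.end)) == [
        ("sc1", 0, 50_000), ("sc1", 50_000, 100_000), ("sc1", 100_000, 120_000)]
    assert list(w.partial) == [False, False, True]


def test_make_windows_short_scaffold_and_conservation():
    w = vio.make_windows({"a": 7_000, "b": 130_000}, 50_000)
    assert (w.end - w.start).sum() == 137_000
    assert w.partial[0]


def test_window_gene_density(tmp_path):
    gff = tmp_path / "genes.gff3"
    rows = [
        ("sc1", 11, 20), ("sc1", 100, 200), ("sc1", 49_990, 50_010),  # spans boundary
        ("sc1", 60_000, 61_000), ("sc2", 5, 50), ("sc1", 70_000, 71_000),
        ("sc1", 99_000, 99_100),
    ]
    lines = ["##gff-version 3"]
    for c, s, e in rows:
        lines.append(f"{c}\tsrc\tgene\t{s}\t{e}\t.\t+\t.\tID=g{s}")
        lines.append(f"{c}\tsrc\tmRNA\t{s}\t{e}\t.\t+\t.\tID=m{s}")  # non-gene ignored
    gff.write_text("\n".join(lines) + "\n")
    w = vio.make_windows({"sc1": 100_000, "sc2": 60_000}, 50_000)
    counts = vio.window_gene_density(w, gff)
    # brute-force interval overlap oracle
    expected = []
    for c, s0, e0 in w:
        n = sum(1 for (c2, s, e) in rows if c2 == c and (s - 1) < e0 and e > s0)
        expected.append(n)
    assert list(counts) == expected
    assert counts[0] == 3 and counts[1] == 4  # boundary gene counts in both


def test_window_gene_density_malformed_line(tmp_path):
    gff = tmp_path / "bad.gff3"
    gff.write_text("sc1\tsrc\tgene\t1\n")
    w = vio.make_windows({"sc1": 1000}, 1000)
    with pytest.raises(ValueError, match="line 1"):
        vio.window_gene_density(w, gff)


# ---------------------------------------------------------------------------
# coding alignments
# ---------------------------------------------------------------------------

def write_fasta(tmp_path, seqs):
    path = tmp_path / "aln.fasta"
    path.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
    return path


def test_read_coding_alignment(tmp_path):
    path = write_fasta(tmp_path, {"x": "ATGAAATTT", "y": "ATGAAGTTT"})
    a = vio.read_coding_alignment(path, {"x": "Ed", "y": "Ev"})
    assert a.n_codons == 3
    assert list(a.labels) == ["Ed", "Ev"]


def test_read_coding_alignment_errors(tmp_path):
    ragged = write_fasta(tmp_path, {"x": "ATGAAA", "y": "ATG"})
    with pytest.raises(ValueError, match="length"):
        vio.read_coding_alignment(ragged, {})
    notriplet = write_fasta(tmp_path, {"x": "ATGA", "y": "ATGA"})
    with pytest.raises(ValueError, match="divisible"):
        vio.read_coding_alignment(notriplet, {})
    stop = write_fasta(tmp_path, {"x": "ATGTAACCCAAA", "y": "ATGCAACCCAAA"})
    with pytest.raises(ValueError, match="stop codon"):
        vio.read_coding_alignment(stop, {})
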