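"""Genotype I/O, filtering, and genome windowing.

This module holds the haploid genotype container used by every window
statistic, readers/writers for the standard formats (VCF v4.2, BED, GFF3,
FASTA), the genotype filter cascade, haploid LD pruning, and non-overlapping
window construction.  All coordinates are 0-based half-open internally; VCF
positions are converted on read/write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "GenomeWindows",
    "CodingAlignment",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_genotypes",
    "ld_prune",
    "make_windows",
    "window_gene_density",
    "read_coding_alignment",
    "haploid_r2",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Haploid calls at biallelic SNPs for a set of labelled individuals.

    Attributes
    ----------
    chrom : array of str, shape (n_sites,)
        Scaffold of each site.
    pos : array of int, shape (n_sites,)
        0-based position of each site, strictly increasing within scaffold.
    calls : array of int8, shape (n_individuals, n_sites)
        0 = reference allele, 1 = alternate allele, -1 = missing.
    samples : list of str
        Individual identifiers.
    populations : array of str, shape (n_individuals,)
        Population label of each individual.
    depth : optional array of int, shape (n_individuals, n_sites)
        Per-call read depth.
    """

    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray
    samples: list[str]
    populations: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x sites)")
        n, s = self.calls.shape
        if len(self.samples) != n or len(self.populations) != n:
            raise ValueError("sample/population labels do not match call matrix")
        if len(self.chrom) != s or len(self.pos) != s:
            raise ValueError("site annotations do not match call matrix")
        if not np.isin(self.calls, [MISSING, 0, 1]).all():
            raise ValueError("calls must be 0, 1 or -1 (missing)")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def pop_mask(self, pop) -> np.ndarray:
        """Boolean individual mask for one label or a collection of labels."""
        labels = {pop} if isinstance(pop, str) else set(pop)
        unknown = labels - set(self.populations)
        if unknown:
            raise KeyError(f"unknown population label(s): {sorted(unknown)}")
        return np.isin(self.populations, sorted(labels))

    def site_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean site mask for the half-open interval [start, end)."""
        return (self.chrom == chrom) & (self.pos >= start) & (self.pos < end)

    def take_sites(self, idx) -> "HaplotypeMatrix":
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            calls=self.calls[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def take_individuals(self, idx) -> "HaplotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            samples = [s for s, keep in zip(self.samples, idx) if keep]
        else:
            samples = [self.samples[i] for i in idx]
        return replace(
            self,
            calls=self.calls[idx],
            samples=samples,
            populations=self.populations[idx],
            depth=None if self.depth is None else self.depth[idx],
        )

    def allele_counts(self, pop=None, sites=None):
        """(alt count, called count) per site, optionally within a population."""
        calls = self.calls if pop is None else self.calls[self.pop_mask(pop)]
        if sites is not None:
            calls = calls[:, sites]
        alt = (calls == 1).sum(axis=0)
        called = (calls != MISSING).sum(axis=0)
        return alt, called


@dataclass
class GenomeWindows:
    """Non-overlapping, sorted genome windows (0-based half-open)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    window_size: int
    partial: np.ndarray = field(default=None)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.partial is None:
            self.partial = (self.end - self.start) < self.window_size
        self.partial = np.asarray(self.partial, dtype=bool)
        if ((self.end - self.start) <= 0).any():
            raise ValueError("empty or inverted window")
        if ((self.end - self.start) > self.window_size).any():
            raise ValueError("window longer than window_size")

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self):
        for c, s, e in zip(self.chrom, self.start, self.end):
            yield str(c), int(s), int(e)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "start": self.start,
            "end": self.end, "partial": self.partial,
        })

    def to_bed(self, path) -> None:
        self.to_dataframe()[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False)


@dataclass
class CodingAlignment:
    """Codon-aligned coding sequences with species / outgroup labels."""

    ids: list[str]
    labels: np.ndarray
    seqs: np.ndarray  # (n, L) array of single-character strings, upper case

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.seqs = np.asarray(self.seqs)
        if self.seqs.ndim != 2:
            raise ValueError("alignment must be rectangular")
        if self.seqs.shape[1] % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return self.seqs.shape[1] // 3

    def group(self, label) -> np.ndarray:
        labels = {label} if isinstance(label, str) else set(label)
        return np.isin(self.labels, sorted(labels))


@dataclass
class FilterReport:
    """Record counts removed by each step of the genotype filter cascade."""

    calls_masked_depth: int = 0
    sites_removed_call_rate: int = 0
    individuals_removed: int = 0
    sites_removed_recheck: int = 0
    sites_removed_maf: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, populations: dict[str, str] | None = None) -> HaplotypeMatrix:
    """Load biallelic SNPs from a VCF with haploid (or homozygous diploid) GTs.

    Multiallelic records and non-SNP records are dropped with a logged count.
    A heterozygous diploid call violates the haploid-male model and raises a
    ``ValueError`` naming the record.

    Parameters
    ----------
    populations
        Optional mapping from sample id to population label.  Samples absent
        from the mapping get the label ``"unassigned"``.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    chroms, poss, rows, depths = [], [], [], []
    n_multi = n_nonsnp = 0
    has_depth = False
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multi += 1
            continue
        if len(rec.ref) != 1 or len(alts[0]) != 1:
            n_nonsnp += 1
            continue
        row = np.empty(len(samples), dtype=np.int8)
        dep = np.zeros(len(samples), dtype=np.int32)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT", (None,))
            alleles = [a for a in gt if a is not None]
            if not alleles:
                row[i] = MISSING
            elif len(set(alleles)) > 1:
                raise ValueError(
                    f"heterozygous diploid call for sample {s} at "
                    f"{rec.chrom}:{rec.pos} violates the haploid model")
            else:
                row[i] = alleles[0]
            dp = rec.samples[s].get("DP")
            if dp is not None:
                has_depth = True
                dep[i] = dp
        chroms.append(rec.chrom)
        poss.append(rec.pos - 1)  # VCF is 1-based
        rows.append(row)
        depths.append(dep)
    if n_multi or n_nonsnp:
        logger.info("read_vcf: dropped %d multiallelic and %d non-SNP records",
                    n_multi, n_nonsnp)
    calls = (np.array(rows, dtype=np.int8).T if rows
             else np.empty((len(samples), 0), dtype=np.int8))
    depth = np.array(depths, dtype=np.int32).T if (rows and has_depth) else None
    pops = np.array([populations.get(s, "unassigned") if populations else "unassigned"
                     for s in samples], dtype=object)
    return HaplotypeMatrix(np.array(chroms, dtype=object), np.array(poss),
                           calls, samples, pops, depth)


def write_vcf(m: HaplotypeMatrix, path, contig_lengths: dict[str, int] | None = None,
              ref: str = "A", alt: str = "T") -> None:
    """Write a haploid GT-only VCF v4.2 (uncompressed text).

    The simulator does not track nucleotide identities, so uniform REF/ALT
    symbols are used unless given.
    """
    if contig_lengths is None:
        contig_lengths = {}
        for c in dict.fromkeys(m.chrom):
            contig_lengths[str(c)] = int(m.pos[m.chrom == c].max()) + 1
    code = {0: "0", 1: "1", MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=euscan\n")
        for c, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        for j in range(m.n_sites):
            gts = "\t".join(code[int(g)] for g in m.calls[:, j])
            fh.write(f"{m.chrom[j]}\t{m.pos[j] + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_genotypes(m: HaplotypeMatrix, min_call_rate: float = 0.5,
                     min_depth: int = 0, min_snps_per_individual: int = 0,
                     maf: float = 0.0) -> tuple[HaplotypeMatrix, FilterReport]:
    """Apply the genotype filter cascade.

    Order of operations: per-call depth mask, site call-rate filter,
    individual called-SNP-count filter, site call-rate re-check on the
    surviving individuals, and finally the minor-allele-frequency filter
    (computed on called haploid alleles).

    Raises
    ------
    ValueError
        If every individual is removed.
    """
    if not 0 <= min_call_rate <= 1 or not 0 <= maf <= 0.5:
        raise ValueError("thresholds out of range")
    rep = FilterReport()
    calls = m.calls.copy()
    if min_depth > 0 and m.depth is not None:
        mask = (m.depth < min_depth) & (calls != MISSING)
        rep.calls_masked_depth = int(mask.sum())
        calls[mask] = MISSING
    m = replace(m, calls=calls, depth=m.depth)

    called = m.calls != MISSING
    keep_sites = called.mean(axis=0) >= min_call_rate
    rep.sites_removed_call_rate = int((~keep_sites).sum())
    m = m.take_sites(keep_sites)

    per_ind = (m.calls != MISSING).sum(axis=1)
    keep_ind = per_ind >= min_snps_per_individual
    rep.individuals_removed = int((~keep_ind).sum())
    if not keep_ind.any():
        raise ValueError("all individuals removed by the SNP-count filter")
    m = m.take_individuals(keep_ind)

    # the cascade is re-applied on the surviving individuals
    keep_sites = (m.calls != MISSING).mean(axis=0) >= min_call_rate
    rep.sites_removed_recheck = int((~keep_sites).sum())
    m = m.take_sites(keep_sites)

    if maf > 0:
        alt, called = m.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / np.maximum(called, 1), 0.0)
        freq = np.minimum(p, 1 - p)
        keep = (freq >= maf) & (called > 0)
        rep.sites_removed_maf = int((~keep).sum())
        m = m.take_sites(keep)
    logger.info("filter_genotypes: %s", rep.as_dict())
    return m, rep


def haploid_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared correlation of two haploid 0/1 vectors on pairwise-complete calls.

    Returns ``nan`` when either locus is monomorphic among complete pairs.
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return np.nan
    c = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(c * c / (vx * vy))


def ld_prune(m: HaplotypeMatrix, r2_max: float = 0.2,
             comparison_window: int = 50) -> HaplotypeMatrix:
    """Greedy left-to-right LD pruning within each scaffold.

    A SNP is dropped when its haploid r^2 with any *retained* SNP among the
    previous ``comparison_window`` retained SNPs reaches ``r2_max``.
    """
    keep = np.zeros(m.n_sites, dtype=bool)
    for c in dict.fromkeys(m.chrom):
        idx = np.flatnonzero(m.chrom == c)
        retained: list[int] = []
        for j in idx:
            drop = False
            for k in retained[-comparison_window:]:
                r2 = haploid_r2(m.calls[:, j], m.calls[:, k])
                if np.isfinite(r2) and r2 >= r2_max:
                    drop = True
                    break
            if not drop:
                retained.append(j)
                keep[j] = True
    return m.take_sites(keep)


# ---------------------------------------------------------------------------
# windows / annotation
# ---------------------------------------------------------------------------

def make_windows(contig_lengths: dict[str, int], window_size: int) -> GenomeWindows:
    """Tile each scaffold with non-overlapping windows, keeping the final
    partial window (flagged)."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    chroms, starts, ends = [], [], []
    for c, ln in contig_lengths.items():
        if ln <= 0:
            raise ValueError(f"non-positive length for contig {c}")
        for s in range(0, ln, window_size):
            chroms.append(c)
            starts.append(s)
            ends.append(min(s + window_size, ln))
    return GenomeWindows(np.array(chroms, dtype=object), np.array(starts),
                         np.array(ends), window_size)


def _read_gff_genes(gff_path) -> pd.DataFrame:
    rows = []
    with open(gff_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line {ln}: expected 9 fields")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as e:
                raise ValueError(f"malformed GFF3 line {ln}: bad coordinates") from e
            if parts[2] == "gene":
                rows.append((parts[0], start - 1, end))  # to 0-based half-open
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_gene_density(windows: GenomeWindows, gff_path) -> np.ndarray:
    """Count gene features overlapping each window.

    A gene spanning a window boundary counts in every window it overlaps.
    """
    genes = _read_gff_genes(gff_path)
    counts = np.zeros(len(windows), dtype=np.int64)
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for i, (c, s, e) in enumerate(windows):
        g = by_chrom.get(c)
        if g is None:
            continue
        counts[i] = int(((g["start"] < e) & (g["end"] > s)).sum())
    return counts


# ---------------------------------------------------------------------------
# coding alignments
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def read_coding_alignment(fasta_path, species: dict[str, str]) -> CodingAlignment:
    """Read a codon-aligned FASTA and attach species / outgroup labels.

    Raises on ragged lengths, length not divisible by 3, or an in-frame stop
    codon before the final codon (the terminal codon may be a stop).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    length = len(records[0].seq)
    for r in records:
        if len(r.seq) != length:
            raise ValueError(f"sequence {r.id} has length {len(r.seq)} != {length}")
    if length % 3 != 0:
        raise ValueError(f"alignment length {length} not divisible by 3")
    seqs = np.array([list(str(r.seq).upper()) for r in records])
    for r, row in zip(records, seqs):
        for c in range(0, length - 3, 3):
            codon = "".join(row[c:c + 3])
            if codon in _STOPS:
                raise ValueError(
                    f"internal stop codon {codon} at codon {c // 3 + 1} in {r.id}")
    labels = [species.get(r.id, "unassigned") for r in records]
    return CodingAlignment([r.id for r in records], np.array(labels, dtype=object), seqs)
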