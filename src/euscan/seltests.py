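"""Gene-level molecular-evolution tests on codon alignments.

Covers the classification of variable sites into fixed vs polymorphic and
synonymous vs non-synonymous changes, the McDonald-Kreitman contingency
test, per-group nucleotide diversity of a gene, and a counting-based branch
dN/dS in which only fixed inter-species differences are polarised against
outgroup sequences by parsimony and divided by Nei-Gojobori potential site
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy import stats
from Bio.Data import CodonTable

from .variantio import CodingAlignment

__all__ = [
    "SubstitutionCounts",
    "DnDsResult",
    "classify_substitutions",
    "mk_test",
    "gene_pi",
    "branch_dnds",
    "nei_gojobori_sites",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_BASES = ("A", "C", "G", "T")


def _translate(codon: str) -> str:
    """Amino acid for a codon; '*' for stop, None if ambiguous."""
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table.get(codon)


@dataclass
class SubstitutionCounts:
    """Fixed/polymorphic x synonymous/non-synonymous site counts."""

    dn: int = 0
    ds: int = 0
    pn: int = 0
    ps: int = 0
    excluded_multiallelic: int = 0
    excluded_missing: int = 0
    site_annotations: list = field(default_factory=list)

    def as_table(self) -> np.ndarray:
        """2x2 table [[Dn, Ds], [Pn, Ps]]."""
        return np.array([[self.dn, self.ds], [self.pn, self.ps]])


@dataclass
class DnDsResult:
    branch: str
    n_subs: int
    s_subs: int
    n_sites: float
    s_sites: float
    unassigned: int = 0

    @property
    def dn(self) -> float:
        return self.n_subs / self.n_sites if self.n_sites > 0 else 0.0

    @property
    def ds(self) -> float:
        return self.s_subs / self.s_sites if self.s_sites > 0 else 0.0

    @property
    def ratio(self) -> float | None:
        """dN/dS, or None when dS = 0 (flagged rather than infinite)."""
        if self.ds == 0:
            return None
        return self.dn / self.ds


_MISSING_CHARS = {"-", "N", "?", "."}


def _species_bases(col: np.ndarray) -> tuple[set, dict]:
    """Distinct called bases and per-base counts in one alignment column."""
    counts: dict[str, int] = {}
    for b in col:
        if b in _MISSING_CHARS:
            continue
        counts[b] = counts.get(b, 0) + 1
    return set(counts), counts


def _consensus_codon(rows: np.ndarray, codon_start: int) -> str:
    """Majority codon context (per position) for a set of sequences."""
    out = []
    for k in range(3):
        _, counts = _species_bases(rows[:, codon_start + k])
        if not counts:
            return None
        out.append(max(sorted(counts), key=counts.get))
    return "".join(out)


def classify_substitutions(a: CodingAlignment, species_a: str,
                           species_b: str) -> SubstitutionCounts:
    """Count fixed and polymorphic synonymous/non-synonymous substitutions.

    A variable site is *fixed* when each species is monomorphic for a
    different base, and *polymorphic* when a minor allele is carried by
    more than one individual within a species (within-species singletons
    are ignored).  Sites with more than two segregating bases, or with a
    species entirely missing, are excluded and counted.  Each substitution
    is called synonymous or non-synonymous by swapping the alternate base
    into its codon with the other two positions at the species-consensus
    state.
    """
    ra = a.seqs[a.group(species_a)]
    rb = a.seqs[a.group(species_b)]
    if len(ra) < 2 or len(rb) < 2:
        raise ValueError("need at least two individuals per species")
    out = SubstitutionCounts()
    L = a.seqs.shape[1]
    for pos in range(L):
        ba, ca = _species_bases(ra[:, pos])
        bb, cb = _species_bases(rb[:, pos])
        if not ba or not bb:
            out.excluded_missing += 1
            continue
        allb = ba | bb
        if len(allb) == 1:
            continue
        if len(allb) > 2:
            out.excluded_multiallelic += 1
            continue
        x, y = sorted(allb)
        c0 = (pos // 3) * 3
        ctx = _consensus_codon(ra, c0)
        if ctx is None:
            out.excluded_missing += 1
            continue
        k = pos - c0
        cod_x = ctx[:k] + x + ctx[k + 1:]
        cod_y = ctx[:k] + y + ctx[k + 1:]
        aa_x, aa_y = _translate(cod_x), _translate(cod_y)
        if aa_x is None or aa_y is None:
            out.excluded_missing += 1
            continue
        syn = aa_x == aa_y
        if len(ba) == 1 and len(bb) == 1:
            kind = "fixed"
            if syn:
                out.ds += 1
            else:
                out.dn += 1
        else:
            # polymorphic only if some species carries a minor allele in >1
            # individual; within-species singletons are ignored
            minor_a = min(ca.values()) if len(ca) > 1 else 0
            minor_b = min(cb.values()) if len(cb) > 1 else 0
            if max(minor_a, minor_b) <= 1:
                continue
            kind = "polymorphic"
            if syn:
                out.ps += 1
            else:
                out.pn += 1
        out.site_annotations.append(
            {"position": pos, "bases": (x, y), "kind": kind,
             "synonymous": syn})
    return out


def mk_test(c: SubstitutionCounts) -> tuple[float | None, float]:
    """McDonald-Kreitman test: four-field Fisher's exact test on
    [[Dn, Ds], [Pn, Ps]].

    Returns (odds ratio, two-sided p).  The odds ratio (Dn*Ps)/(Ds*Pn) is
    None when a denominator cell is zero; degenerate tables give p = 1.
    """
    table = c.as_table() if isinstance(c, SubstitutionCounts) else np.asarray(c)
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    dn, ds, pn, ps = table.ravel()
    odds = (dn * ps) / (ds * pn) if ds * pn > 0 else None
    return odds, float(p)


def gene_pi(a: CodingAlignment, group: str) -> float:
    """Mean pairwise difference per aligned bp within a group (pairwise
    deletion of positions missing in either sequence)."""
    rows = a.seqs[a.group(group)]
    n = len(rows)
    if n < 2:
        raise ValueError("need at least two sequences")
    L = rows.shape[1]
    miss = np.isin(rows, sorted(_MISSING_CHARS))
    total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(miss[i] | miss[j])
            total += (rows[i, ok] != rows[j, ok]).sum()
            npairs += 1
    return total / npairs / L


# ---------------------------------------------------------------------------
# Nei-Gojobori counting dN/dS on polarised fixed differences
# ---------------------------------------------------------------------------

def nei_gojobori_sites(seq: str) -> tuple[float, float]:
    """Potential non-synonymous and synonymous site counts of a sequence.

    Classic equal-weight counting: at each codon position, the fraction of
    the three possible single-base changes that alter the amino acid
    contributes to the non-synonymous site count (changes to stop codons
    count as non-synonymous).  Codons containing missing data or stops are
    skipped.
    """
    n_sites = s_sites = 0.0
    for c0 in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[c0:c0 + 3]
        if any(b not in _BASES for b in codon):
            continue
        aa = _translate(codon)
        if aa is None or aa == "*":
            continue
        for k in range(3):
            syn = 0
            for b in _BASES:
                if b == codon[k]:
                    continue
                alt = codon[:k] + b + codon[k + 1:]
                if _translate(alt) == aa:
                    syn += 1
            s_sites += syn / 3
            n_sites += (3 - syn) / 3
    return n_sites, s_sites


def _pathway_counts(anc: str, der: str) -> tuple[float, float]:
    """Nei-Gojobori pathway-averaged (non-synonymous, synonymous) change
    counts between two codons, averaging over all orderings of the
    differing positions; pathways through stop codons are discarded when
    any stop-free pathway exists."""
    diffs = [k for k in range(3) if anc[k] != der[k]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in set(permutations(diffs)):
        cur = anc
        n = s = 0
        through_stop = False
        for k in order:
            nxt = cur[:k] + der[k] + cur[k + 1:]
            aa0, aa1 = _translate(cur), _translate(nxt)
            if aa1 == "*" or aa0 == "*":
                through_stop = True
            if aa0 == aa1:
                s += 1
            else:
                n += 1
            cur = nxt
        paths.append((through_stop, n, s))
    usable = [p for p in paths if not p[0]] or paths
    n = float(np.mean([p[1] for p in usable]))
    s = float(np.mean([p[2] for p in usable]))
    return n, s


def branch_dnds(a: CodingAlignment, species_a: str, species_b: str,
                outgroups) -> dict[str, DnDsResult]:
    """Counting-based branch dN/dS from fixed inter-species differences.

    Fixed differences between the two species are polarised against the
    outgroup consensus: a difference is assigned to the branch of the
    species whose base differs from the outgroup state; sites where the
    outgroup matches neither base stay unassigned (reported).  Potential
    site counts are Nei-Gojobori counts on the ancestral
    (outgroup-matching) sequence; multi-difference codons are
    pathway-averaged per branch.
    """
    ra = a.seqs[a.group(species_a)]
    rb = a.seqs[a.group(species_b)]
    ro = a.seqs[a.group(outgroups)]
    if len(ro) < 1:
        raise ValueError("need at least one outgroup sequence")
    L = a.seqs.shape[1]
    anc = []
    branch_of: dict[int, str] = {}   # site -> species carrying derived base
    derived_base: dict[int, str] = {}
    unassigned = 0
    for pos in range(L):
        ba, _ = _species_bases(ra[:, pos])
        bb, _ = _species_bases(rb[:, pos])
        bo, co = _species_bases(ro[:, pos])
        out_base = max(sorted(co), key=co.get) if co else None
        if len(ba) == 1 and len(bb) == 1 and ba != bb:
            x, y = next(iter(ba)), next(iter(bb))
            if out_base == x:
                branch_of[pos] = species_b
                derived_base[pos] = y
                anc.append(x)
            elif out_base == y:
                branch_of[pos] = species_a
                derived_base[pos] = x
                anc.append(y)
            else:
                unassigned += 1
                anc.append(x)  # context only; site not assigned
        else:
            shared = (ba & bb) or ba or bb
            anc.append(sorted(shared)[0] if shared else (out_base or "N"))
    anc = "".join(anc)
    n_sites, s_sites = nei_gojobori_sites(anc)
    results = {sp: DnDsResult(branch=sp, n_subs=0, s_subs=0,
                              n_sites=n_sites, s_sites=s_sites,
                              unassigned=unassigned)
               for sp in (species_a, species_b)}
    for c0 in range(0, L - L % 3, 3):
        codon_anc = anc[c0:c0 + 3]
        if any(b not in _BASES for b in codon_anc):
            continue
        for sp in (species_a, species_b):
            der = list(codon_anc)
            changed = False
            for k in range(3):
                p = c0 + k
                if branch_of.get(p) == sp:
                    der[k] = derived_base[p]
                    changed = True
            if not changed:
                continue
            n, s = _pathway_counts(codon_anc, "".join(der))
            r = results[sp]
            r.n_subs += round(n) if float(n).is_integer() else n
            r.s_subs += round(s) if float(s).is_integer() else s
    return results
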