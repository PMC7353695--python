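"""Population-genomic summary statistics.

SNP-matrix statistics (observed heterozygosity, effective number of alleles,
polymorphic information content, Weir–Cockerham F_ST with a permutation test,
Nei's 1972 standard distance) and sequence statistics on per-locus haplotype
alignments (nucleotide diversity, Tajima's D, Dxy, net p-distance), plus the
four-statistic summary vector used for ABC.

All statistics use complete-case allele frequencies per locus (non-missing
calls only) and are invariant to locus order and to swapping the 0/2 allele
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, LocusAlignment, LocusAlignmentSet

__all__ = [
    "SnpSummary",
    "SeqSummary",
    "ABC_STAT_NAMES",
    "observed_heterozygosity",
    "effective_num_alleles",
    "pic",
    "snp_summary",
    "nucleotide_diversity",
    "tajimas_d",
    "seq_summary",
    "pairwise_fst",
    "dxy",
    "neis_distance",
    "net_p_distance",
    "abc_stats",
    "abc_stats_from_counts",
]

#: Fixed order of the ABC summary-statistic vector.
ABC_STAT_NAMES = (
    "prop_monomorphic",
    "mean_gene_diversity",
    "var_gene_diversity",
    "mean_maf",
)

#: Nei distance reported when units share no alleles at any locus (I = 0).
NEI_DISTANCE_CAP = 50.0


@dataclass(frozen=True)
class SnpSummary:
    n_snps: int
    effective_num_alleles: float
    observed_heterozygosity: float
    pic: float


@dataclass(frozen=True)
class SeqSummary:
    total_length: int
    pi: float
    tajimas_d: float
    s: int


def _informative_loci(g: GenotypeMatrix) -> np.ndarray:
    called = (g.genotypes != MISSING).sum(axis=0)
    if (called == 0).any():
        warnings.warn(
            f"excluding {(called == 0).sum()} all-missing locus/loci",
            UserWarning,
            stacklevel=3,
        )
    return called > 0


# ---------------------------------------------------------------------------
# SNP-matrix statistics
# ---------------------------------------------------------------------------

def observed_heterozygosity(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Per-locus and mean Ho: share of heterozygous calls among non-missing."""
    keep = _informative_loci(g)
    geno = g.genotypes[:, keep]
    called = geno != MISSING
    ho = (geno == 1).sum(axis=0) / called.sum(axis=0)
    return ho, float(ho.mean())


def effective_num_alleles(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Per-locus and mean Ae = 1 / sum(p_i^2); 1 for monomorphic loci."""
    p = g.allele_frequencies()[_informative_loci(g)]
    ae = 1.0 / (p**2 + (1 - p) ** 2)
    return ae, float(ae.mean())


def pic(g: GenotypeMatrix) -> tuple[np.ndarray, float]:
    """Polymorphic information content (Botstein), biallelic case:
    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2."""
    p = g.allele_frequencies()[_informative_loci(g)]
    q = 1 - p
    val = 1 - (p**2 + q**2) - 2 * p**2 * q**2
    return val, float(val.mean())


def snp_summary(g: GenotypeMatrix) -> SnpSummary:
    return SnpSummary(
        n_snps=g.n_loci,
        effective_num_alleles=effective_num_alleles(g)[1],
        observed_heterozygosity=observed_heterozygosity(g)[1],
        pic=pic(g)[1],
    )


# ---------------------------------------------------------------------------
# sequence statistics
# ---------------------------------------------------------------------------

def _pair_diffs(a: np.ndarray, i: int, j: int) -> int:
    """Differences between haplotypes i and j, pairwise deletion of N/-."""
    valid = ~(np.isin(a[i], ("N", "-")) | np.isin(a[j], ("N", "-")))
    return int((a[i][valid] != a[j][valid]).sum())


def _locus_pair_stats(aln: LocusAlignment) -> tuple[float, int]:
    """(mean pairwise differences, segregating sites) for one locus."""
    a = aln.as_array()
    n = aln.n_haplotypes
    if n < 2:
        raise ValueError(f"locus {aln.locus_id} has fewer than 2 haplotypes")
    diffs = [_pair_diffs(a, i, j) for i, j in combinations(range(n), 2)]
    seg = 0
    for col in a.T:
        obs = set(col) - {"N", "-"}
        if len(obs) > 1:
            seg += 1
    return float(np.mean(diffs)), seg


def nucleotide_diversity(aln: LocusAlignmentSet | LocusAlignment) -> float:
    """Per-site nucleotide diversity pooled across loci: the mean pairwise
    difference count summed over loci, divided by the total length."""
    loci = aln.loci if isinstance(aln, LocusAlignmentSet) else [aln]
    if not loci:
        raise ValueError("empty alignment set")
    total_diffs = sum(_locus_pair_stats(a)[0] for a in loci)
    total_len = sum(a.length for a in loci)
    return total_diffs / total_len


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def tajimas_d_from_counts(n: int, s: int, mean_pairwise: float) -> float:
    """Tajima's (1989) D from sample size, segregating sites and the mean
    number of pairwise differences.  NaN when S = 0 (undefined)."""
    if s == 0:
        return float("nan")
    k = _tajima_constants(n)
    return (mean_pairwise - s / k["a1"]) / np.sqrt(k["e1"] * s + k["e2"] * s * (s - 1))


def tajimas_d(aln: LocusAlignmentSet | LocusAlignment) -> tuple[np.ndarray, float]:
    """Per-locus D (NaN where a locus is invariant) and the pooled D computed
    from totals over loci (all loci must share one sample size)."""
    loci = aln.loci if isinstance(aln, LocusAlignmentSet) else [aln]
    sizes = {a.n_haplotypes for a in loci}
    if len(sizes) != 1:
        raise ValueError("pooled Tajima's D needs a common number of haplotypes")
    n = sizes.pop()
    per = []
    tot_pi, tot_s = 0.0, 0
    for a in loci:
        mp, s = _locus_pair_stats(a)
        per.append(tajimas_d_from_counts(n, s, mp))
        tot_pi += mp
        tot_s += s
    return np.array(per), tajimas_d_from_counts(n, tot_s, tot_pi)


def seq_summary(aln: LocusAlignmentSet) -> SeqSummary:
    total_s = sum(_locus_pair_stats(a)[1] for a in aln)
    return SeqSummary(
        total_length=aln.total_length,
        pi=nucleotide_diversity(aln),
        tajimas_d=tajimas_d(aln)[1],
        s=int(total_s),
    )


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _wc_theta_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-locus (a, a+b+c) for r populations.

    ``n``: diploid sample sizes (r, L); ``p``: alt-allele frequencies (r, L);
    ``h``: observed heterozygote proportions (r, L).  Loci typed in fewer than
    two populations get NaN and are dropped by the caller.
    """
    r = n.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nsum = n.sum(axis=0)
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    return a, a + b + c


def _group_locus_stats(geno: np.ndarray, members: np.ndarray):
    """(n, p, h) per locus for the individuals selected by ``members``."""
    sub = geno[members]
    called = sub != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, sub, 0).sum(axis=0) / (2 * n)
        h = (sub == 1).sum(axis=0) / n
    return n, p, h


def wc_theta(g: GenotypeMatrix, group_masks: list[np.ndarray]) -> float:
    """Multi-locus Weir–Cockerham theta (ratio of sums across loci)."""
    stats = [_group_locus_stats(g.genotypes, m) for m in group_masks]
    n = np.array([s[0] for s in stats])
    p = np.array([s[1] for s in stats])
    h = np.array([s[2] for s in stats])
    usable = (n >= 1).all(axis=0) & ((n.sum(axis=0)) >= 2)
    a, denom = _wc_theta_components(n[:, usable], p[:, usable], h[:, usable])
    good = np.isfinite(a) & np.isfinite(denom)
    d = denom[good].sum()
    return float(a[good].sum() / d) if d != 0 else float("nan")


def _pair_theta_permutations(
    geno: np.ndarray, idx: np.ndarray, n1: int, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed theta for the first ``n1`` of ``idx`` vs the rest, and the
    one-sided permutation p-value from reshuffling individuals across the two
    groups (vectorised in blocks)."""
    sub = geno[idx]
    m_obs = np.zeros(len(idx), dtype=bool)
    m_obs[:n1] = True

    def theta_for(masks: np.ndarray) -> np.ndarray:
        # masks: (B, n_ind) boolean for group 1 membership
        called = (sub != MISSING).astype(float)
        altc = np.where(sub != MISSING, sub, 0).astype(float)
        hetc = (sub == 1).astype(float)
        out = np.empty(masks.shape[0])
        for b, mask in enumerate(masks):
            n = np.vstack([called[mask].sum(axis=0), called[~mask].sum(axis=0)])
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.vstack([altc[mask].sum(axis=0), altc[~mask].sum(axis=0)]) / (2 * n)
                h = np.vstack([hetc[mask].sum(axis=0), hetc[~mask].sum(axis=0)]) / n
            usable = (n >= 1).all(axis=0)
            a, denom = _wc_theta_components(n[:, usable], p[:, usable], h[:, usable])
            good = np.isfinite(a) & np.isfinite(denom)
            d = denom[good].sum()
            out[b] = a[good].sum() / d if d != 0 else np.nan
        return out

    theta_obs = float(theta_for(m_obs[None, :])[0])
    if n_perm == 0:
        return theta_obs, float("nan")
    perms = np.empty((n_perm, len(idx)), dtype=bool)
    for k in range(n_perm):
        perm = rng.permutation(len(idx))
        row = np.zeros(len(idx), dtype=bool)
        row[perm[:n1]] = True
        perms[k] = row
    theta_perm = theta_for(perms)
    n_ge = np.sum(theta_perm[np.isfinite(theta_perm)] >= theta_obs)
    pval = (n_ge + 1) / (n_perm + 1)
    return theta_obs, float(pval)


def pairwise_fst(
    g: GenotypeMatrix,
    groups: list | np.ndarray,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise multi-locus Weir–Cockerham theta between groups, with a
    one-sided permutation test (individuals reshuffled across each pair).

    Returns ``(theta, pvalues)`` as symmetric labelled DataFrames.
    """
    groups = np.asarray(groups)
    labels = [lab for lab in pd.unique(groups)]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 individuals")
    if rng is None and n_perm > 0:
        raise ValueError("permutation test needs an rng")
    theta = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    pval = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for la, lb in combinations(labels, 2):
        ia = np.flatnonzero(groups == la)
        ib = np.flatnonzero(groups == lb)
        idx = np.concatenate([ia, ib])
        th, pv = _pair_theta_permutations(g.genotypes, idx, len(ia), n_perm, rng)
        theta.loc[la, lb] = theta.loc[lb, la] = th
        pval.loc[la, lb] = pval.loc[lb, la] = pv
    return theta, pval


def dxy(
    data: LocusAlignmentSet | GenotypeMatrix,
    groups: list | np.ndarray,
    group_of_haplotype: list | np.ndarray | None = None,
) -> pd.DataFrame:
    """Average number of nucleotide substitutions per site between groups.

    For alignments: the mean over all between-group haplotype pairs of raw
    difference counts, pooled over the total sequence length (``groups`` then
    labels haplotypes, per locus in input order).  For a SNP matrix: each
    locus is one site and Dxy = mean over loci of p1(1-p2) + p2(1-p1).
    """
    groups = np.asarray(groups)
    labels = [lab for lab in pd.unique(groups)]
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for lab in labels:
        out.loc[lab, lab] = 0.0
    if isinstance(data, GenotypeMatrix):
        for la, lb in combinations(labels, 2):
            ga = data.subset_individuals(groups == la).allele_frequencies()
            gb = data.subset_individuals(groups == lb).allele_frequencies()
            ok = np.isfinite(ga) & np.isfinite(gb)
            val = float(np.mean(ga[ok] * (1 - gb[ok]) + gb[ok] * (1 - ga[ok])))
            out.loc[la, lb] = out.loc[lb, la] = val
        return out
    for la, lb in combinations(labels, 2):
        total_diffs, total_pairs_len = 0.0, 0
        for aln in data:
            a = aln.as_array()
            ia = np.flatnonzero(groups == la)
            ib = np.flatnonzero(groups == lb)
            if len(ia) == 0 or len(ib) == 0:
                raise ValueError("both groups must be non-empty")
            diffs = [_pair_diffs(a, i, j) for i in ia for j in ib]
            total_diffs += float(np.mean(diffs))
            total_pairs_len += aln.length
        out.loc[la, lb] = out.loc[lb, la] = total_diffs / total_pairs_len
    return out


def net_p_distance(seqs_a: list[str], seqs_b: list[str]) -> float:
    """Net between-group p-distance: Dxy - (pi_A + pi_B) / 2, with
    uncorrected (p) distances on aligned equal-length sequences."""
    lengths = {len(s) for s in seqs_a} | {len(s) for s in seqs_b}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    length = lengths.pop()

    def mean_p(pairs) -> float:
        a = np.array([list(s.upper()) for s in pairs[0]])
        b = np.array([list(s.upper()) for s in pairs[1]])
        d = [
            _pair_diffs(np.vstack([a[i], b[j]]), 0, 1) / length
            for i in range(len(a))
            for j in range(len(b))
            if pairs[0] is not pairs[1] or i < j
        ]
        return float(np.mean(d)) if d else 0.0

    d_between = mean_p((seqs_a, seqs_b))
    pi_a = mean_p((seqs_a, seqs_a)) if len(seqs_a) > 1 else 0.0
    pi_b = mean_p((seqs_b, seqs_b)) if len(seqs_b) > 1 else 0.0
    return d_between - (pi_a + pi_b) / 2


def neis_distance(g: GenotypeMatrix, units: str = "individuals", groups=None) -> pd.DataFrame:
    """Nei's (1972) standard genetic distance D = -ln I between units.

    ``units='individuals'`` treats each individual's allele frequencies as
    (0, 0.5, 1); ``units='groups'`` pools by ``groups``.  Loci missing in
    either unit are excluded pairwise; I = 0 is reported as the documented cap
    ``NEI_DISTANCE_CAP`` with a warning.
    """
    if units == "individuals":
        labels = list(g.individuals)
        with np.errstate(invalid="ignore"):
            freqs = np.where(g.genotypes == MISSING, np.nan, g.genotypes / 2.0)
    elif units == "groups":
        if groups is None:
            raise ValueError("units='groups' requires group labels")
        groups = np.asarray(groups)
        labels = [lab for lab in pd.unique(groups)]
        freqs = np.vstack(
            [g.subset_individuals(groups == lab).allele_frequencies() for lab in labels]
        )
    else:
        raise ValueError("units must be 'individuals' or 'groups'")
    n_units = len(labels)
    out = np.zeros((n_units, n_units))
    capped = False
    for i, j in combinations(range(n_units), 2):
        ok = np.isfinite(freqs[i]) & np.isfinite(freqs[j])
        p1, p2 = freqs[i][ok], freqs[j][ok]
        jxy = float(np.sum(p1 * p2 + (1 - p1) * (1 - p2)))
        jx = float(np.sum(p1**2 + (1 - p1) ** 2))
        jy = float(np.sum(p2**2 + (1 - p2) ** 2))
        identity = jxy / np.sqrt(jx * jy) if jx > 0 and jy > 0 else 0.0
        if identity <= 0:
            capped = True
            d = NEI_DISTANCE_CAP
        else:
            d = min(-np.log(identity), NEI_DISTANCE_CAP)
        out[i, j] = out[j, i] = d
    if capped:
        warnings.warn(
            f"Nei identity of 0 capped at D = {NEI_DISTANCE_CAP}", UserWarning, stacklevel=2
        )
    return pd.DataFrame(out, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# ABC summary vector
# ---------------------------------------------------------------------------

def abc_stats_from_counts(derived: np.ndarray, called: np.ndarray) -> np.ndarray:
    """The four ABC summary statistics from per-locus allele counts.

    ``derived`` and ``called`` are per-locus alternate-allele copies and total
    called copies; 2-D input (datasets x loci) reduces along the last axis.
    Order: proportion of monomorphic loci, mean and variance of unbiased gene
    diversity ``2n/(2n-1) * 2pq``, mean minor-allele frequency.  The identical
    kernel serves observed matrices and simulated reference rows.
    """
    derived = np.asarray(derived, dtype=float)
    called = np.asarray(called, dtype=float)
    if derived.size == 0:
        raise ValueError("no loci")
    if np.any(called < 2):
        raise ValueError("every locus needs at least one called genotype")
    p = derived / called
    mono = (derived == 0) | (derived == called)
    h = called / (called - 1.0) * 2.0 * p * (1.0 - p)
    maf = np.minimum(p, 1.0 - p)
    stats = np.stack(
        [
            mono.mean(axis=-1),
            h.mean(axis=-1),
            h.var(axis=-1),
            maf.mean(axis=-1),
        ],
        axis=-1,
    )
    return stats


def abc_stats(g: GenotypeMatrix) -> np.ndarray:
    """ABC summary vector for a single-population genotype matrix."""
    derived, called = g.allele_counts()
    keep = called >= 2
    if not keep.all():
        warnings.warn(
            f"excluding {(~keep).sum()} locus/loci with <1 called genotype",
            UserWarning,
            stacklevel=2,
        )
    return abc_stats_from_counts(derived[keep], called[keep])
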