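"""Independent reference implementations used as test oracles.

Everything here is written directly from the primary definitions (textbook
formulas, brute-force enumeration, naive discrete-generation simulation) and
shares no code with the package, so agreement between the two is meaningful.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, log, sqrt

import numpy as np


# ---------------------------------------------------------------------------
# sequence statistics
# ---------------------------------------------------------------------------

def pi_bruteforce(seqs: list[str]) -> float:
    """Nucleotide diversity per site by exhaustive pair enumeration."""
    n = len(seqs)
    length = len(seqs[0])
    diffs = [
        sum(1 for a, b in zip(seqs[i], seqs[j]) if a != b and "N" not in (a, b) and "-" not in (a, b))
        for i, j in combinations(range(n), 2)
    ]
    return sum(diffs) / len(diffs) / length


def dxy_bruteforce(group_a: list[str], group_b: list[str]) -> float:
    """Between-group mean pairwise difference per site, all cross pairs."""
    length = len(group_a[0])
    diffs = [
        sum(1 for x, y in zip(a, b) if x != y) for a in group_a for b in group_b
    ]
    return sum(diffs) / len(diffs) / length


def tajimas_d_textbook(seqs: list[str]) -> float:
    """Tajima's D from the 1989 definitions, coded independently."""
    n = len(seqs)
    length = len(seqs[0])
    s = sum(1 for site in range(length) if len({seq[site] for seq in seqs}) > 1)
    if s == 0:
        return float("nan")
    k_hat = pi_bruteforce(seqs) * length  # mean pairwise differences
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_hat - s / a1) / sqrt(e1 * s + e2 * s * (s - 1))


def net_p_distance_bruteforce(group_a: list[str], group_b: list[str]) -> float:
    def mean_within(group):
        if len(group) < 2:
            return 0.0
        vals = [
            sum(1 for x, y in zip(a, b) if x != y) / len(a)
            for a, b in combinations(group, 2)
        ]
        return sum(vals) / len(vals)

    return dxy_bruteforce(group_a, group_b) - (mean_within(group_a) + mean_within(group_b)) / 2


# ---------------------------------------------------------------------------
# SNP statistics
# ---------------------------------------------------------------------------

def wc84_single_locus(genos_a: list[int], genos_b: list[int]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for one locus
    and two populations of diploid genotypes coded 0/1/2."""
    r = 2
    pops = [genos_a, genos_b]
    n = [len(g) for g in pops]
    p = [sum(g) / (2 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x**2 for x in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def nei_d_from_freqs(p1: list[float], p2: list[float]) -> float:
    """Nei (1972) standard distance for biallelic loci from frequencies."""
    jxy = sum(a * b + (1 - a) * (1 - b) for a, b in zip(p1, p2))
    jx = sum(a**2 + (1 - a) ** 2 for a in p1)
    jy = sum(b**2 + (1 - b) ** 2 for b in p2)
    return -log(jxy / sqrt(jx * jy))


# ---------------------------------------------------------------------------
# coalescent oracles
# ---------------------------------------------------------------------------

def wf_tmrca(
    n_lineages: int,
    n_recent: float,
    n_ancestral: float,
    t_switch: float,
    rng: np.random.Generator,
) -> int:
    """TMRCA (generations) of a sample under the exact discrete-generation
    haploid-parent Wright-Fisher genealogy with a stepwise size change.

    Each generation every lineage picks one of the 2N parents uniformly;
    collisions merge (multiple mergers allowed).  Collision-free stretches
    are skipped with a geometric draw, which leaves the process distribution
    exactly unchanged.
    """
    t = 0
    j = n_lineages
    while j > 1:
        two_n = int(2 * (n_recent if t < t_switch else n_ancestral))
        q_no = 1.0
        for k in range(1, j):
            q_no *= 1.0 - k / two_n
        if q_no <= 0.0:
            gens_to_event = 1
        else:
            gens_to_event = 1 + int(np.floor(np.log(rng.random()) / np.log(q_no)))
        if t < t_switch and t + gens_to_event > t_switch:
            # the skip would cross the size change; restart from the boundary
            t = int(t_switch)
            continue
        t += gens_to_event
        while True:  # parent assignment conditioned on >= 1 collision
            parents = rng.integers(0, two_n, size=j)
            uniq = len(np.unique(parents))
            if uniq < j:
                j = uniq
                break
    return t


def conditioned_sfs_oracle(
    n: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Expected SFS of a single branch-proportional mutation per genealogy
    (constant population size), integrating the topology analytically.

    Conditional on the level waiting times T_j, the mutation lands at level j
    with probability j*T_j / L, and a uniformly chosen block at level j has
    size b with probability C(n-b-1, j-2) / C(n-1, j-1); only the (scale-free)
    waiting times are Monte-Carlo sampled.
    """
    levels = np.arange(n, 1, -1)
    rates = levels * (levels - 1) / 2.0
    q = np.zeros((n - 1, n - 1))  # level idx x derived count-1
    for idx, j in enumerate(levels):
        for b in range(1, n - j + 2):
            q[idx, b - 1] = comb(n - b - 1, j - 2) / comb(n - 1, j - 1)
    t = rng.exponential(size=(n_reps, n - 1)) / rates  # units of 2N
    w = t * levels
    w /= w.sum(axis=1, keepdims=True)
    return w.mean(axis=0) @ q
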