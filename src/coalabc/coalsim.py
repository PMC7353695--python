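"""Coalescent simulation of unlinked SNP and short sequence loci.

Single panmictic population whose diploid effective size follows one of three
demographic scenarios: constant size ``Nc``; a stepwise expansion from an
ancestral size ``NA`` to a present size ``N`` at ``TEXP`` generations before
present dated either to the onset of the last glacial maximum or to the last
interglacial.  Time is measured backwards in generations (one year per
generation by default), sizes are diploid effective sizes.

Genealogies follow the standard n-coalescent with a piecewise-constant
population size: while ``j`` ancestral lineages remain, the waiting time to
the next coalescence has hazard ``j(j-1)/2 / (2*Ne(t))``; the change-point is
handled by exact piecewise rescaling of a unit exponential, never by
rejection.  SNP loci carry exactly one mutation, placed on a branch chosen
with probability proportional to its length, so every simulated SNP is
polymorphic in-sample (the data shape produced by calling a single SNP per
RAD locus).  Sequence loci mutate under the infinite-sites model.

Two equivalent generators are provided for SNPs:

* a per-locus path (:func:`simulate_tree` + :func:`simulate_snp_locus`) that
  materialises the genealogy and is used wherever individual genotypes are
  needed;
* a vectorised counts-only path (:func:`simulate_snp_counts`) used for large
  ABC reference tables.  It draws the per-level waiting times ``T_j``
  directly, picks the mutation level with probability proportional to the
  realised ``j*T_j``, and draws the derived-allele count from the
  level-conditional block-size law ``P(b | j) = C(n-b-1, j-2) / C(n-1, j-1)``.
  Because Kingman waiting times are independent of the merger chain and block
  sizes at a level are exchangeable, this is distribution-identical to
  simulating the topology and dropping the mutation on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.special import comb

__all__ = [
    "ModelKind",
    "DemographicScenario",
    "SampleSpec",
    "CoalescentTree",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_snp_locus",
    "simulate_sequence_locus",
    "simulate_snp_counts",
    "thin_allele_counts",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))


class InvalidScenarioError(ValueError):
    """Raised for demographic scenarios that cannot be simulated."""


class ModelKind(str, Enum):
    """The three competing demographic models."""

    CONSTANT = "constant"
    EXPANSION_LGM = "expansion_lgm"
    EXPANSION_INTERGLACIAL = "expansion_interglacial"


@dataclass(frozen=True)
class DemographicScenario:
    """One demographic model with its parameters.

    Parameters
    ----------
    kind
        Which of the three models this is.
    Nc
        Diploid effective size of the constant model.
    NA, N
        Ancestral and post-expansion diploid effective sizes (expansion
        models).
    TEXP
        Expansion time in generations before present (``TEXP1`` for the
        glacial model, ``TEXP2`` for the interglacial model).
    generation_time_years
        Years per generation; 1 for small passerines, so generations and
        years coincide throughout.
    """

    kind: ModelKind
    Nc: float | None = None
    NA: float | None = None
    N: float | None = None
    TEXP: float | None = None
    generation_time_years: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == ModelKind.CONSTANT:
            sizes = [self.Nc]
        else:
            sizes = [self.NA, self.N]
            if self.TEXP is None or not np.isfinite(self.TEXP) or self.TEXP <= 0:
                raise InvalidScenarioError(
                    f"expansion scenario requires TEXP > 0, got {self.TEXP}"
                )
        for s in sizes:
            if s is None or not np.isfinite(s) or s < 2:
                raise InvalidScenarioError(f"population size must be finite and >= 2, got {s}")

    # Backwards-in-time piecewise description: size now, size past the
    # change-point, and the change-point itself (inf = no change).
    @property
    def recent_size(self) -> float:
        return float(self.Nc if self.kind == ModelKind.CONSTANT else self.N)

    @property
    def ancestral_size(self) -> float:
        return float(self.Nc if self.kind == ModelKind.CONSTANT else self.NA)

    @property
    def switch_time(self) -> float:
        return np.inf if self.kind == ModelKind.CONSTANT else float(self.TEXP)

    def size_at(self, t: float) -> float:
        """Diploid effective size at ``t`` generations before present."""
        return self.recent_size if t < self.switch_time else self.ancestral_size

    def with_params(self, **params: float) -> "DemographicScenario":
        return replace(self, **params)


@dataclass(frozen=True)
class SampleSpec:
    """Shape of a simulated sample.

    ``seq_mu_per_site`` is the per-site per-generation mutation rate used for
    sequence loci (SNP loci are conditioned on a single mutation and need no
    rate).  ``sex_labels`` are recorded for provenance only; all loci are
    autosomal.
    """

    n_diploid: int = 20
    n_snp_loci: int = 2000
    n_seq_loci: int = 0
    seq_locus_length: int = 140
    per_locus_missing_rate: float = 0.0
    seq_mu_per_site: float = 2.5e-9

    def __post_init__(self) -> None:
        if self.n_diploid < 2:
            raise ValueError("need at least 2 diploid individuals")
        if self.n_snp_loci < 0 or self.n_seq_loci < 0 or self.seq_locus_length <= 0:
            raise ValueError("locus counts must be non-negative and lengths positive")
        if not 0.0 <= self.per_locus_missing_rate < 1.0:
            raise ValueError("per_locus_missing_rate must be in [0, 1)")

    @property
    def n_haploid(self) -> int:
        return 2 * self.n_diploid


@dataclass
class CoalescentTree:
    """A realised genealogy over ``n_tips`` haploid lineages.

    Nodes ``0 .. n_tips-1`` are tips at time 0; internal nodes are appended
    in coalescence order, so a parent always has a larger index (and a later
    time) than its children.  ``parent[root] == -1``.
    """

    parent: np.ndarray
    time: np.ndarray
    n_tips: int

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        nonroot = np.arange(self.n_nodes - 1)
        return self.time[self.parent[nonroot]] - self.time[nonroot]

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def n_descendant_tips(self) -> np.ndarray:
        """Number of tips below each node (tips count themselves)."""
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        counts[: self.n_tips] = 1
        for v in range(self.n_nodes - 1):  # parents have larger indices
            counts[self.parent[v]] += counts[v]
        return counts

    def tips_below(self, node: int) -> np.ndarray:
        """Sorted tip ids in the subtree rooted at ``node``."""
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            children[self.parent[v]].append(v)
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            else:
                stack.extend(children[v])
        return np.array(sorted(out), dtype=np.int64)


# ---------------------------------------------------------------------------
# waiting times under piecewise-constant Ne
# ---------------------------------------------------------------------------

def _waiting_time(j, t0, n_recent, n_ancestral, t_switch, unit_exp):
    """Generations until the next coalescence, given ``j`` lineages at ``t0``.

    Exact piecewise rescaling of a unit-rate exponential ``unit_exp``;
    vectorised (all arguments broadcast).
    """
    c = j * (j - 1) / 2.0
    in_recent = t0 < t_switch
    with np.errstate(invalid="ignore"):
        # exponential "budget" consumed by sitting in the recent epoch; the
        # crossing branch is inf - inf for constant scenarios but never taken
        capacity = np.where(in_recent, (t_switch - t0) * c / (2.0 * n_recent), 0.0)
        dt_recent = unit_exp * 2.0 * n_recent / c
        dt_cross = (t_switch - t0) + (unit_exp - capacity) * 2.0 * n_ancestral / c
        dt_anc = unit_exp * 2.0 * n_ancestral / c
        return np.where(
            in_recent, np.where(unit_exp <= capacity, dt_recent, dt_cross), dt_anc
        )


def simulate_tree(
    n_haploid: int, scenario: DemographicScenario, rng: np.random.Generator
) -> CoalescentTree:
    """Simulate one coalescent genealogy for ``n_haploid`` lineages."""
    if n_haploid < 2:
        raise ValueError("n_haploid must be >= 2")
    n = int(n_haploid)
    nr, na, tsw = scenario.recent_size, scenario.ancestral_size, scenario.switch_time
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    for j in range(n, 1, -1):
        t += float(_waiting_time(j, t, nr, na, tsw, rng.exponential()))
        i1 = int(rng.integers(j))  # uniform distinct pair
        i2 = int(rng.integers(j - 1))
        if i2 >= i1:
            i2 += 1
        a, b = active[i1], active[i2]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active[min(i1, i2)] = nxt
        active.pop(max(i1, i2))
        nxt += 1
    return CoalescentTree(parent=parent, time=time, n_tips=n)


# ---------------------------------------------------------------------------
# mutation models
# ---------------------------------------------------------------------------

def simulate_snp_locus(tree: CoalescentTree, rng: np.random.Generator) -> np.ndarray:
    """One biallelic SNP on ``tree``: a single mutation on a branch chosen
    proportional to its length.  Returns the haploid 0/1 allele vector;
    the derived count is always in ``[1, n_tips-1]``."""
    lengths = tree.branch_lengths()
    total = lengths.sum()
    if not total > 0:
        raise ValueError("degenerate tree with zero total branch length")
    branch = rng.choice(len(lengths), p=lengths / total)
    alleles = np.zeros(tree.n_tips, dtype=np.int8)
    alleles[tree.tips_below(branch)] = 1
    return alleles


def simulate_sequence_locus(
    tree: CoalescentTree,
    mu_per_site: float,
    length: int,
    rng: np.random.Generator,
) -> list[str]:
    """Infinite-sites haplotypes of ``length`` bp evolved on ``tree``.

    The number of mutations is Poisson with mean ``mu * L * total branch
    length``; each hits a fresh site on a branch chosen proportional to its
    length.  If more mutations are requested than there are sites the locus
    saturates with a warning.
    """
    lengths = tree.branch_lengths()
    total = lengths.sum()
    mean = mu_per_site * length * total
    if not np.isfinite(mean):
        raise ValueError("non-finite expected mutation count")
    n_mut = int(rng.poisson(mean))
    if n_mut > length:
        warnings.warn(
            f"requested {n_mut} mutations on a {length} bp locus; saturating",
            RuntimeWarning,
            stacklevel=2,
        )
        n_mut = length
    ancestral = _BASES[rng.integers(0, 4, size=length)]
    haps = np.tile(ancestral, (tree.n_tips, 1))
    if n_mut:
        sites = rng.choice(length, size=n_mut, replace=False)
        branches = rng.choice(len(lengths), size=n_mut, p=lengths / total)
        for site, branch in zip(sites, branches):
            derived = _BASES[(np.flatnonzero(_BASES == ancestral[site])[0] + rng.integers(1, 4)) % 4]
            haps[tree.tips_below(branch), site] = derived
    return ["".join(row) for row in haps]


# ---------------------------------------------------------------------------
# vectorised counts-only SNP path
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _block_size_cdf(n_haploid: int) -> np.ndarray:
    """Row ``idx`` (level ``j = n - idx``): CDF over derived counts 1..n-1 of
    the size of a uniformly chosen block when ``j`` blocks remain,
    ``P(b | j) = C(n-b-1, j-2) / C(n-1, j-1)``."""
    n = n_haploid
    b = np.arange(1, n)  # possible derived counts
    pmf = np.zeros((n - 1, n - 1))
    for idx, j in enumerate(range(n, 1, -1)):
        p = comb(n - b - 1, j - 2) / comb(n - 1, j - 1)
        p[b > n - j + 1] = 0.0
        pmf[idx] = p
    cdf = np.cumsum(pmf, axis=1)
    cdf[:, -1] = 1.0
    return cdf


try:  # single-pass kernel; the numpy path below is the reference fallback
    from numba import njit as _njit

    @_njit(cache=True)
    def _snp_count_kernel(e, u_lvl, u_blk, nr, na, tsw, cdf, n):  # pragma: no cover
        m = e.shape[0]
        out = np.empty(m, dtype=np.int64)
        n_lvl = n - 1
        w = np.empty(n_lvl)
        for i in range(m):
            tau = 0.0
            tau_sw = tsw[i] / (2.0 * nr[i])
            t_prev = 0.0
            total = 0.0
            for idx in range(n_lvl):
                j = n - idx
                tau += e[i, idx] * 2.0 / (j * (j - 1))
                if tau <= tau_sw:
                    t = 2.0 * nr[i] * tau
                else:
                    t = tsw[i] + 2.0 * na[i] * (tau - tau_sw)
                w[idx] = j * (t - t_prev)
                t_prev = t
                total += w[idx]
            target = u_lvl[i] * total
            acc = 0.0
            lvl = n_lvl - 1
            for idx in range(n_lvl):
                acc += w[idx]
                if acc >= target:
                    lvl = idx
                    break
            u2 = u_blk[i]
            b = n - 1
            for idx in range(n - 1):
                if cdf[lvl, idx] >= u2:
                    b = idx + 1
                    break
            out[i] = b
        return out

except ImportError:  # pragma: no cover
    _snp_count_kernel = None


def simulate_snp_counts(
    n_haploid: int,
    n_recent,
    n_ancestral,
    t_switch,
    rng: np.random.Generator,
    n_loci: int | None = None,
) -> np.ndarray:
    """Derived-allele counts for independent single-mutation SNP loci.

    ``n_recent``, ``n_ancestral`` and ``t_switch`` may be scalars or arrays
    with one entry per locus (so loci simulated under different parameter
    draws can share one call).  Returns an int array of counts in
    ``[1, n_haploid - 1]``.
    """
    n = int(n_haploid)
    if n < 2:
        raise ValueError("n_haploid must be >= 2")
    n_recent = np.atleast_1d(np.asarray(n_recent, dtype=float))
    n_ancestral = np.atleast_1d(np.asarray(n_ancestral, dtype=float))
    t_switch = np.atleast_1d(np.asarray(t_switch, dtype=float))
    if np.any(n_recent < 2) or np.any(n_ancestral < 2):
        raise InvalidScenarioError("population sizes must be >= 2")
    if n_loci is None:
        n_loci = int(np.broadcast_shapes(n_recent.shape, n_ancestral.shape, t_switch.shape)[0])
    m = int(n_loci)
    # Work on the coalescent time scale tau = integral dt / (2 Ne(t)), where
    # the process is the constant-rate Kingman coalescent: the tau-scale
    # waiting time with j lineages is Exp(j(j-1)/2).  Cumulative-sum all
    # levels at once, then invert the (piecewise-linear) time change.
    # Randomness is drawn up front from the caller's generator so the jitted
    # and numpy paths consume the identical stream.
    e = rng.exponential(size=(m, n - 1))
    u_lvl = rng.random(m)
    u_blk = rng.random(m)
    if _snp_count_kernel is not None:
        nr = np.broadcast_to(n_recent, (m,)).astype(float)
        na = np.broadcast_to(n_ancestral, (m,)).astype(float)
        tsw = np.broadcast_to(t_switch, (m,)).astype(float)
        return _snp_count_kernel(e, u_lvl, u_blk, nr, na, tsw, _block_size_cdf(n), n)
    levels = np.arange(n, 1, -1)
    rates = levels * (levels - 1) / 2.0
    tau = np.cumsum(e / rates, axis=1)
    nr = n_recent.reshape(-1, 1)
    na = n_ancestral.reshape(-1, 1)
    with np.errstate(invalid="ignore"):
        tau_switch = (t_switch / (2.0 * n_recent)).reshape(-1, 1)
        t_events = np.where(
            tau <= tau_switch,
            2.0 * nr * tau,
            t_switch.reshape(-1, 1) + 2.0 * na * (tau - tau_switch),
        )
    dt = np.diff(t_events, axis=1, prepend=0.0)
    level_weight = levels * dt
    cum = np.cumsum(level_weight, axis=1)
    u = u_lvl * cum[:, -1]
    lvl = np.minimum((cum < u[:, None]).sum(axis=1), n - 2)
    cdf = _block_size_cdf(n)[lvl]
    counts = (cdf < u_blk[:, None]).sum(axis=1) + 1
    return np.minimum(counts, n - 1).astype(np.int64)


def thin_allele_counts(
    derived: np.ndarray,
    n_diploid: int,
    missing_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-genotype missingness to per-locus derived counts.

    Dropping a random diploid removes two allele copies; because haploid
    lineages are paired at random, the retained copies are a uniform random
    subset, so the retained derived count is hypergeometric.  Returns
    ``(derived_called, called_copies)`` per locus.
    """
    derived = np.asarray(derived)
    n_hap = 2 * n_diploid
    if missing_rate == 0.0:
        return derived.copy(), np.full_like(derived, n_hap)
    kept = rng.binomial(n_diploid, 1.0 - missing_rate, size=derived.shape)
    called = 2 * kept
    out = np.zeros_like(derived)
    pos = called > 0
    out[pos] = rng.hypergeometric(derived[pos], n_hap - derived[pos], called[pos])
    return out, called


# ---------------------------------------------------------------------------
# full synthetic datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """A simulated study: genotypes, optional sequence loci, and the truth."""

    genotypes: "GenotypeMatrix"  # noqa: F821 - forward ref to coalabc.data
    alignments: "LocusAlignmentSet | None"  # noqa: F821
    scenario: DemographicScenario
    spec: SampleSpec
    truth: dict = field(default_factory=dict)


def simulate_dataset(
    scenario: DemographicScenario,
    spec: SampleSpec,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Simulate a full RAD-style dataset under ``scenario``.

    Haploid lineages ``2k`` and ``2k+1`` form diploid individual ``k``
    (random mating); genotypes are derived-allele counts 0/1/2 with
    per-genotype missingness injected uniformly at random.
    """
    from .data import GenotypeMatrix, LocusAlignment, LocusAlignmentSet
    import pandas as pd

    n_dip = spec.n_diploid
    geno = np.empty((n_dip, spec.n_snp_loci), dtype=np.int8)
    for locus in range(spec.n_snp_loci):
        tree = simulate_tree(spec.n_haploid, scenario, rng)
        alleles = simulate_snp_locus(tree, rng)
        geno[:, locus] = alleles[0::2] + alleles[1::2]
    if spec.per_locus_missing_rate > 0:
        miss = rng.random(geno.shape) < spec.per_locus_missing_rate
        geno[miss] = -1

    individuals = [f"ind_{k:03d}" for k in range(n_dip)]
    metadata = pd.DataFrame(
        {"sex": ["M" if k < n_dip // 2 else "F" for k in range(n_dip)]},
        index=pd.Index(individuals, name="individual"),
    )
    gm = GenotypeMatrix(
        genotypes=geno,
        individuals=individuals,
        loci=[f"locus_{j:05d}" for j in range(spec.n_snp_loci)],
        metadata=metadata,
    )

    aln = None
    if spec.n_seq_loci:
        loci = []
        for locus in range(spec.n_seq_loci):
            tree = simulate_tree(spec.n_haploid, scenario, rng)
            seqs = simulate_sequence_locus(tree, spec.seq_mu_per_site, spec.seq_locus_length, rng)
            names = [f"ind_{k // 2:03d}_hap{k % 2}" for k in range(spec.n_haploid)]
            loci.append(
                LocusAlignment(
                    locus_id=f"seqlocus_{locus:05d}",
                    names=names,
                    sequences=seqs,
                    individual_of_origin=[k // 2 for k in range(spec.n_haploid)],
                )
            )
        aln = LocusAlignmentSet(loci=loci)

    truth = {
        "kind": scenario.kind.value,
        "Nc": scenario.Nc,
        "NA": scenario.NA,
        "N": scenario.N,
        "TEXP": scenario.TEXP,
    }
    return SimulatedDataset(genotypes=gm, alignments=aln, scenario=scenario, spec=spec, truth=truth)
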