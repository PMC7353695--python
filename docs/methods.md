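# Methods

## Demographic models and simulator

All three candidate demographies describe one panmictic diploid population;
time runs backwards in generations from the present (the generation time is
1 year, so generations and years are interchangeable; every reported time
can be rescaled through `generation_time_years`).

* constant size `Nc`;
* stepwise expansion: size `N` for `t < TEXP`, ancestral size `NA` for
  `t >= TEXP` (two variants differing only in the prior window on the
  expansion time: glacial, 10–40 ka; interglacial, 110–130 ka).

Genealogies are n-coalescent trees under piecewise-constant `Ne(t)`: with
`j` active lineages the coalescence hazard is `j(j-1)/2 / (2 Ne(t))`.
Waiting times are generated by exact piecewise rescaling of unit
exponentials (equivalently: simulate on the coalescent time scale
`tau = ∫ dt / 2Ne(t)` where the process has constant rates, then invert the
piecewise-linear time change).  No rejection sampling is involved, so the
switch point costs nothing.

**SNP loci.** Each unlinked SNP locus receives exactly one mutation, placed
on a branch with probability proportional to its length.  This matches the
data shape of a RAD pipeline that calls a single SNP per locus and
guarantees in-sample polymorphism (derived counts in `[1, n-1]`).  Note the
conditioning: the resulting frequency spectrum is the fixed-S law
`E[L_i/L]`, which slightly enriches singletons relative to the classical
unconditional `P(i) ∝ 1/i` spectrum (at `n = 10` the singleton class is
0.378 vs 0.354).  The tests therefore calibrate against the exact
conditioned law (computed by a times-only Monte-Carlo oracle that
integrates the topology analytically) and against an independent
msprime-based oracle, and check only coarse proportionality to `1/i`.
A minor-allele-frequency cutoff on simulated SNPs is available
(`min MAF`-style filtering via `filter_loci`) but off by default.

**Fast counts-only path.** ABC needs ~10^8 independent SNP genealogies at
realistic scale, so the reference-table generator never builds topologies.
Because Kingman waiting times are independent of the merger chain, and block
sizes when `j` blocks remain are exchangeable with the uniform-composition
law `P(b | j) = C(n-b-1, j-2) / C(n-1, j-1)`, the derived-allele count of a
single branch-proportional mutation can be drawn by (i) sampling the level
waiting times `T_j`, (ii) picking the mutation's level with probability
proportional to the realised `j·T_j`, and (iii) drawing the block size from
the level-conditional law.  This is distribution-identical to the explicit
tree path (verified by a two-sample chi-square in the tests) and runs as a
single-pass numba kernel (~10^6 loci/s on one core) with all randomness
pre-drawn from the caller's numpy generator, so the jitted and pure-numpy
fallback paths are bit-identical.

**Sequence loci** (for π, Tajima's D, Dxy) use infinite sites: a Poisson
number of mutations with mean `mu · L · total branch length`, each at a
fresh site; requests beyond `L` sites saturate with a warning.  The default
`mu = 2.5e-9`/site/generation gives per-site diversities of a few 10^-3 at
the default sizes, the order observed in RAD data from large bird
populations.

**Diploids and missingness.** Haploid lineages `2k, 2k+1` form individual
`k` (random mating; no inbreeding parameter).  Missingness is injected per
genotype call uniformly at random — the filtering rule downstream (max 20%
missing per locus) constrains its amount but real missingness is not
mechanistically modelled.  On the counts-only path, dropping a random
diploid removes two allele copies; since pairing is uniform the retained
derived count is exactly hypergeometric, which is how missingness is
applied there.

## Summary statistics

The ABC summary vector is fixed and ordered: proportion of monomorphic
loci, mean and variance of unbiased gene diversity
`2n/(2n-1) · 2p(1-p)`, and mean minor-allele frequency — the standard
single-population SNP summaries of DIYABC-style analyses.  The identical
kernel is applied to observed matrices (reduced to per-locus allele counts
from non-missing calls) and to simulated reference rows; this symmetry is
mandatory for valid ABC.  Without missing data every simulated locus is
polymorphic, so the monomorphic proportion is constant and is dropped from
the distance (zero-variance statistics are always dropped, with a warning),
leaving three informative statistics.

Descriptive statistics use complete-case allele frequencies per locus.
F_ST is the Weir–Cockerham (1984) multi-locus θ (ratio of sums across
loci) — chosen as the field-standard, well-documented estimator where the
original "distance method" is ambiguous — with a one-sided permutation test
(10,000 permutations by default) reshuffling individuals across the pair of
groups.  Dxy is the mean between-group pairwise difference per site; it is
deliberately diversity-independent and serves as the check on F_ST, which
inflates when within-group diversity is low.  Nei's (1972) `D = -ln I`
treats per-individual frequencies as (0, ½, 1) in individual mode; a
shared-allele identity of zero is reported as the documented cap `D = 50`.
Tajima's D follows the 1989 constants; the pooled value across loci is
computed from pooled totals of S and mean pairwise differences (all loci
must share one sample size).

## Structure diagnostics

PCoA is classical metric scaling (double-centred `-½ J D² J`,
eigendecomposition); coordinates use positive eigenvalues only, and each
axis's share is reported out of the positive-eigenvalue total.  The Mantel
test correlates upper-triangle entries with a one-sided permutation
p-value `(#{r_perm >= r_obs} + 1)/(n_perm + 1)`; the conventional "999
bootstraps" of GenAlEx-style workflows is interpreted as 999 permutations
(Mantel tests permute).  Geographic distances are great-circle (haversine)
from latitude/longitude; no log transform is applied by default.  Evanno's
ΔK is `|L''(K)| / sd(L(K))` over run-averaged STRUCTURE log-likelihoods and
needs ≥3 consecutive K with ≥2 runs each; zero across-run SD flags ΔK
undefined.  Mutual-kNN graphs connect pairs that appear in each other's k
nearest neighbours (stable tie-break by index); automatic selection of k by
community-detection congruence is out of scope, so k defaults to
`ceil(sqrt(n))` in the CLI.

## ABC engine

* Priors: independent uniforms; defaults `NA ~ U(100, 30000)`,
  `N ~ U(10000, 200000)`, `Nc ~ U(100, 200000)`, `TEXP1 ~ U(10000, 40000)`,
  `TEXP2 ~ U(110000, 130000)`, all overridable.
* Distance: Euclidean on statistics standardised by the reference-table SD;
  acceptance keeps a fixed count (default 500) of closest rows, ties broken
  by row index for determinism.
* Weights: Epanechnikov `1 - (d/d_max)²` with bandwidth at the largest
  accepted distance; degenerate all-zero weights fall back to uniform.
* Model choice: accepted-model frequencies, and a weighted multinomial
  logistic regression of the model indicator on statistic deviations
  evaluated at zero deviation (unpenalised fit; falls back to the rejection
  estimate, flagged, if any accepted model has <2 rows).
* Parameter estimation: Beaumont local-linear adjustment on the logit scale
  anchored at the prior bounds (adjusted draws cannot leave the prior
  support); weighted 5/50/95% quantiles; an unfittable regression falls
  back, flagged, to the unadjusted rejection posterior.  A zero-spread
  design (all accepted statistics equal to the observation) is adjusted by
  the identity, as it should be.
* Validation: posterior-predictive percentile checks ("within posterior
  space" = all percentiles in (0.5, 99.5)); the pseudo-observed posterior
  error rate (resampling the accepted rows, scoring each against the table
  with itself excluded); and simulation–reinference bias/precision, with
  injectable simulator/estimator hooks for plumbing tests.

## Problem sizes and what the synthetic conditions show

The canonical reference analysis here uses 20,000–50,000 simulations per
model (the acceptance tests use 50,000; the reproduction script 20,000)
against the original workflow's 10^6 — a deliberate desk-scale choice.  At
these sizes, recovery of the canonical truth (10,000 → 100,000 diploids at
28,000 generations; 2,000 SNPs; 20 individuals) is robust: both model-choice
methods put ≈1.0 on the glacial-expansion model, the pseudo-observed error
rate is ≈0, and the posterior-median expansion time lands at ~30,000–32,000
generations — slightly above truth, a mild upward bias that the regression
adjustment reduces but does not remove.  The SD of posterior medians shrinks
monotonically over 500→3,000 SNPs.

Limitations worth keeping in mind:

* With three informative summary statistics, occasional observed datasets
  fall near the overlap of the glacial and interglacial expansion models;
  at desk-scale reference tables the pseudo-observed error rate can then
  reach ~0.07 rather than 0.  Larger tables and/or richer statistic sets
  tighten this.
* The generator emulates the *downstream products* of a RAD pipeline
  (unlinked biallelic SNPs, one per locus; short alignments).  It does not
  model linkage within loci, allele dropout, paralog collapse, sequencing
  error, population structure, migration, or selection — so passing tests
  demonstrate correctness of the inference machinery under the stated
  model, not robustness to those real-data artefacts.
* Expansion is a single stepwise size change; gradual growth would shift
  the time estimate.

## Numerical choices

Seeds: every stochastic function takes a `numpy.random.Generator`; the CLI
derives all randomness from one `--seed`.  Logit transforms clip parameter
positions to `(1e-10, 1 - 1e-10)` of the prior range before transforming.
Weighted quantiles interpolate the mid-point weighted empirical CDF.  The
Nei-distance cap is 50 natural-log units.  Tie-breaks (acceptance order,
nearest-neighbour lists, model argmax) are by index/model order, making
every result a pure function of inputs and seed.
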