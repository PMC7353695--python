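# coalabc

Coalescent simulation and approximate Bayesian computation (ABC) for
demographic inference from reduced-representation (RAD-seq) SNP data, with
the population-genomic summary statistics and structure diagnostics that
typically accompany such an analysis.

## The problem

Population-genomic studies of montane birds (and many other non-model
organisms) produce a few thousand unlinked biallelic SNPs from 20–30
individuals, plus short (~140 bp) RAD-locus haplotype alignments.  A common
question is whether such a population has been demographically stable or
expanded — and if it expanded, *when*: during a glacial period (when cooling
shifted montane habitat downslope and enlarged it) or during a warm
interglacial.  `coalabc` re-implements that inference end to end on
synthetic data: a coalescent simulator for the candidate demographies, a
DIYABC-style rejection + regression ABC engine for model choice and
parameter estimation, validation tooling (posterior-predictive checks,
pseudo-observed error rates, bias/precision), and a power analysis of
estimation accuracy as a function of SNP count.

## Model and method

Three single-population demographies are compared, parameterised by diploid
effective sizes and times in generations before present (1 year/generation):

* **constant** — size `Nc` throughout;
* **glacial expansion** — stepwise growth from an ancestral `NA` to a
  present `N` at `TEXP1` (prior window 10–40 ka, the last glaciation);
* **interglacial expansion** — the same with `TEXP2` in 110–130 ka.

Genealogies follow the n-coalescent with piecewise-constant `Ne(t)`: while
`j` lineages remain, the coalescence hazard is `j(j-1)/2 · 1/(2Ne(t))`, with
the size change handled by exact piecewise rescaling.  Each SNP locus
carries exactly one mutation placed on a branch with probability
proportional to its length (so every locus is polymorphic in-sample, the
data shape produced by calling one SNP per RAD locus); sequence loci evolve
under the infinite-sites model.

Inference is likelihood-free.  Each simulated or observed dataset is reduced
to a four-statistic summary (proportion of monomorphic loci, mean and
variance of unbiased gene diversity, mean minor-allele frequency).  From a
reference table of prior draws, the 500 simulations closest to the observed
summary (Euclidean distance on SD-standardised statistics) are accepted;
model probabilities come from accepted-model frequencies (*rejection*) and
from a weighted multinomial logistic regression evaluated at the observed
point (*logistic*); parameters are adjusted by Beaumont local-linear
regression on a logit scale anchored to the prior bounds, which keeps the
adjusted draws inside the prior support.

Supporting statistics: observed heterozygosity, effective number of alleles,
PIC, nucleotide diversity π, Tajima's D, Weir–Cockerham F_ST (`θ`) with a
permutation test, Dxy, Nei's (1972) D, net p-distance, PCoA (classical
scaling), individual-based Mantel tests, Evanno ΔK, and mutual-kNN networks.

## Worked example

Simulate a 2,000-SNP dataset for 20 diploids under a glacial expansion from
10,000 to 100,000 at 28,000 generations before present, then infer the
demography back:

```python
import numpy as np
import coalabc as ca
from coalabc.inference import (build_reference_table, default_models,
                               estimate_params, model_choice, reject)

rng = np.random.default_rng(7)
truth = ca.DemographicScenario(kind=ca.ModelKind.EXPANSION_LGM,
                               NA=10_000, N=100_000, TEXP=28_000)
spec = ca.SampleSpec(n_diploid=20, n_snp_loci=2000)
dataset = ca.simulate_dataset(truth, spec, rng)
s_obs = ca.abc_stats(dataset.genotypes)

models = default_models()
table = build_reference_table(models, spec, 20_000, rng)
acc = reject(table, s_obs, n_accept=500)
choice = model_choice(acc)
print(choice.rejection, choice.logistic)
print(estimate_params(acc, 1).quantiles.round(0))
```

Output:

```
{'constant': 0.0, 'expansion_lgm': 1.0, 'expansion_interglacial': 0.0}
{'constant': 0.0, 'expansion_lgm': 1.0, 'expansion_interglacial': 0.0}
            q5    median       q95
NA      5380.0   11511.0   16371.0
N      59551.0  124287.0  172223.0
TEXP1  15683.0   31533.0   39069.0
```

Both model-choice methods put probability 1.0 on the glacial-expansion
model.  The posterior medians recover the simulated truth: `NA` ≈ 11,500
(truth 10,000), `N` ≈ 124,000 (truth 100,000) and an expansion time of
≈ 31,500 generations — near, and characteristically slightly above, the
simulated 28,000, with the 5–95% interval covering the truth.

The same pipeline is scriptable from the shell (`coalabc simulate`,
`coalabc abc-fit`, `coalabc sumstats`, `coalabc structure`,
`coalabc validate`, `coalabc power`); every command takes `--seed` and
writes a JSON run manifest next to its outputs.

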