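"""Power analysis: accuracy of ABC model choice and parameter estimation as a
function of the number of SNPs.

Replicated observed datasets are simulated under a known expansion truth
(by default 10,000 -> 100,000 diploids at 28,000 generations before present,
20 sampled individuals), the full three-model ABC pipeline is run on each,
and per-SNP-count means/SDs of the posterior medians are aggregated along
with the model-misidentification count.  Parameters are always estimated
under the glacial-expansion (truth) model so per-setting summaries stay well
defined; misidentifications are counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .coalsim import DemographicScenario, ModelKind, SampleSpec, simulate_dataset
from .inference import (
    ModelDef,
    build_reference_table,
    default_models,
    estimate_params,
    model_choice,
    reject,
)
from .popgen import abc_stats

__all__ = ["PowerDesign", "PowerReport", "run_power", "summarize_sd_trend"]


def _default_truth() -> DemographicScenario:
    return DemographicScenario(
        kind=ModelKind.EXPANSION_LGM, NA=10_000, N=100_000, TEXP=28_000
    )


@dataclass
class PowerDesign:
    """Design of the simulation study."""

    snp_counts: tuple[int, ...] = (500, 1000, 2000, 3000)
    replicates_per_count: int = 5
    truth: DemographicScenario = field(default_factory=_default_truth)
    n_diploid: int = 20
    n_sims_per_model: int = 20_000
    n_accept: int = 500
    models: list[ModelDef] | None = None

    def __post_init__(self) -> None:
        if self.replicates_per_count < 2:
            raise ValueError("need at least 2 replicates per SNP count for an SD")
        if list(self.snp_counts) != sorted(set(self.snp_counts)):
            raise ValueError("snp_counts must be strictly increasing")


@dataclass
class PowerReport:
    """Aggregated results plus the per-replicate detail."""

    summary: pd.DataFrame  # (snp_count, parameter) -> mean, sd of medians
    misidentified: pd.DataFrame  # per snp_count: replicates, n_misidentified
    replicates: pd.DataFrame  # one row per (snp_count, replicate)


def run_power(design: PowerDesign, rng: np.random.Generator) -> PowerReport:
    """Run the full simulation study.  Pure function of (design, rng state)."""
    models = design.models if design.models is not None else default_models()
    truth_model_index = next(
        i for i, m in enumerate(models) if m.kind == design.truth.kind
    )
    records = []
    for snp_count in design.snp_counts:
        spec = SampleSpec(n_diploid=design.n_diploid, n_snp_loci=snp_count)
        table = build_reference_table(models, spec, design.n_sims_per_model, rng)
        for rep in range(design.replicates_per_count):
            dataset = simulate_dataset(design.truth, spec, rng)
            s_obs = abc_stats(dataset.genotypes)
            acc = reject(table, s_obs, design.n_accept)
            choice = model_choice(acc)
            best = choice.best("logistic")
            record = {
                "snp_count": snp_count,
                "replicate": rep,
                "best_model": best,
                "misidentified": best != models[truth_model_index].name,
                "p_truth_rejection": choice.rejection[models[truth_model_index].name],
                "p_truth_logistic": choice.logistic[models[truth_model_index].name],
            }
            try:
                post = estimate_params(acc, truth_model_index)
                for name in post.param_names:
                    record[f"median_{name}"] = post.median(name)
            except ValueError:
                record["estimation_failed"] = True
            records.append(record)
    detail = pd.DataFrame(records)

    param_names = list(models[truth_model_index].prior.names)
    rows = []
    for snp_count, grp in detail.groupby("snp_count"):
        for name in param_names:
            col = grp.get(f"median_{name}")
            vals = col.dropna() if col is not None else pd.Series(dtype=float)
            rows.append(
                {
                    "snp_count": snp_count,
                    "parameter": name,
                    "mean_median": vals.mean() if len(vals) else np.nan,
                    "sd_median": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "n_replicates": len(vals),
                }
            )
    summary = pd.DataFrame(rows)
    misid = (
        detail.groupby("snp_count")["misidentified"]
        .agg(replicates="count", n_misidentified="sum")
        .reset_index()
    )
    return PowerReport(summary=summary, misidentified=misid, replicates=detail)


def summarize_sd_trend(report: PowerReport) -> pd.DataFrame:
    """Spearman rank correlation of the SD of posterior medians against the
    SNP count, per parameter; verdict "decreasing" iff rho < 0."""
    rows = []
    for name, grp in report.summary.groupby("parameter"):
        grp = grp.dropna(subset=["sd_median"]).sort_values("snp_count")
        if len(grp) < 3:
            continue
        if grp["sd_median"].nunique() == 1:
            rho = 0.0
        else:
            rho = spearmanr(grp["snp_count"], grp["sd_median"]).statistic
        rows.append(
            {
                "parameter": name,
                "spearman_rho": rho,
                "verdict": "decreasing" if rho < 0 else "not decreasing",
            }
        )
    if not rows:
        raise ValueError("need SDs at >= 3 SNP counts for a trend")
    return pd.DataFrame(rows).set_index("parameter")
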