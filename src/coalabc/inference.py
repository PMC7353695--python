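"""Approximate Bayesian computation for demographic model choice and
parameter estimation.

The workflow mirrors the rejection/regression ABC of DIYABC-style analyses:

1. draw parameters from uniform priors and simulate a *reference table* of
   (model, parameter vector, summary-statistic vector) rows;
2. *reject* all but the ``n_accept`` simulations closest to the observed
   statistics (Euclidean distance on statistics standardised by the
   reference-table SD; zero-variance statistics are dropped);
3. model choice by accepted-model *frequency* (rejection) and by a weighted
   multinomial *logistic* regression of model identity on statistic
   deviations evaluated at the observed point;
4. parameter estimation by Beaumont-style *local-linear regression*:
   parameters are mapped through a logit transform to their prior bounds,
   regressed on statistic deviations with Epanechnikov weights, adjusted to
   the observed point and back-transformed (adjusted draws therefore never
   leave the prior support);
5. validation: posterior-predictive percentile checks, the pseudo-observed
   posterior error rate for model selection, and simulation–reinference
   bias/precision of the parameter estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import coalsim
from .coalsim import DemographicScenario, ModelKind, SampleSpec
from .popgen import ABC_STAT_NAMES, abc_stats_from_counts

__all__ = [
    "PriorSpec",
    "ModelDef",
    "default_models",
    "ReferenceTable",
    "Acceptance",
    "ModelChoiceResult",
    "ABCPosterior",
    "ValidationReport",
    "build_reference_table",
    "reject",
    "model_choice",
    "estimate_params",
    "ppc_check",
    "posterior_error_rate",
    "bias_precision",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors, one (lower, upper) pair per parameter."""

    bounds: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for name, lo, hi in self.bounds:
            if not (0 < lo < hi):
                raise ValueError(f"prior for {name} needs 0 < lower < upper, got {(lo, hi)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[2] for b in self.bounds])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, len(self.bounds)))


@dataclass(frozen=True)
class ModelDef:
    """A demographic model template plus its prior.

    ``param_roles`` maps each prior parameter to its role in the piecewise
    description: ``recent`` / ``ancestral`` / ``switch``.  The constant model
    has a single size parameter filling both epoch roles.
    """

    name: str
    kind: ModelKind
    prior: PriorSpec
    param_roles: dict = field(default_factory=dict)

    def piecewise_params(self, draws: np.ndarray):
        """(recent size, ancestral size, switch time) arrays for draws."""
        cols = {name: draws[:, i] for i, name in enumerate(self.prior.names)}
        role = {r: cols[p] for p, r in self.param_roles.items()}
        if self.kind == ModelKind.CONSTANT:
            size = role["recent"]
            return size, size, np.full_like(size, np.inf)
        return role["recent"], role["ancestral"], role["switch"]

    def scenario(self, draw: np.ndarray) -> DemographicScenario:
        params = dict(zip(self.prior.names, draw))
        if self.kind == ModelKind.CONSTANT:
            return DemographicScenario(kind=self.kind, Nc=params[next(iter(params))])
        by_role = {self.param_roles[p]: v for p, v in params.items()}
        return DemographicScenario(
            kind=self.kind,
            N=by_role["recent"],
            NA=by_role["ancestral"],
            TEXP=by_role["switch"],
        )


def default_models(prior_bounds: dict | None = None) -> list[ModelDef]:
    """The three competing scenarios with their default uniform priors.

    Defaults bracket the biologically motivated windows: an expansion during
    the last glaciation (TEXP1 in 10–40 ka) or during the last interglacial
    (TEXP2 in 110–130 ka), ancestral sizes up to 30,000, present sizes up to
    200,000 diploids.  All bounds are overridable through ``prior_bounds``.
    """
    b = {
        "Nc": (100.0, 200000.0),
        "NA": (100.0, 30000.0),
        "N": (10000.0, 200000.0),
        "TEXP1": (10000.0, 40000.0),
        "TEXP2": (110000.0, 130000.0),
    }
    if prior_bounds:
        b.update({k: tuple(v) for k, v in prior_bounds.items()})
    return [
        ModelDef(
            name="constant",
            kind=ModelKind.CONSTANT,
            prior=PriorSpec(bounds=(("Nc", *b["Nc"]),)),
            param_roles={"Nc": "recent"},
        ),
        ModelDef(
            name="expansion_lgm",
            kind=ModelKind.EXPANSION_LGM,
            prior=PriorSpec(bounds=(("NA", *b["NA"]), ("N", *b["N"]), ("TEXP1", *b["TEXP1"]))),
            param_roles={"NA": "ancestral", "N": "recent", "TEXP1": "switch"},
        ),
        ModelDef(
            name="expansion_interglacial",
            kind=ModelKind.EXPANSION_INTERGLACIAL,
            prior=PriorSpec(bounds=(("NA", *b["NA"]), ("N", *b["N"]), ("TEXP2", *b["TEXP2"]))),
            param_roles={"NA": "ancestral", "N": "recent", "TEXP2": "switch"},
        ),
    ]


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Simulated (model, parameters, statistics) rows plus normalisation."""

    models: list[ModelDef]
    model_ids: np.ndarray  # (R,) index into models
    params: list[np.ndarray]  # per model: (n_m, k_m) in prior order
    row_in_model: np.ndarray  # (R,) row index within its model's param block
    stats: np.ndarray  # (R, n_stats)
    stat_names: tuple[str, ...]
    spec: SampleSpec | None = None
    stat_mean: np.ndarray = field(init=False)
    stat_sd: np.ndarray = field(init=False)
    retained: np.ndarray = field(init=False)  # stats with sd > 0

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        self.stat_mean = self.stats.mean(axis=0)
        self.stat_sd = self.stats.std(axis=0)
        self.retained = self.stat_sd > 0
        if not self.retained.any():
            raise ValueError("all summary statistics have zero variance")
        if not self.retained.all():
            dropped = [n for n, r in zip(self.stat_names, self.retained) if not r]
            warnings.warn(
                f"dropping zero-variance statistic(s): {dropped}", UserWarning, stacklevel=2
            )

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def standardise(self, stats: np.ndarray) -> np.ndarray:
        """Project onto the retained statistics, centred and scaled by the
        reference-table mean/SD."""
        stats = np.atleast_2d(np.asarray(stats, dtype=float))
        out = (stats[:, self.retained] - self.stat_mean[self.retained]) / self.stat_sd[
            self.retained
        ]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (model, parameters as columns, statistics)."""
        blocks = []
        for m, model in enumerate(self.models):
            rows = self.model_ids == m
            df = pd.DataFrame(self.params[m], columns=list(model.prior.names))
            df.insert(0, "model", model.name)
            for j, name in enumerate(self.stat_names):
                df[name] = self.stats[rows, j]
            blocks.append(df)
        return pd.concat(blocks, ignore_index=True)


def _simulate_stat_rows(
    n_recent: np.ndarray,
    n_ancestral: np.ndarray,
    t_switch: np.ndarray,
    spec: SampleSpec,
    rng: np.random.Generator,
    chunk_loci: int = 400_000,
) -> np.ndarray:
    """Summary-statistic rows for one parameter draw per row (vectorised)."""
    n_rows = len(n_recent)
    L = spec.n_snp_loci
    n_hap = spec.n_haploid
    out = np.empty((n_rows, len(ABC_STAT_NAMES)))
    rows_per_chunk = max(1, chunk_loci // L)
    for start in range(0, n_rows, rows_per_chunk):
        stop = min(start + rows_per_chunk, n_rows)
        nrep = stop - start
        rec = np.repeat(n_recent[start:stop], L)
        anc = np.repeat(n_ancestral[start:stop], L)
        tsw = np.repeat(t_switch[start:stop], L)
        counts = coalsim.simulate_snp_counts(n_hap, rec, anc, tsw, rng)
        derived, called = coalsim.thin_allele_counts(
            counts, spec.n_diploid, spec.per_locus_missing_rate, rng
        )
        # loci losing every genotype to missingness carry no information;
        # re-draw their missingness pattern so the stat kernel stays defined
        while np.any(called < 2):
            redo = called < 2
            derived[redo], called[redo] = coalsim.thin_allele_counts(
                counts[redo], spec.n_diploid, spec.per_locus_missing_rate, rng
            )
        out[start:stop] = abc_stats_from_counts(
            derived.reshape(nrep, L), called.reshape(nrep, L)
        )
    return out


def build_reference_table(
    models: list[ModelDef],
    spec: SampleSpec,
    n_sims_per_model: int,
    rng: np.random.Generator,
) -> ReferenceTable:
    """Draw from each model's prior, simulate, and tabulate statistics."""
    if n_sims_per_model < 1:
        raise ValueError("n_sims_per_model must be positive")
    params, stats_blocks, ids, row_in_model = [], [], [], []
    for m, model in enumerate(models):
        draws = model.prior.sample(n_sims_per_model, rng)
        rec, anc, tsw = model.piecewise_params(draws)
        stats_blocks.append(_simulate_stat_rows(rec, anc, tsw, spec, rng))
        params.append(draws)
        ids.append(np.full(n_sims_per_model, m))
        row_in_model.append(np.arange(n_sims_per_model))
    with warnings.catch_warnings():
        # a statistic that is constant by construction (e.g. no missing data
        # -> no monomorphic loci) is expected; the table handles it
        warnings.simplefilter("ignore", UserWarning)
        table = ReferenceTable(
            models=models,
            model_ids=np.concatenate(ids),
            params=params,
            row_in_model=np.concatenate(row_in_model),
            stats=np.vstack(stats_blocks),
            stat_names=ABC_STAT_NAMES,
            spec=spec,
        )
    return table


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

@dataclass
class Acceptance:
    """The ``n_accept`` reference rows closest to the observed statistics."""

    table: ReferenceTable
    s_obs: np.ndarray
    indices: np.ndarray  # global row indices, by increasing distance
    distances: np.ndarray
    stat_devs: np.ndarray  # standardised accepted stats minus observed
    weights: np.ndarray  # Epanechnikov in distance

    @property
    def model_ids(self) -> np.ndarray:
        return self.table.model_ids[self.indices]

    @property
    def threshold(self) -> float:
        return float(self.distances.max())

    def params_for_model(self, model_index: int) -> tuple[np.ndarray, np.ndarray]:
        """(accepted parameter rows, their weights) for one model."""
        sel = self.model_ids == model_index
        rows = self.table.row_in_model[self.indices[sel]]
        return self.table.params[model_index][rows], self.weights[sel]


def _epanechnikov(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    w = 1.0 - (d / dmax) ** 2
    return w if w.sum() > 0 else np.ones_like(d)


def reject(table: ReferenceTable, s_obs: np.ndarray, n_accept: int = 500) -> Acceptance:
    """Keep the ``n_accept`` rows closest to ``s_obs`` (Euclidean distance on
    standardised statistics; ties broken by row index)."""
    if not 1 <= n_accept <= table.n_rows:
        raise ValueError(f"n_accept must be in [1, {table.n_rows}]")
    z_obs = table.standardise(s_obs)[0]
    z = table.standardise(table.stats)
    d = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:n_accept]
    return Acceptance(
        table=table,
        s_obs=np.asarray(s_obs, dtype=float),
        indices=order,
        distances=d[order],
        stat_devs=z[order] - z_obs,
        weights=_epanechnikov(d[order]),
    )


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    """Posterior model probabilities by model name."""

    rejection: dict
    logistic: dict
    n_accepted: dict
    logistic_fell_back: bool = False

    def best(self, method: str = "logistic") -> str:
        probs = getattr(self, method)
        # deterministic argmax: highest probability, ties by model order
        best, best_p = None, -1.0
        for name, p in probs.items():
            if p > best_p + 1e-12:
                best, best_p = name, p
        return best


def model_choice(acc: Acceptance, method: str = "both") -> ModelChoiceResult:
    """Posterior model probabilities from an accepted set.

    ``rejection``: each model's frequency among accepted rows.  ``logistic``:
    weighted multinomial logistic regression of the model indicator on
    statistic deviations, evaluated at the observed point (zero deviation);
    falls back to the rejection estimate, flagged, when any accepted model
    has fewer than 2 rows.
    """
    if method not in {"rejection", "logistic", "both"}:
        raise ValueError(f"unknown method {method!r}")
    names = [m.name for m in acc.table.models]
    ids = acc.model_ids
    if len(ids) == 0:
        raise ValueError("empty accepted set")
    counts = {name: int((ids == m).sum()) for m, name in enumerate(names)}
    total = len(ids)
    rejection = {name: counts[name] / total for name in names}

    present = [m for m in range(len(names)) if counts[names[m]] > 0]
    fell_back = False
    if method == "rejection":
        logistic = dict(rejection)
    elif len(present) == 1:
        logistic = {name: 1.0 if counts[name] else 0.0 for name in names}
    elif any(counts[names[m]] < 2 for m in present):
        logistic = dict(rejection)
        fell_back = True
    else:
        from sklearn.linear_model import LogisticRegression

        # effectively unpenalised fit (C -> inf keeps every sklearn version happy)
        clf = LogisticRegression(C=1e10, solver="lbfgs", max_iter=5000)
        clf.fit(acc.stat_devs, ids, sample_weight=acc.weights)
        probs = clf.predict_proba(np.zeros((1, acc.stat_devs.shape[1])))[0]
        logistic = {name: 0.0 for name in names}
        for cls, p in zip(clf.classes_, probs):
            logistic[names[int(cls)]] = float(p)
    return ModelChoiceResult(
        rejection=rejection,
        logistic=logistic,
        n_accepted=counts,
        logistic_fell_back=fell_back,
    )


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    """Weighted quantiles by interpolation of the weighted empirical CDF."""
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cdf = (cw - 0.5 * w) / cw[-1]
    return np.interp(np.atleast_1d(q), cdf, x)


@dataclass
class ABCPosterior:
    """Accepted and regression-adjusted parameter draws for one model."""

    model: str
    param_names: tuple[str, ...]
    raw: np.ndarray
    adjusted: np.ndarray
    weights: np.ndarray
    quantiles: pd.DataFrame  # rows: parameters; columns: q5, median, q95
    threshold: float
    regression_adjusted: bool

    def median(self, name: str) -> float:
        return float(self.quantiles.loc[name, "median"])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw parameter vectors from the adjusted posterior (weighted)."""
        p = self.weights / self.weights.sum()
        return self.adjusted[rng.choice(len(self.adjusted), size=n, p=p)]


def estimate_params(
    acc: Acceptance,
    model_index: int,
    s_obs: np.ndarray | None = None,
) -> ABCPosterior:
    """Beaumont local-linear regression adjustment for one model's accepted
    draws.

    Parameters are logit-transformed to their prior bounds, regressed on the
    standardised statistic deviations with Epanechnikov weights, shifted to
    the observed point, and back-transformed; reported quantiles (5%, median,
    95%) are weighted.  Falls back to the unadjusted rejection posterior,
    flagged, when the regression cannot be fitted.
    """
    model = acc.table.models[model_index]
    theta, w = acc.params_for_model(model_index)
    if len(theta) == 0:
        raise ValueError(f"no accepted draws for model {model.name!r}")
    sel = acc.model_ids == model_index
    X = acc.stat_devs[sel]
    lo, hi = model.prior.lower, model.prior.upper

    eps = 1e-10
    frac = np.clip((theta - lo) / (hi - lo), eps, 1 - eps)
    z = np.log(frac / (1 - frac))

    adjusted_flag = False
    z_adj = z
    if len(theta) >= X.shape[1] + 2 and np.ptp(X, axis=0).max() > 0:
        sw = np.sqrt(np.maximum(w, 0))
        A = np.hstack([np.ones((len(z), 1)), X])
        try:
            beta, *_ = np.linalg.lstsq(A * sw[:, None], z * sw[:, None], rcond=None)
            cand = z - X @ beta[1:]
            if np.isfinite(cand).all():
                z_adj = cand
                adjusted_flag = True
        except np.linalg.LinAlgError:  # pragma: no cover - lstsq rarely fails
            pass
    theta_adj = lo + (hi - lo) * expit(z_adj)

    qs = np.vstack(
        [_weighted_quantile(theta_adj[:, j], w, [0.05, 0.5, 0.95]) for j in range(theta.shape[1])]
    )
    quantiles = pd.DataFrame(
        qs, index=list(model.prior.names), columns=["q5", "median", "q95"]
    )
    return ABCPosterior(
        model=model.name,
        param_names=model.prior.names,
        raw=theta,
        adjusted=theta_adj,
        weights=w,
        quantiles=quantiles,
        threshold=acc.threshold,
        regression_adjusted=adjusted_flag,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    posterior_error_rate: float | None = None
    n_pseudo_observed: int = 0
    bias: pd.DataFrame | None = None  # per parameter: mean_rel_bias, rel_rmse


def ppc_check(
    posterior: ABCPosterior,
    model: ModelDef,
    spec: SampleSpec,
    s_obs: np.ndarray,
    n_draws: int = 500,
    rng: np.random.Generator | None = None,
) -> dict:
    """Posterior-predictive percentile of each observed statistic.

    Simulates ``n_draws`` datasets at parameters drawn from the adjusted
    posterior and reports the (mid-rank) percentile of each observed
    statistic in the predictive cloud; "within posterior space" means every
    percentile lies in (0.5, 99.5).
    """
    if rng is None:
        raise ValueError("ppc_check needs an rng")
    draws = posterior.sample(n_draws, rng)
    rec, anc, tsw = model.piecewise_params(draws)
    sims = _simulate_stat_rows(rec, anc, tsw, spec, rng)
    s_obs = np.asarray(s_obs, dtype=float)
    pct = {}
    for j, name in enumerate(ABC_STAT_NAMES):
        less = (sims[:, j] < s_obs[j]).sum()
        equal = (sims[:, j] == s_obs[j]).sum()
        pct[name] = 100.0 * (less + 0.5 * equal) / n_draws
    pct["within_posterior"] = all(0.5 < v < 99.5 for k, v in pct.items() if k != "within_posterior")
    return pct


def posterior_error_rate(
    table: ReferenceTable,
    s_obs: np.ndarray,
    n_accept: int = 500,
    n_pseudo: int = 500,
    rng: np.random.Generator | None = None,
    method: str = "rejection",
) -> ValidationReport:
    """Model-selection error rate on pseudo-observed datasets.

    Pseudo-observations are sampled with replacement from the ``n_accept``
    rows closest to the observed data; each is scored against the reference
    table with itself excluded, and the error rate is the fraction whose true
    model does not come out on top.
    """
    if n_pseudo < 1:
        raise ValueError("n_pseudo must be positive")
    if rng is None:
        raise ValueError("posterior_error_rate needs an rng")
    acc = reject(table, s_obs, n_accept)
    chosen = rng.choice(acc.indices, size=n_pseudo, replace=True)
    z = table.standardise(table.stats)
    names = [m.name for m in table.models]
    n_wrong = 0
    for row in chosen:
        d = np.sqrt(((z - z[row]) ** 2).sum(axis=1))
        d[row] = np.inf  # leave the pseudo-observed row out of its own scoring
        order = np.argsort(d, kind="stable")[:n_accept]
        ids = table.model_ids[order]
        if method == "rejection":
            counts = np.bincount(ids, minlength=len(names))
            top = int(np.argmax(counts))  # ties -> lowest model id
        else:
            sub = Acceptance(
                table=table,
                s_obs=table.stats[row],
                indices=order,
                distances=d[order],
                stat_devs=z[order] - z[row],
                weights=_epanechnikov(d[order]),
            )
            top_name = model_choice(sub).best("logistic")
            top = names.index(top_name)
        if top != table.model_ids[row]:
            n_wrong += 1
    return ValidationReport(
        posterior_error_rate=n_wrong / n_pseudo, n_pseudo_observed=n_pseudo
    )


def bias_precision(
    table: ReferenceTable,
    posterior: ABCPosterior,
    model_index: int,
    spec: SampleSpec,
    n_datasets: int = 500,
    n_accept: int = 500,
    rng: np.random.Generator | None = None,
    estimator=None,
    simulator=None,
) -> ValidationReport:
    """Simulation–reinference bias and precision of the parameter estimates.

    For each round: draw true parameters from the fitted posterior, simulate
    a dataset, re-estimate (rejection + regression against ``table``), and
    record the relative error of the posterior median.  Validation plumbing:
    ``estimator`` (a callable (s_obs, truth) -> medians) and ``simulator``
    (a callable (truths, rng) -> stat rows) can be injected; the defaults are
    the full ABC re-fit and the coalescent generator.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be positive")
    if rng is None:
        raise ValueError("bias_precision needs an rng")
    model = table.models[model_index]
    truths = posterior.sample(n_datasets, rng)
    if simulator is not None:
        sims = np.asarray(simulator(truths, rng), dtype=float)
    else:
        rec, anc, tsw = model.piecewise_params(truths)
        sims = _simulate_stat_rows(rec, anc, tsw, spec, rng)
    rel_err = np.empty_like(truths)
    for i in range(n_datasets):
        if estimator is not None:
            medians = np.asarray(estimator(sims[i], truths[i]), dtype=float)
        else:
            acc = reject(table, sims[i], n_accept)
            post = estimate_params(acc, model_index)
            medians = post.quantiles["median"].to_numpy()
        rel_err[i] = (medians - truths[i]) / truths[i]
    bias = pd.DataFrame(
        {
            "mean_rel_bias": rel_err.mean(axis=0),
            "rel_rmse": np.sqrt((rel_err**2).mean(axis=0)),
        },
        index=list(model.prior.names),
    )
    return ValidationReport(bias=bias, n_pseudo_observed=n_datasets)
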