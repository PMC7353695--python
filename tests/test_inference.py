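"""ABC engine: reference tables, rejection, model choice, regression
adjustment, and validation machinery."""

import numpy as np
import pytest
from scipy.stats import kstest, norm, truncnorm

import coalabc as ca
from coalabc.coalsim import ModelKind, SampleSpec
from coalabc.inference import (
    Acceptance,
    ModelDef,
    PriorSpec,
    ReferenceTable,
    bias_precision,
    build_reference_table,
    default_models,
    estimate_params,
    model_choice,
    posterior_error_rate,
    ppc_check,
    reject,
)


def _toy_table(stats, model_ids, params_per_model, models):
    """Assemble a ReferenceTable from explicit arrays."""
    model_ids = np.asarray(model_ids)
    row_in_model = np.zeros(len(model_ids), dtype=int)
    for m in range(len(models)):
        rows = np.flatnonzero(model_ids == m)
        row_in_model[rows] = np.arange(len(rows))
    return ReferenceTable(
        models=models,
        model_ids=model_ids,
        params=[np.atleast_2d(p) for p in params_per_model],
        row_in_model=row_in_model,
        stats=np.asarray(stats, dtype=float),
        stat_names=tuple(f"s{i}" for i in range(np.asarray(stats).shape[1])),
    )


def _one_param_model(lo=0.1, hi=20.1, name="toy"):
    return ModelDef(
        name=name,
        kind=ModelKind.CONSTANT,
        prior=PriorSpec(bounds=(("theta", lo, hi),)),
        param_roles={"theta": "recent"},
    )


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

def test_reference_table_shape_and_determinism():
    models = default_models()
    spec = SampleSpec(n_diploid=6, n_snp_loci=30)
    t1 = build_reference_table(models, spec, 100, np.random.default_rng(5))
    t2 = build_reference_table(models, spec, 100, np.random.default_rng(5))
    assert t1.n_rows == 300
    assert [int((t1.model_ids == m).sum()) for m in range(3)] == [100, 100, 100]
    np.testing.assert_array_equal(t1.stats, t2.stats)
    for a, b in zip(t1.params, t2.params):
        np.testing.assert_array_equal(a, b)
    # without missing data every SNP is polymorphic: prop_monomorphic dropped
    assert not t1.retained[0] and t1.retained[1:].all()


def test_prior_marginals_uniform():
    prior = default_models()[1].prior
    draws = prior.sample(10_000, np.random.default_rng(11))
    for j, (name, lo, hi) in enumerate(prior.bounds):
        assert kstest(draws[:, j], "uniform", args=(lo, hi - lo)).pvalue > 0.01


def test_degenerate_prior_rejected():
    with pytest.raises(ValueError):
        PriorSpec(bounds=(("x", 5.0, 5.0),))
    with pytest.raises(ValueError):
        PriorSpec(bounds=(("x", -1.0, 5.0),))


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

def test_reject_exact_match_and_full_acceptance(rng):
    models = [_one_param_model()]
    stats = rng.normal(size=(10, 2))
    table = _toy_table(stats, np.zeros(10, int), [rng.uniform(1, 10, size=(10, 1))], models)
    acc = reject(table, stats[3], n_accept=1)
    assert acc.indices[0] == 3 and acc.distances[0] == 0.0
    assert len(reject(table, stats[3], n_accept=10).indices) == 10
    with pytest.raises(ValueError):
        reject(table, stats[3], n_accept=11)


def test_reject_matches_exhaustive_sort_oracle(rng):
    models = [_one_param_model()]
    stats = rng.normal(size=(10, 3))
    table = _toy_table(stats, np.zeros(10, int), [rng.uniform(1, 10, size=(10, 1))], models)
    s_obs = rng.normal(size=3)
    acc = reject(table, s_obs, n_accept=4)
    # oracle: standardise by table SD, then exhaustive sorted distances
    z = (stats - stats.mean(0)) / stats.std(0)
    zo = (s_obs - stats.mean(0)) / stats.std(0)
    oracle = np.argsort(np.linalg.norm(z - zo, axis=1), kind="stable")[:4]
    np.testing.assert_array_equal(acc.indices, oracle)


def test_reject_drops_zero_variance_statistic(rng):
    models = [_one_param_model()]
    stats = np.column_stack([np.full(20, 7.0), rng.normal(size=20)])
    with pytest.warns(UserWarning, match="zero-variance"):
        table = _toy_table(stats, np.zeros(20, int), [rng.uniform(1, 10, size=(20, 1))], models)
    acc = reject(table, stats[0], n_accept=5)
    assert acc.stat_devs.shape[1] == 1


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

def test_model_choice_symmetric_for_identical_simulators(rng):
    """Three models drawing statistics from one distribution are
    indistinguishable: both methods give ~1/3 each."""
    n = 3000
    models = [_one_param_model(name=f"m{i}") for i in range(3)]
    stats = rng.normal(size=(3 * n, 2))
    ids = np.repeat([0, 1, 2], n)
    table = _toy_table(stats, ids, [rng.uniform(1, 10, size=(n, 1))] * 3, models)
    acc = reject(table, np.zeros(2), n_accept=600)
    res = model_choice(acc)
    for probs in (res.rejection, res.logistic):
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
        for p in probs.values():
            assert abs(p - 1 / 3) < 0.1


def test_model_choice_single_model_and_fallback(rng):
    models = [_one_param_model(name="a"), _one_param_model(name="b")]
    stats = np.vstack([rng.normal(size=(50, 2)), rng.normal(loc=50.0, size=(50, 2))])
    ids = np.repeat([0, 1], 50)
    table = _toy_table(stats, ids, [rng.uniform(1, 10, size=(50, 1))] * 2, models)
    # accepted set is pure model a
    res = model_choice(reject(table, np.zeros(2), n_accept=20))
    assert res.rejection == {"a": 1.0, "b": 0.0}
    assert res.logistic == {"a": 1.0, "b": 0.0}
    # one stray row of model b -> logistic falls back, flagged
    res2 = model_choice(reject(table, np.zeros(2), n_accept=51))
    assert res2.logistic_fell_back
    assert res2.logistic == res2.rejection


def test_model_choice_prefers_true_expansion(rng, expansion_scenario):
    """Observed data simulated under a 10x expansion: the expansion model
    wins with probability ~1 over the constant model by both methods."""
    models = default_models()
    spec = SampleSpec(n_diploid=10, n_snp_loci=500)
    table = build_reference_table(models, spec, 4000, rng)
    ds = ca.simulate_dataset(expansion_scenario, spec, rng)
    acc = reject(table, ca.abc_stats(ds.genotypes), n_accept=200)
    res = model_choice(acc)
    assert res.best("logistic") == "expansion_lgm"
    assert res.logistic["expansion_lgm"] > 0.8
    assert res.rejection["expansion_lgm"] > 0.6


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def test_estimate_params_identity_when_stats_match(rng):
    """Accepted rows with statistics equal to the observation need no
    adjustment: quantiles equal the raw (uniformly weighted) quantiles."""
    models = [_one_param_model(lo=1.0, hi=11.0)]
    theta = rng.uniform(1.0, 11.0, size=(30, 1))
    stats = np.vstack([np.tile([1.0, 2.0], (10, 1)), rng.normal(10, 1, size=(20, 2))])
    table = _toy_table(stats, np.zeros(30, int), [theta], models)
    acc = reject(table, np.array([1.0, 2.0]), n_accept=10)
    post = estimate_params(acc, 0)
    raw_sorted = np.sort(theta[acc.indices, 0])
    assert post.median("theta") == pytest.approx(np.median(raw_sorted), rel=0.05)
    np.testing.assert_allclose(post.adjusted, post.raw, atol=1e-9)


def test_abc_posterior_matches_conjugate_oracle(rng):
    """Toy model theta ~ U(0.1, 20.1), stat = theta + N(0,1): the ABC
    posterior mean is within 0.1 of the analytic truncated-normal posterior
    and adjusted draws never leave the prior support."""
    lo, hi = 0.1, 20.1
    n_sims, n_accept = 100_000, 500
    models = [_one_param_model(lo, hi)]
    theta = rng.uniform(lo, hi, size=(n_sims, 1))
    stats = theta + rng.normal(size=(n_sims, 1))
    table = _toy_table(stats, np.zeros(n_sims, int), [theta], models)
    for s_obs in (5.0, 10.0, 16.0):
        acc = reject(table, np.array([s_obs]), n_accept=n_accept)
        post = estimate_params(acc, 0)
        analytic = truncnorm.mean((lo - s_obs) / 1.0, (hi - s_obs) / 1.0, loc=s_obs, scale=1.0)
        abc_mean = np.average(post.adjusted[:, 0], weights=post.weights)
        assert abs(abc_mean - analytic) < 0.1
        assert post.adjusted.min() > lo and post.adjusted.max() < hi
        q = post.quantiles.loc["theta"]
        assert q["q5"] <= q["median"] <= q["q95"]


def test_posterior_quantiles_invariant_to_stat_order_and_scale(rng):
    """Standardisation makes the fit invariant to reordering statistics or
    rescaling any one of them."""
    models = [_one_param_model(1.0, 11.0)]
    theta = rng.uniform(1.0, 11.0, size=(2000, 1))
    stats = np.column_stack([theta[:, 0] + rng.normal(size=2000),
                             2 * theta[:, 0] + rng.normal(size=2000)])
    s_obs = np.array([6.0, 12.0])

    def fit(stats_mod, s_obs_mod):
        table = _toy_table(stats_mod, np.zeros(2000, int), [theta], models)
        return estimate_params(reject(table, s_obs_mod, 300), 0).quantiles

    base = fit(stats, s_obs)
    swapped = fit(stats[:, ::-1], s_obs[::-1])
    scaled = fit(stats * np.array([1000.0, 1.0]), s_obs * np.array([1000.0, 1.0]))
    np.testing.assert_allclose(base, swapped, rtol=1e-9)
    np.testing.assert_allclose(base, scaled, rtol=1e-9)


# ---------------------------------------------------------------------------
# validation machinery
# ---------------------------------------------------------------------------

def test_ppc_deterministic_and_detects_misfit(rng, expansion_scenario):
    models = default_models()
    spec = SampleSpec(n_diploid=8, n_snp_loci=120)
    table = build_reference_table(models, spec, 1500, rng)
    ds = ca.simulate_dataset(expansion_scenario, spec, rng)
    s_obs = ca.abc_stats(ds.genotypes)
    acc = reject(table, s_obs, 200)
    post = estimate_params(acc, 1)
    r1 = ppc_check(post, models[1], spec, s_obs, n_draws=150, rng=np.random.default_rng(9))
    r2 = ppc_check(post, models[1], spec, s_obs, n_draws=150, rng=np.random.default_rng(9))
    assert r1 == r2
    assert r1["within_posterior"]
    # an impossible observation sits at percentile 0 or 100
    crazy = np.array([0.0, 5.0, 5.0, 5.0])
    r3 = ppc_check(post, models[1], spec, crazy, n_draws=100, rng=np.random.default_rng(9))
    assert not r3["within_posterior"]
    assert r3["mean_gene_diversity"] == 100.0


def test_error_rate_half_for_identical_models(rng):
    """Two models with the same simulator cannot be told apart: the
    pseudo-observed error rate sits near 1/2."""
    n = 2000
    models = [_one_param_model(name="a"), _one_param_model(name="b")]
    stats = rng.normal(size=(2 * n, 2))
    table = _toy_table(stats, np.repeat([0, 1], n), [rng.uniform(1, 10, size=(n, 1))] * 2, models)
    rep = posterior_error_rate(table, np.zeros(2), n_accept=200, n_pseudo=300, rng=rng)
    assert 0.35 < rep.posterior_error_rate < 0.65
    with pytest.raises(ValueError):
        posterior_error_rate(table, np.zeros(2), n_pseudo=0, rng=rng)


def test_bias_precision_stub_estimator_gives_zero(rng):
    models = [_one_param_model(1.0, 11.0)]
    theta = rng.uniform(1.0, 11.0, size=(500, 1))
    stats = theta + rng.normal(size=(500, 1))
    table = _toy_table(stats, np.zeros(500, int), [theta], models)
    table.spec = SampleSpec(n_diploid=4, n_snp_loci=10)
    acc = reject(table, np.array([6.0]), 100)
    post = estimate_params(acc, 0)
    rep = bias_precision(
        table, post, 0, table.spec, n_datasets=50, rng=rng,
        estimator=lambda s_obs, truth: truth,
        simulator=lambda truths, r: truths + r.normal(size=truths.shape),
    )
    assert rep.bias["mean_rel_bias"].abs().max() == 0.0
    assert rep.bias["rel_rmse"].max() == 0.0


def test_bias_precision_small_on_conjugate_toy(rng):
    """Full re-estimation loop on the toy model: relative bias < 5%."""
    lo, hi = 0.1, 20.1
    models = [_one_param_model(lo, hi)]
    theta = rng.uniform(lo, hi, size=(40_000, 1))
    stats = theta + rng.normal(size=(40_000, 1))
    table = _toy_table(stats, np.zeros(40_000, int), [theta], models)
    acc = reject(table, np.array([10.0]), 500)
    post = estimate_params(acc, 0)

    def toy_estimator(s_obs, truth):
        a = reject(table, np.atleast_1d(s_obs), 500)
        return estimate_params(a, 0).quantiles["median"].to_numpy()

    rep = bias_precision(
        table, post, 0, SampleSpec(n_diploid=4, n_snp_loci=10),
        n_datasets=150, rng=rng, estimator=toy_estimator,
        simulator=lambda truths, r: truths + r.normal(size=truths.shape),
    )
    assert abs(rep.bias.loc["theta", "mean_rel_bias"]) < 0.05
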