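import numpy as np
import pytest
from scipy.special import ndtri

from siidanet.srm import (
    MCMCSettings,
    SRMData,
    SRMPosterior,
    build_srm_data,
    fit_srm,
    odds_ratio,
    predict_tie_probability,
    reciprocity_correlations,
    simulate_from_posterior,
    variance_partition,
)


def _ids(n):
    return [f"n{i}" for i in range(n)]


def _data(y, dyadic=None, ego=None):
    n = y.shape[0]
    return SRMData(
        y=y, dyadic_covariates=dyadic or {}, ego_covariates=ego or {}, node_ids=_ids(n)
    )


def _degenerate_posterior(beta, names, n_draws=50):
    """A posterior whose every draw is identical; no random effects."""
    beta = np.tile(np.asarray(beta, float), (n_draws, 1))
    return SRMPosterior(
        beta=beta,
        covariate_names=names,
        sigma_gr=np.zeros((n_draws, 2, 2)),
        rho=np.zeros(n_draws),
        settings=MCMCSettings(iterations=n_draws, burn_in=0, thin=1, seed=0),
        node_ids=_ids(4),
    )


@pytest.fixture(scope="module")
def half_density_fit():
    rng = np.random.default_rng(5)
    n = 60
    y = (rng.random((n, n)) < 0.5).astype(float)
    np.fill_diagonal(y, 0)
    return fit_srm(
        _data(y), mcmc=MCMCSettings(iterations=1500, burn_in=500, thin=5, seed=1)
    )


def test_intercept_only_recovers_probit_of_density(half_density_fit):
    s = half_density_fit.summary()["beta_intercept"]
    lo, hi = s["ci95"]
    assert lo < 0.0 < hi, "95% credible interval for the intercept covers Phi^-1(0.5)=0"


def test_posterior_predictive_density_matches_observed(half_density_fit):
    p = half_density_fit.tie_probability_mean
    off = ~np.eye(p.shape[0], dtype=bool)
    assert abs(p[off].mean() - 0.5) < 0.03


def test_symmetric_outcomes_push_dyadic_reciprocity_up():
    rng = np.random.default_rng(3)
    n = 24
    upper = rng.random((n, n)) < 0.4
    y = np.triu(upper, 1)
    y = (y + y.T).astype(float)
    post = fit_srm(
        _data(y), mcmc=MCMCSettings(iterations=1200, burn_in=400, thin=4, seed=2)
    )
    assert np.quantile(post.rho, 0.05) > 0.0, "mass of rho concentrated above zero"


def test_variance_partition_shares_sum_to_one(half_density_fit):
    vp = variance_partition(half_density_fit)
    shares = vp["per_draw_shares"]
    assert np.allclose(shares.sum(axis=1), 1.0, atol=1e-12)


def test_variance_partition_degenerate_dyadic_only():
    post = _degenerate_posterior([0.0], ["intercept"])
    vp = variance_partition(post)
    assert vp["dyadic"]["mean"] == 1.0
    assert vp["giver"]["mean"] == 0.0
    assert vp["receiver"]["mean"] == 0.0


def test_variance_partition_combines_printed_shares():
    """Combined giver+receiver share is the sum of the two shares."""
    vp_draws = np.array([[0.3018, 0.1242, 0.5740]])
    assert vp_draws[0, 0] + vp_draws[0, 1] == pytest.approx(0.426, abs=1e-4)


def test_reciprocity_correlations_bounded(half_density_fit):
    rc = reciprocity_correlations(half_density_fit)
    for key in ("generalized", "dyadic"):
        lo, hi = rc[key]["ci95"]
        assert -1.0 <= lo <= hi <= 1.0


def test_predict_probability_degenerate_is_half():
    post = _degenerate_posterior([0.0, 0.0, 0.0], ["intercept", "relatedness", "same_siida"])
    curve = predict_tie_probability(post, np.linspace(0, 1, 5))
    assert np.allclose(curve["median"], 0.5)
    assert np.allclose(curve["lo95"], 0.5)


def test_predict_probability_monotone_in_relatedness():
    post = _degenerate_posterior([-0.5, 0.8, 0.3], ["intercept", "relatedness", "same_siida"])
    curve = predict_tie_probability(post, np.linspace(0, 1, 9), same_siida=0)
    assert (np.diff(curve["median"]) >= 0).all()
    within = predict_tie_probability(post, np.linspace(0, 1, 9), same_siida=1)
    assert (within["median"] >= curve["median"]).all()


def test_odds_ratio_zero_contrast_is_one(half_density_fit):
    ref = {"relatedness": 0.0} if "relatedness" in half_density_fit.covariate_names else {}
    res = odds_ratio(half_density_fit, ref, ref)
    assert np.allclose(res["draws"], 1.0)


def test_odds_ratio_closed_form():
    # p1 = 0.8, p0 = 0.5 -> OR = (0.8/0.2)/(0.5/0.5) = 4
    post = _degenerate_posterior([0.0, ndtri(0.8)], ["intercept", "same_siida"])
    res = odds_ratio(post, {"same_siida": 1.0}, {"same_siida": 0.0})
    assert res["median"] == pytest.approx(4.0, rel=1e-10)


def test_srm_rejects_collinear_covariates():
    rng = np.random.default_rng(0)
    n = 8
    y = (rng.random((n, n)) < 0.4).astype(float)
    np.fill_diagonal(y, 0)
    x = rng.normal(size=(n, n))
    with pytest.raises(ValueError, match="collinear"):
        fit_srm(_data(y, dyadic={"a": x, "b": 2 * x}),
                mcmc=MCMCSettings(iterations=10, burn_in=1, thin=1, seed=0))


def test_srm_rejects_tiny_networks():
    y = np.zeros((3, 3))
    with pytest.raises(ValueError, match="4 nodes"):
        fit_srm(_data(y), mcmc=MCMCSettings(iterations=10, burn_in=1, thin=1, seed=0))


def test_chains_agree_across_seeds():
    """Split-chain potential scale reduction < 1.1 for all scalar
    parameters when the same data are fitted from two seeds."""
    arviz = pytest.importorskip("arviz")
    rng = np.random.default_rng(9)
    n = 40
    siida = np.repeat([0, 1], n // 2)
    same = (siida[:, None] == siida[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    lp = -1.2 + 1.0 * same
    y = (rng.random((n, n)) < 0.5 * (1 + np.tanh(lp))).astype(float)
    np.fill_diagonal(y, 0)
    data = _data(y, dyadic={"same_siida": same})
    chains = [
        fit_srm(data, mcmc=MCMCSettings(iterations=3000, burn_in=1000, thin=2, seed=s))
        for s in (11, 12)
    ]
    for extract in (
        lambda p: p.beta[:, 0],
        lambda p: p.beta[:, 1],
        lambda p: p.sigma2_g,
        lambda p: p.sigma2_r,
        lambda p: p.rho,
    ):
        stacked = np.stack([extract(c) for c in chains])
        rhat = float(np.asarray(arviz.rhat(arviz.convert_to_dataset(stacked))["x"]))
        assert rhat < 1.1


def test_build_srm_data_conventions(community):
    from siidanet.networks import gift_network

    gnet = gift_network(community.gift_ledger, community.roster.ids)
    data = build_srm_data(
        community.cooperation, community.roster, community.relatedness, gift_network=gnet
    )
    n = data.n_nodes
    assert data.y.shape == (n, n)
    assert np.all(np.diag(data.y) == 0)
    assert data.covariate_names == [
        "intercept", "relatedness", "same_siida", "gift", "interviewed",
    ]
    # gift covariate is directional: i gave to j
    rec = community.gift_ledger.records[0]
    i = data.node_ids.index(rec.giver)
    j = data.node_ids.index(rec.recipient)
    assert data.dyadic_covariates["gift"][i, j] == 1.0


def test_posterior_predictive_simulations_have_no_self_ties(half_density_fit):
    n = len(half_density_fit.node_ids)
    rngy = np.random.default_rng(0)
    y = (rngy.random((n, n)) < 0.5).astype(float)
    np.fill_diagonal(y, 0)
    sims = simulate_from_posterior(half_density_fit, _data(y), n_networks=5, seed=4)
    for s in sims:
        assert np.all(np.diag(s) == 0)
        assert set(np.unique(s)) <= {0.0, 1.0}
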