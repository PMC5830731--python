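"""Binary probit social relations model (SRM) fitted by Gibbs sampling.

The SRM decomposes directed dyadic outcomes into giver, receiver and
relationship components. For ordered dyad (i, j), a latent propensity

    z_ij = x_d(i,j)' beta_d + x_g(i)' beta_g + intercept + g_i + r_j + d_ij

generates the observed tie y_ij = 1(z_ij > 0). Giver/receiver effects
(g_i, r_i) are mean-zero bivariate normal with free covariance; their
correlation measures *generalized reciprocity* (people who name many others
also get named). The within-dyad errors (d_ij, d_ji) are bivariate normal
with unit marginal variance (the probit identification constraint) and free
correlation rho, the *dyadic reciprocity*.

The sampler is a data-augmentation Gibbs scheme:

* latent z: truncated-normal draws, each direction conditioned on the other
  through rho;
* coefficients: conjugate normal update after pairwise decorrelating the
  two directions of each dyad (a GLS whitening with the 2x2 dyadic
  covariance);
* (g_i, r_i): exact bivariate conjugate update per node, scanning nodes in
  sequence given the others;
* giver-receiver covariance: conjugate inverse-Wishart;
* rho: random-walk Metropolis on (-1, 1) under a uniform prior.

Priors default to weakly informative choices standard in additive
network-effects modelling: Normal(0, 5^2) on all coefficients,
inverse-Wishart(df 4, scale I) on the 2x2 covariance, uniform(-1, 1) on rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart

from .io import Roster
from .kinship import RelatednessMatrix
from .networks import DirectedBinaryNetwork

__all__ = [
    "SRMData",
    "SRMPriors",
    "MCMCSettings",
    "SRMPosterior",
    "build_srm_data",
    "fit_srm",
    "variance_partition",
    "reciprocity_correlations",
    "predict_tie_probability",
    "odds_ratio",
    "simulate_from_posterior",
]

_U_EPS = 1e-12


@dataclass
class SRMData:
    """Dyadic outcome matrix plus covariates, in one fixed node ordering.

    ``y`` is an (n, n) 0/1 matrix with a structurally missing diagonal;
    ``dyadic_covariates`` maps names to (n, n) matrices; ``ego_covariates``
    maps names to length-n vectors applied to the sending side.
    """

    y: np.ndarray
    dyadic_covariates: dict[str, np.ndarray]
    ego_covariates: dict[str, np.ndarray]
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.node_ids)
        if self.y.shape != (n, n):
            raise ValueError("y must be square with one row per node id")
        off = ~np.eye(n, dtype=bool)
        vals = self.y[off]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("off-diagonal outcomes must be 0 or 1")
        for name, m in self.dyadic_covariates.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n) or not np.isfinite(m[off]).all():
                raise ValueError(f"dyadic covariate {name!r} must be finite and (n, n)")
            self.dyadic_covariates[name] = m
        for name, v in self.ego_covariates.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (n,) or not np.isfinite(v).all():
                raise ValueError(f"ego covariate {name!r} must be a finite length-n vector")
            self.ego_covariates[name] = v

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def covariate_names(self) -> list[str]:
        return ["intercept"] + list(self.dyadic_covariates) + list(self.ego_covariates)

    def design_tensor(self) -> np.ndarray:
        """(n, n, p) design array; column 0 is the intercept."""
        n = self.n_nodes
        cols = [np.ones((n, n))]
        cols += [self.dyadic_covariates[k] for k in self.dyadic_covariates]
        cols += [np.broadcast_to(self.ego_covariates[k][:, None], (n, n)).copy()
                 for k in self.ego_covariates]
        return np.stack(cols, axis=-1)


def build_srm_data(
    cooperation: DirectedBinaryNetwork,
    roster: Roster,
    relatedness: RelatednessMatrix,
    gift_network: DirectedBinaryNetwork | None = None,
    include_interviewed_ego: bool = True,
) -> SRMData:
    """Assemble SRM inputs for the cooperation network among licence owners.

    The outcome universe is all ordered dyads of licence owners. Rows of
    egos who were not interviewed are kept as observed zeros, with the
    interviewed indicator as an ego-level fixed effect absorbing their
    structurally lower naming rate. The gift covariate is directional:
    1 iff the ego gave the alter a gift.
    """
    ids = [i for i in roster.ids if i in set(roster.licensed_ids)]
    n = len(ids)
    idx = {v: k for k, v in enumerate(ids)}
    y = np.zeros((n, n))
    for i, j in cooperation.edges:
        if i in idx and j in idx:
            y[idx[i], idx[j]] = 1.0
    sub = roster.table.set_index("id").loc[ids]
    siida = sub["siida"].to_numpy()
    same = (siida[:, None] == siida[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    rel_idx = [relatedness.ids.index(i) for i in ids]
    rel = relatedness.values[np.ix_(rel_idx, rel_idx)].copy()
    np.fill_diagonal(rel, 0.0)
    dyadic = {"relatedness": rel, "same_siida": same}
    if gift_network is not None:
        gift = np.zeros((n, n))
        for i, j in gift_network.edges:
            if i in idx and j in idx:
                gift[idx[i], idx[j]] = 1.0
        dyadic["gift"] = gift
    ego = {}
    if include_interviewed_ego:
        ego["interviewed"] = sub["interviewed"].to_numpy(dtype=float)
    return SRMData(y=y, dyadic_covariates=dyadic, ego_covariates=ego, node_ids=ids)


@dataclass(frozen=True)
class SRMPriors:
    beta_mean: float = 0.0
    beta_sd: float = 5.0
    iw_df: float = 4.0
    iw_scale: tuple = ((1.0, 0.0), (0.0, 1.0))

    def __post_init__(self) -> None:
        if self.beta_sd <= 0:
            raise ValueError("beta_sd must be positive")
        if self.iw_df < 3:
            raise ValueError("inverse-Wishart df must be >= 3 for a 2x2 scale")


@dataclass(frozen=True)
class MCMCSettings:
    iterations: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class SRMPosterior:
    """Thinned post-burn-in draws from the SRM posterior."""

    beta: np.ndarray                 # (ndraws, p)
    covariate_names: list[str]
    sigma_gr: np.ndarray             # (ndraws, 2, 2)
    rho: np.ndarray                  # (ndraws,)
    settings: MCMCSettings
    node_ids: list[str]
    tie_probability_mean: np.ndarray | None = None   # (n, n), conditional on g, r
    accept_rate_rho: float = float("nan")

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def sigma2_g(self) -> np.ndarray:
        return self.sigma_gr[:, 0, 0]

    @property
    def sigma2_r(self) -> np.ndarray:
        return self.sigma_gr[:, 1, 1]

    @property
    def cor_gr(self) -> np.ndarray:
        denom = np.sqrt(self.sigma2_g * self.sigma2_r)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(denom > 0, self.sigma_gr[:, 0, 1] / denom, 0.0)
        return np.clip(c, -1.0, 1.0)

    def beta_named(self, name: str) -> np.ndarray:
        return self.beta[:, self.covariate_names.index(name)]

    def summary(self) -> dict:
        out = {}
        for k, name in enumerate(self.covariate_names):
            d = self.beta[:, k]
            out[f"beta_{name}"] = _summ(d)
        out["sigma2_giver"] = _summ(self.sigma2_g)
        out["sigma2_receiver"] = _summ(self.sigma2_r)
        out["cor_giver_receiver"] = _summ(self.cor_gr)
        out["rho_dyadic"] = _summ(self.rho)
        return out


def _summ(d: np.ndarray) -> dict:
    lo, hi = np.quantile(d, [0.025, 0.975])
    return {
        "mean": float(np.mean(d)),
        "sd": float(np.std(d)),
        "median": float(np.median(d)),
        "ci95": [float(lo), float(hi)],
    }


def _truncated_normal(mean, sd, y, u):
    """Inverse-CDF truncated-normal draw: positive where y=1, else <= 0."""
    p0 = ndtr(-mean / sd)  # P(z <= 0)
    u = np.clip(u, _U_EPS, 1 - _U_EPS)
    # y=1: sample u' in (p0, 1); y=0: sample u' in (0, p0)
    up = np.where(y > 0.5, p0 + u * (1 - p0), u * p0)
    up = np.clip(up, _U_EPS, 1 - _U_EPS)
    z = mean + sd * ndtri(up)
    return np.where(y > 0.5, np.maximum(z, 0.0), np.minimum(z, 0.0))


def fit_srm(
    data: SRMData,
    priors: SRMPriors = SRMPriors(),
    mcmc: MCMCSettings = MCMCSettings(),
    random_effects: bool = True,
) -> SRMPosterior:
    """Fit the probit SRM by data-augmentation Gibbs sampling.

    With ``random_effects=False`` the giver/receiver effects and the dyadic
    correlation are fixed at zero and the sampler reduces exactly to
    Bayesian probit regression on the dyadic design (Albert–Chib).
    """
    n = data.n_nodes
    if n < 4:
        raise ValueError("need at least 4 nodes to fit the SRM")
    X = data.design_tensor()              # (n, n, p)
    p = X.shape[-1]
    Xf = X.reshape(n * n, p)
    rank = np.linalg.matrix_rank(Xf)
    if rank < p:
        raise ValueError("covariates are collinear to machine precision")
    y = data.y
    off = ~np.eye(n, dtype=bool)
    iu = np.triu_indices(n, k=1)
    il = (iu[1], iu[0])

    rng = np.random.default_rng(mcmc.seed)

    # prior
    b0 = np.full(p, priors.beta_mean)
    B0_inv = np.eye(p) / priors.beta_sd**2
    iw_df0 = priors.iw_df
    iw_S0 = np.asarray(priors.iw_scale, dtype=float)

    # pairwise sums/differences of design rows, fixed across iterations
    Xu = X[iu]                            # (m, p)
    Xl = X[il]
    Xs = Xu + Xl
    Xd = Xu - Xl
    Gs = Xs.T @ Xs
    Gd = Xd.T @ Xd

    # state
    beta = np.zeros(p)
    beta[0] = ndtri(np.clip(y[off].mean(), 1e-3, 1 - 1e-3))
    g = np.zeros(n)
    r = np.zeros(n)
    Sigma = np.eye(2) * 0.25
    rho = 0.0
    z = np.where(y > 0.5, 0.5, -0.5)
    np.fill_diagonal(z, 0.0)

    n_keep = mcmc.n_draws
    out_beta = np.empty((n_keep, p))
    out_sigma = np.empty((n_keep, 2, 2))
    out_rho = np.empty(n_keep)
    prob_sum = np.zeros((n, n))
    kept = 0
    rho_step = max(0.02, 1.2 / np.sqrt(len(iu[0])))
    rho_acc = 0
    rho_tries = 0

    for it in range(mcmc.iterations):
        mu = X @ beta + g[:, None] + r[None, :]

        # --- latent z, one triangle at a time, conditioning through rho
        sd_c = np.sqrt(max(1.0 - rho**2, 1e-12))
        m_u = mu[iu] + rho * (z[il] - mu[il])
        z[iu] = _truncated_normal(m_u, sd_c, y[iu], rng.random(len(iu[0])))
        m_l = mu[il] + rho * (z[iu] - mu[iu])
        z[il] = _truncated_normal(m_l, sd_c, y[il], rng.random(len(iu[0])))
        if not np.isfinite(z[off]).all():
            raise FloatingPointError(
                f"non-finite latent propensity at iteration {it}; the chain diverged"
            )

        # --- coefficients (GLS whitening of the dyad pairs)
        w = z - g[:, None] - r[None, :]
        ws = w[iu] + w[il]
        wd = w[iu] - w[il]
        a_s = 1.0 / (2.0 * max(1.0 + rho, 1e-12))
        a_d = 1.0 / (2.0 * max(1.0 - rho, 1e-12))
        prec = B0_inv + a_s * Gs + a_d * Gd
        rhs = B0_inv @ b0 + a_s * (Xs.T @ ws) + a_d * (Xd.T @ wd)
        cf = np.linalg.cholesky(prec)
        mean_b = np.linalg.solve(prec, rhs)
        beta = mean_b + np.linalg.solve(cf.T, rng.standard_normal(p))

        if random_effects:
            # --- (g_i, r_i) scan: exact bivariate conjugate update per node
            h = z - X @ beta
            rowsum = h.sum(axis=1) - np.diag(h)
            colsum = h.sum(axis=0) - np.diag(h)
            a = 1.0 / max(1.0 - rho**2, 1e-12)
            b = -rho * a
            Rinv = np.array([[a, b], [b, a]])
            Sg = g.sum()
            Sr = r.sum()
            Sigma_inv = np.linalg.inv(Sigma)
            P = Sigma_inv + (n - 1) * Rinv
            Pc = np.linalg.cholesky(np.linalg.inv(P))
            for i in range(n):
                usum = np.array(
                    [rowsum[i] - (Sr - r[i]), colsum[i] - (Sg - g[i])]
                )
                mean_i = np.linalg.solve(P, Rinv @ usum)
                draw = mean_i + Pc @ rng.standard_normal(2)
                Sg += draw[0] - g[i]
                Sr += draw[1] - r[i]
                g[i], r[i] = draw

            # --- giver-receiver covariance
            GR = np.column_stack([g, r])
            Sigma = invwishart.rvs(
                df=iw_df0 + n, scale=iw_S0 + GR.T @ GR, random_state=rng
            )

            # --- dyadic correlation (random-walk Metropolis, uniform prior)
            d = z - X @ beta - g[:, None] - r[None, :]
            du, dl = d[iu], d[il]
            prop = rho + rng.normal(0.0, rho_step)
            rho_tries += 1
            if -1.0 < prop < 1.0:
                ll_cur = _bvn_pair_loglik(du, dl, rho)
                ll_prop = _bvn_pair_loglik(du, dl, prop)
                if np.log(rng.random()) < ll_prop - ll_cur:
                    rho = prop
                    rho_acc += 1

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and kept < n_keep:
            out_beta[kept] = beta
            out_sigma[kept] = Sigma if random_effects else np.zeros((2, 2))
            out_rho[kept] = rho
            prob_sum += ndtr(X @ beta + g[:, None] + r[None, :])
            kept += 1

    prob = prob_sum / max(kept, 1)
    np.fill_diagonal(prob, 0.0)
    return SRMPosterior(
        beta=out_beta[:kept],
        covariate_names=data.covariate_names,
        sigma_gr=out_sigma[:kept],
        rho=out_rho[:kept],
        settings=mcmc,
        node_ids=list(data.node_ids),
        tie_probability_mean=prob,
        accept_rate_rho=(rho_acc / rho_tries) if rho_tries else float("nan"),
    )


def _bvn_pair_loglik(du: np.ndarray, dl: np.ndarray, rho: float) -> float:
    one_m = 1.0 - rho**2
    q = (du**2 - 2.0 * rho * du * dl + dl**2) / one_m
    return float(-0.5 * len(du) * np.log(one_m) - 0.5 * q.sum())


# ---------------------------------------------------------------------------
# posterior summaries


def variance_partition(posterior: SRMPosterior) -> dict:
    """Giver / receiver / dyadic shares of the latent random variance.

    Per draw the dyadic variance is the unit probit residual variance;
    shares are (sigma2_g, sigma2_r, 1) normalized to sum to 1. The combined
    giver+receiver share quantifies how much of tie variation is owed to
    individuals' roles rather than to unique relationships.
    """
    s2g, s2r = posterior.sigma2_g, posterior.sigma2_r
    total = s2g + s2r + 1.0
    shares = np.column_stack([s2g / total, s2r / total, 1.0 / total])
    out = {
        name: _summ(shares[:, k])
        for k, name in enumerate(["giver", "receiver", "dyadic"])
    }
    out["giver_plus_receiver"] = _summ(shares[:, 0] + shares[:, 1])
    out["per_draw_shares"] = shares
    return out


def reciprocity_correlations(posterior: SRMPosterior) -> dict:
    """Generalized (giver-receiver) and dyadic reciprocity correlations."""
    return {
        "generalized": _summ(posterior.cor_gr),
        "dyadic": _summ(posterior.rho),
    }


def _marginal_probability(
    posterior: SRMPosterior, covariates: dict[str, float]
) -> np.ndarray:
    """Per-draw tie probability at given covariates, random effects
    integrated out: Phi(x'beta / sqrt(1 + sigma2_g + sigma2_r))."""
    x = np.zeros(len(posterior.covariate_names))
    x[0] = 1.0
    for name, val in covariates.items():
        x[posterior.covariate_names.index(name)] = val
    lp = posterior.beta @ x
    scale = np.sqrt(1.0 + posterior.sigma2_g + posterior.sigma2_r)
    return ndtr(lp / scale)


def predict_tie_probability(
    posterior: SRMPosterior,
    relatedness_grid: np.ndarray,
    same_siida: int = 0,
    gift: int | None = None,
    extra: dict[str, float] | None = None,
) -> dict:
    """Posterior median and central 95% interval of P(tie) over a
    relatedness grid, at fixed same-siida / gift covariates."""
    grid = np.asarray(relatedness_grid, dtype=float)
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("relatedness grid values must lie in [0, 1]")
    med = np.empty_like(grid)
    lo = np.empty_like(grid)
    hi = np.empty_like(grid)
    for k, rv in enumerate(grid):
        cov = {"relatedness": float(rv), "same_siida": float(same_siida)}
        if gift is not None and "gift" in posterior.covariate_names:
            cov["gift"] = float(gift)
        if extra:
            cov.update(extra)
        pr = _marginal_probability(posterior, cov)
        med[k] = np.median(pr)
        lo[k], hi[k] = np.quantile(pr, [0.025, 0.975])
    return {"relatedness": grid, "median": med, "lo95": lo, "hi95": hi}


def odds_ratio(
    posterior: SRMPosterior,
    contrast: dict[str, float],
    reference: dict[str, float],
) -> dict:
    """Posterior odds ratio comparing two covariate settings.

    Per draw, OR = [p1/(1-p1)] / [p0/(1-p0)] with probabilities computed by
    marginalizing the random effects. Returns the median and 95% interval.
    """
    p1 = _marginal_probability(posterior, contrast)
    p0 = _marginal_probability(posterior, reference)
    eps = np.finfo(float).eps
    if np.any(p1 <= eps) or np.any(p1 >= 1 - eps) or np.any(p0 <= eps) or np.any(p0 >= 1 - eps):
        raise ValueError(
            "tie probability of 0 or 1 at machine precision; "
            "use a finite covariate contrast"
        )
    ors = (p1 / (1 - p1)) / (p0 / (1 - p0))
    s = _summ(ors)
    s["draws"] = ors
    return s


def simulate_from_posterior(
    posterior: SRMPosterior,
    data: SRMData,
    n_networks: int,
    seed: int,
    conditional: bool = False,
) -> list[np.ndarray]:
    """Posterior-predictive binary outcome matrices.

    For each of ``n_networks`` evenly spaced posterior draws, simulates a
    full outcome matrix from the model. By default new giver/receiver and
    dyadic effects are drawn from their fitted law (marginal prediction);
    ``conditional=True`` is not implemented because per-node effect draws
    are not retained.
    """
    if conditional:
        raise NotImplementedError("conditional posterior prediction is not retained")
    rng = np.random.default_rng(seed)
    X = data.design_tensor()
    n = data.n_nodes
    iu = np.triu_indices(n, k=1)
    il = (iu[1], iu[0])
    picks = np.linspace(0, posterior.n_draws - 1, n_networks).astype(int)
    sims = []
    for t in picks:
        beta = posterior.beta[t]
        Sigma = posterior.sigma_gr[t]
        rho = float(posterior.rho[t])
        gr = rng.multivariate_normal(np.zeros(2), Sigma + 1e-12 * np.eye(2), size=n)
        chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]) + 1e-12 * np.eye(2))
        pair = rng.standard_normal((len(iu[0]), 2)) @ chol.T
        d = np.zeros((n, n))
        d[iu] = pair[:, 0]
        d[il] = pair[:, 1]
        z = X @ beta + gr[:, 0][:, None] + gr[:, 1][None, :] + d
        ysim = (z > 0).astype(float)
        np.fill_diagonal(ysim, 0.0)
        sims.append(ysim)
    return sims
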