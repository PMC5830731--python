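# Methods

This note documents the models and algorithms implemented in `siidanet`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Kinship and relatedness

Kin paths are strings over `{M, F, B, Z, S, D}` (mother, father, brother,
sister, son, daughter) walked from ego to alter; the coefficient of
relatedness is r = 1/2^k for a path of k links, so the empty path (self)
gives 1, a sibling or parent 1/2, an uncle 1/4, a first cousin 1/8.
Siblings are treated as full siblings — the grammar has no half-sibling
token — and affinal (marriage) links are not representable, defaulting to
r = 0. When both directions of a dyad are reported and disagree, the larger
implied r is kept and a warning logged: conservative toward detecting kin
effects, and flagged for audit. Only the single reported path enters r;
multiple independent genealogical paths between a pair are not summed.

## Network statistics and nulls

All networks are directed and binary with no self-loops. Reciprocity is
edge-based (the share of directed edges whose reverse exists); a dyad-based
variant (share of connected dyads that are mutual) is exposed as
`dyad_reciprocity` for comparison. Assortment is the within-group edge
fraction, not Newman's assortativity coefficient — it reads directly as
"the share of nominations that stay inside the siida". Layer aggregation is
edge-set union. Null distributions fix the node set and edge count and draw
edges uniformly over ordered non-self pairs (directed Erdős–Rényi G(n, m));
degree sequences are deliberately not preserved. Under this null the
expected reciprocity is (m−1)/(n(n−1)−1) and the expected assortment is the
same-siida fraction among all ordered pairs; both identities are used as
closed-form oracles in the tests. Empirical quantiles use an add-one
convention so p-values stay in (0, 1].

## Binary probit social relations model

For ordered dyad (i, j) among licence owners:

    z_ij = x_d(i,j)' β_d + x_g(i)' β_g + g_i + r_j + d_ij,   y_ij = 1(z_ij > 0)

* (g_i, r_i) ~ N(0, Σ), 2×2 Σ free; cor(g, r) is generalized reciprocity.
* (d_ij, d_ji) ~ N(0, [[1, ρ], [ρ, 1]]); ρ is dyadic reciprocity. The unit
  marginal variance is the probit identification constraint.
* Dyadic covariates: relatedness, same-siida, and a directional gift
  indicator (1 iff i gave j a gift). Ego covariate: interviewed dummy.
  Rows of non-interviewed egos are kept as observed zeros — the dummy
  absorbs their structurally lower naming rate — rather than treated as
  missing data.

Priors (weakly informative, standard for additive network-effects models):
Normal(0, 5²) on every coefficient, inverse-Wishart(df 4, scale I₂) on Σ,
uniform(−1, 1) on ρ.

The Gibbs sampler alternates:

1. **Latent z**: truncated-normal draws; each triangle of the matrix is
   updated conditional on the other through ρ (conditional mean
   μ_ij + ρ(z_ji − μ_ji), variance 1 − ρ²). Inverse-CDF sampling with
   uniforms clipped to [1e−12, 1 − 1e−12]; a non-finite z aborts with a
   diagnostic.
2. **Coefficients**: the two directions of each dyad are decorrelated by
   the sum/difference transform (variances 2(1 ± ρ)), giving a conjugate
   normal GLS update; the Gram matrices of pair sums and differences are
   precomputed once.
3. **(g_i, r_i)**: an exact bivariate conjugate update per node, scanning
   nodes sequentially given the others (posterior precision
   Σ⁻¹ + (n−1)R⁻¹ with R the dyadic correlation matrix). This per-node scan
   is an exact Gibbs step with the same stationary distribution as a joint
   2n-dimensional update and is simpler to verify.
4. **Σ**: conjugate inverse-Wishart.
5. **ρ**: random-walk Metropolis on (−1, 1), step 1.2/√(#dyads) (floor
   0.02), acceptance rate reported.

With `random_effects=False` the sampler reduces exactly to Albert–Chib
Bayesian probit regression; the tests verify its posterior against a dense
grid-quadrature oracle (total variation < 0.05 per marginal).

Default chain length is 10,000 iterations, 2,000 burn-in, thinning 10, an
explicit seed required. Parameter-recovery and pipeline runs in the test
and acceptance suites use 600–6,000 iterations at 24–80 nodes, sizes chosen
so the whole suite stays desk-scale while split-chain R̂ < 1.1 holds.

Derived summaries, per draw: variance shares (σ²_g, σ²_r, 1)/(σ²_g + σ²_r + 1)
— the dyadic share uses the unit-fixed probit residual variance, so the
three shares sum to exactly 1; marginal tie probabilities
Φ(x'β / √(1 + σ²_g + σ²_r)), i.e. random effects integrated out (a
conditional version would require retaining per-node effect draws, which
the sampler does not store); odds ratios as probability contrasts
[p₁/(1−p₁)]/[p₀/(1−p₀)] at two covariate settings — note this is a
*probability-contrast* odds ratio, not an exponentiated coefficient, and
the two conventions differ numerically.

## Goodness of fit and ranking

The four relational statistics are computed on the grand-mean-centred
matrix with the diagonal excluded: sd of row means, sd of column means,
Pearson correlation of (e_ij, e_ji) over dyads, and triadic dependence
Σ e_ij·e_jk·e_ik over distinct triples normalized by the triple count times
sd(e)³ — the conventional standardized third moment for relational data
(the statistic is named in the literature without a fixed formula; this
choice is documented here as ours). Posterior-predictive draws simulate
whole networks from sampled (β, Σ, ρ) with *new* random effects
(marginal prediction). RMSE per statistic is √mean((s_draw − s_obs)²).
Classification thresholds the posterior mean of Φ(x'β + g + r) at 0.5 (the
threshold is a documented choice, not estimated). Ranking: mean rank across
the four RMSEs; ties break by higher F1, then fewer parameters.

## Gift-count models and stacking

Gifts received per licence owner (zeros included) are regressed on
cooperation in-degree with a log link: Poisson, NB2 negative binomial
(var = μ + φμ²; φ is the inverse dispersion), and intercept-only Poisson.
Priors: Normal(0, 2.5²) on intercept and slope, half-normal(1) on φ.
Posteriors are sampled with the emcee ensemble sampler (vectorized
log-density, walkers initialized near the penalized mode, fixed RNG state,
so fits are bit-reproducible). "Gifts received" counts gift events by
default; distinct givers is available via `count="givers"`.

Stacking maximizes Σ_i log Σ_m w_m p(y_i | y_−i, model m) over the weight
simplex. With only ~60 observations, leave-one-out densities are computed
by exact refitting (n refits per model, seeds derived deterministically
from the base seed and the held-out index) instead of importance-sampling
approximations. The optimizer uses a softmax reparametrization with
multiple deterministic starts plus a 1e−6-nat entropy bonus that resolves
the degenerate flat ridge between observationally identical models toward
equal weights without perturbing separated optima; it is verified against
a dense simplex grid search. Credible intervals are central 95% intervals
of μ(x) across draws; prediction intervals additionally simulate counts
from the fitted family at each draw (≈2,000 simulated counts per grid
point), so they always contain the credible interval.

## Synthetic community generator

The generator emulates a herding district of 60 licence owners in 4 siidas,
30 of them interviewed; only interviewed egos nominate partners, and all 30
play the gift game.

* **Roster**: siida sizes are one-guaranteed-member plus a
  Dirichlet-multinomial (mass 10 → mildly uneven groups); interviewed
  status is ⌈fraction·n⌉ individuals drawn at random; everyone holds a
  licence.
* **Genealogies**: families are one parent plus a full-sibling set of
  children, nested in siidas; disjoint pairs of families are linked by
  making their parents siblings (probability 0.7 within a siida, 0.15
  across), which produces parent/child, sibling, uncle/aunt and
  first-cousin paths — all mutually consistent, emitted in both directions,
  nothing beyond three links. Real genealogies are deeper and include
  affines; this generator covers exactly the path grammar the analysis
  consumes.
* **Tie layers**: three i.i.d. draws from the generative SRM above (a
  `layer_coupling` option mixes in a shared dyadic component when
  correlated layers are wanted). The calibrated defaults
  (intercept −6.6, β_relatedness 1.3, β_same-siida 1.75, β_interviewed 4.0,
  sd_g 0.72, sd_r 0.46, cor(g,r) 0.4, ρ 0.8) were chosen once so that
  generated communities reproduce the qualitative field pattern: per-layer
  assortment ≈ 0.82–0.84, per-layer reciprocity ≈ 0.26–0.33, a majority
  dyadic variance share with giver ≈ 30% and receiver ≈ 12%, and a strongly
  negative baseline that silences non-interviewed egos. Per-layer edge
  counts are free rather than fixed (how many alters a typical ego named
  per layer is not pinned down, so density is a parameter, not a constant).
* **Gift game**: each player chooses K = 1 + Poisson(1.5) recipients
  (≈2.5 gifts/player) by softmax weights 0.8·same-siida + 0.8·relatedness
  + 2.2·(cooperation tie, each direction counted — mutual partners weigh
  double, which concentrates gifts on fellow players and yields realistic
  gift-network reciprocity ≈ 0.25). The 35 l endowment is split equally to
  the cent of a litre (largest-remainder rounding; 35/4 = 8.75 l each), or
  by Dirichlet weights when `split="dirichlet"`. Ledger amounts are
  `Decimal`, so per-giver totals equal 35 exactly.

What passing tests on this generator do **not** show: robustness to
interviewer effects, missing or censored nominations, multiple kin paths,
seasonal siida recomposition, or degree heterogeneity beyond what the SRM's
random effects induce. The generator is a controlled testbed, not a
demographic simulation.

## Pipeline and determinism

`run_pipeline` executes simulate → kinship → network statistics + nulls →
SRM (additive and intercept-only) → GOF ranking → gift-count stacking →
gift accounting, writing CSV/JSON artifacts plus a manifest with SHA-256
hashes. Every stochastic stage consumes an explicit integer seed from the
configuration (a config without seeds is refused), and no artifact embeds
a timestamp, so the manifest hash is reproducible byte-for-byte. Monetary
arithmetic is `Decimal` end to end (35 l → 525 NOK, 8.75 l → 131.25 NOK,
18.12 l → 271.80 NOK exactly).

## Known limitations

* The SRM has no multiplicative latent factors, so higher-order structure
  (e.g. transitivity beyond what covariates and reciprocity induce) is not
  captured; triadic-dependence RMSE in the GOF table is where that misfit
  would show.
* The odds ratio is a probability contrast; comparisons with
  coefficient-exponentiation odds ratios from logit models are not
  apples-to-apples.
* Exact-LOO stacking refits n times per model; beyond a few hundred
  observations an approximate LOO would be needed.
* Variance-partition shares treat the unit probit residual as the dyadic
  variance; they are latent-scale shares, not observed-scale R².
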