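# siidanet

Cooperation-network analysis for small-scale communities, built around the
case of Saami reindeer herders whose labour is organized into *siidas*
(herding groups of kin and non-kin households). The package asks how
kinship, herding-group membership and gift-giving structure who names whom
as a cooperation partner — and whether a cooperative reputation brings
material rewards — and ships a synthetic-community generator so the whole
analysis can be exercised end-to-end with known ground truth.

It is a library first (import `siidanet`, see `examples/`), with a thin
`siidanet` CLI for running the pipeline from a shell.

## What it computes

**Kinship.** Genealogies are recorded as gendered kin-term paths from ego
to alter over the alphabet `M F B Z S D` (mother, father, brother, sister,
son, daughter): a brother is `"B"`, a father's brother's son `"FBS"`. The
coefficient of relatedness for a path of *k* links is *r* = 1/2^*k*.

**Network statistics.** Directed cooperation layers (advice, help, sharing
items) are aggregated by union into one binary cooperation network; a gift
network comes from an economic game. Edge reciprocity (share of directed
links whose reverse exists), siida assortment (share of links within a
herding group) and Jaccard similarity between layers are compared against
1000 random directed networks with the same numbers of nodes and edges.

**Social relations model.** Tie formation is modelled with a binary probit
SRM: for ordered dyad (i, j),

    z_ij = x_d(i,j)' β_d + x_g(i)' β_g + g_i + r_j + d_ij,    y_ij = 1(z_ij > 0)

with giver/receiver effects (g_i, r_i) bivariate normal (their correlation
is *generalized reciprocity*) and within-dyad errors (d_ij, d_ji)
correlated with coefficient ρ (*dyadic reciprocity*), unit marginal
variance. Dyadic covariates are relatedness, same-siida membership and a
directional gift indicator; an ego dummy marks who was interviewed. The
model is fitted by a data-augmentation Gibbs sampler written for this
package, and summarized through variance-partition components, reciprocity
correlations, predicted tie probabilities and odds ratios.

**Model assessment.** Posterior-predictive RMSE on four relational
statistics (sd of ego means, sd of alter means, dyadic correlation, triadic
dependence) plus F1/accuracy of thresholded tie probabilities; models are
ranked by mean RMSE rank with simplicity as the tie-break.

**Gift counts.** Gifts received per licence owner are regressed on
cooperation in-degree (a reputation proxy) with Bayesian Poisson,
negative-binomial and intercept-only models, combined by stacking of exact
leave-one-out predictive densities, with 95% credible and posterior
prediction intervals.

**Gift game accounting.** Every player gives away exactly 35 litres of
petrol (15 NOK/litre, so a 525 NOK endowment); ledgers are kept in exact
decimal arithmetic.

## Worked example

```python
from siidanet.synthetic import CommunityConfig, generate_community
from siidanet import gift_summary

ds = generate_community(CommunityConfig(random_seed=1))
print(len(ds.roster), len(ds.roster.interviewed_ids))   # 60 licence owners, 30 interviewed
print(gift_summary(ds.gift_ledger)["median_given_litres"])  # 8.75
```

Running `python examples/03_fit_srm.py` fits the SRM to that community and
prints (abridged):

```
variance shares: giver 30.5%, receiver 11.5%, dyadic 58.1%
generalized reciprocity 0.05, dyadic reciprocity 0.38
odds ratio for same-siida membership: 17.31 [11.49, 27.18]
```

Read: over half of tie variation lives in unique dyadic relationships (and
those relationships tend to be reciprocal, ρ ≈ 0.4); herders differ more as
givers than as receivers of nominations; and a shared siida multiplies the
odds of being named by an order of magnitude. `examples/05_gift_regression.py`
then shows the weak positive in-degree → gifts-received relationship and
its stacking-based model comparison. The other examples cover simulation,
descriptive network statistics with nulls, and goodness-of-fit ranking.

## Layout

- `src/siidanet/` — `kinship`, `networks`, `srm`, `evaluation`, `gifts`,
  `synthetic`, `io`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, algorithms, calibration and limitations
- `tests/` — unit, property and acceptance suites
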