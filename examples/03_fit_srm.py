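"""Fit the probit social relations model to the cooperation network.

The SRM decomposes directed tie variation into giver, receiver and
relationship components while estimating effects of relatedness, shared
siida membership and gift giving on the probability of naming someone as a
cooperation partner.
"""

import numpy as np

from siidanet import (
    MCMCSettings,
    build_srm_data,
    fit_srm,
    gift_network,
    odds_ratio,
    predict_tie_probability,
    reciprocity_correlations,
    variance_partition,
)
from siidanet.synthetic import CommunityConfig, generate_community

ds = generate_community(CommunityConfig(random_seed=1))
data = build_srm_data(
    ds.cooperation, ds.roster, ds.relatedness,
    gift_network=gift_network(ds.gift_ledger, ds.roster.ids),
)
post = fit_srm(data, mcmc=MCMCSettings(iterations=4000, burn_in=1000, thin=5, seed=3))

print("fixed effects (posterior mean [95% CI]):")
for name, s in post.summary().items():
    if name.startswith("beta_"):
        print(f"  {name:<22} {s['mean']:6.2f}  [{s['ci95'][0]:.2f}, {s['ci95'][1]:.2f}]")

vp = variance_partition(post)
print("\nvariance shares: "
      f"giver {100 * vp['giver']['mean']:.1f}%, "
      f"receiver {100 * vp['receiver']['mean']:.1f}%, "
      f"dyadic {100 * vp['dyadic']['mean']:.1f}%")

rc = reciprocity_correlations(post)
print(f"generalized reciprocity {rc['generalized']['mean']:.2f}, "
      f"dyadic reciprocity {rc['dyadic']['mean']:.2f}")

res = odds_ratio(
    post,
    contrast={"relatedness": 0.0, "same_siida": 1.0, "gift": 0.0, "interviewed": 1.0},
    reference={"relatedness": 0.0, "same_siida": 0.0, "gift": 0.0, "interviewed": 1.0},
)
print(f"odds ratio for same-siida membership: {res['median']:.2f} "
      f"[{res['ci95'][0]:.2f}, {res['ci95'][1]:.2f}]")

curve = predict_tie_probability(post, np.linspace(0, 0.5, 5), same_siida=1,
                                gift=0, extra={"interviewed": 1.0})
print("\nP(tie) within a siida as relatedness rises 0 -> 0.5:")
for r, m in zip(curve["relatedness"], curve["median"]):
    print(f"  r = {r:.3f}: {m:.3f}")
# Closer kin and fellow siida members are markedly more likely to be named;
# most remaining variation sits in unique dyadic relationships.
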