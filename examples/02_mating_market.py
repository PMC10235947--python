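"""The generalized polygyny-threshold model on a single mating market.

Draws rival (R) and nonrival (G) male resources at target Gini levels,
finds the bilaterally Nash ideal-free matching and the socially imposed
monogamy matching on the same market, and compares polygyny frequency
and sex-specific reproductive skew between the two rules.
"""

from dataclasses import replace

import numpy as np

from repskew import (
    MatingMarketConfig,
    match_ideal_free,
    match_imposed_monogamy,
    polygyny_metrics,
    sample_resources,
    simulate_reproduction,
)
from repskew.skew import compute_M_values

# high rival inequality (Gini 0.55), modest rival importance (mu 0.3):
# the regime where free female choice should produce substantial polygyny
cfg = MatingMarketConfig(n_males=300, gini_R=0.55, gini_G=0.12, mu=0.3, seed=7)
rng = np.random.default_rng(cfg.seed)
R = sample_resources(cfg.n_males, cfg.gini_R, rng)
G = sample_resources(cfg.n_males, cfg.gini_G, rng)

for rule in ("ideal_free", "imposed_monogamy"):
    cfg_rule = replace(cfg, mating_rule=rule)
    if rule == "ideal_free":
        state = match_ideal_free(cfg_rule, R, G, rng)
    else:
        state = match_imposed_monogamy(cfg_rule, R, G, rng)
    pct_men, pct_women = polygyny_metrics(state)
    recs = simulate_reproduction(state, cfg_rule, rng)
    M = {sex: compute_M_values(recs.loc[recs["sex"] == sex, "rs"].to_numpy(),
                               None, method="analytic")
         for sex in ("male", "female")}
    print(f"{rule:17s}: {pct_men:5.1f}% polygynous men, "
          f"{pct_women:5.1f}% women with cowives | "
          f"M_m={M['male']:+.3f}  M_f={M['female']:+.3f}  "
          f"diff={M['male'] - M['female']:+.3f}")
# under free choice, unequal rival resources concentrate wives and
# offspring on rich males (high M_m, low M_f); imposing monogamy on the
# same resource distribution flattens the sex difference.
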