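"""Multi-regime Ornstein-Uhlenbeck model comparison.

Relative brain size is simulated under a two-optimum OUM process (tropical
vs. temperate regimes); the five candidate families are fitted and ranked
by AICc, and the optima are recovered.
"""

import numpy as np

from phyloenv.ou import compare_models, fit_ou
from phyloenv.synthetic import (
    er_rate_matrix, scale_tree, simulate_regime_history, simulate_trait,
)
from phyloenv.trees import simulate_yule_tree

tree = scale_tree(simulate_yule_tree(400, seed=11), 1.0)
history = simulate_regime_history(tree, er_rate_matrix(2, 0.5), 0, seed=12,
                                  state_labels=["tropical", "temperate"])
trait = simulate_trait(history, theta=[0.0, 0.3], alpha=2.0, sigma2=0.05,
                       root_value=0.0, seed=13)

fits = [fit_ou(history, trait, fam) for fam in ("BM1", "BMS", "OU1", "OUM", "OUMV")]
tab = compare_models(fits)
print(tab[["family", "loglik", "k", "aicc", "delta_aicc", "weight"]]
      .round(3).to_string(index=False))
oum = next(f for f in fits if f.family == "OUM")
print("\nOUM optima:", oum.theta.round(3).to_dict(), f"alpha = {oum.alpha:.2f}")
print(
    "\nThe multi-optimum families carry essentially all the Akaike weight and"
    "\nthe estimated optima recover the generating contrast (0 vs 0.3): the"
    "\ntrait is pulled toward a larger value in the temperate regime."
)
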