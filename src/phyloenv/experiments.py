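"""Replicated parameter-recovery experiments.

These drive the package end to end under known ground truth: simulate a
study at the stated conditions, run the estimator, and record what came
back.  They back both the recovery test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trees import simulate_yule_tree
from .synthetic import (
    er_rate_matrix, scale_tree, simulate_allometric_dataset,
    simulate_regime_history, simulate_trait,
)
from .comparative import pgls_fit
from .ou import fit_ou, compare_models
from .regimes import fit_mk, stochastic_map, summarize_transitions

__all__ = [
    "pgls_recovery",
    "ou_recovery",
    "transition_coverage",
]


def pgls_recovery(
    n_reps: int = 100,
    n_tips: int = 835,
    slope: float = 0.59,
    lambda_resid: float = 0.9,
    sigma2_resid: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate allometric datasets and refit PGLS with ML lambda.

    Each replicate draws a fresh Yule tree (depth normalised to 1), log body
    size under Brownian motion, and log brain size with the given slope and
    lambda-structured residuals.  Returns one row per replicate with the
    slope and lambda estimates, the slope SE, and whether the true slope
    fell inside the 95% Wald interval.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        tree = scale_tree(simulate_yule_tree(n_tips, rng=rng), 1.0)
        df = simulate_allometric_dataset(
            tree, beta1=slope, lambda_resid=lambda_resid,
            sigma2_resid=sigma2_resid, rng=rng,
        )
        fit = pgls_fit(df["log_brain"], df[["log_body"]], tree)
        est, se = fit.params.loc["log_body", ["estimate", "se"]]
        rows.append(
            {
                "rep": rep,
                "slope_hat": est,
                "slope_se": se,
                "lambda_hat": fit.lambda_hat,
                "covered": abs(est - slope) <= 1.959963984540054 * se,
            }
        )
    return pd.DataFrame(rows)


def ou_recovery(
    n_reps: int = 100,
    n_tips: int = 500,
    theta: tuple[float, float] = (0.0, 0.3),
    alpha: float = 2.0,
    sigma2: float = 0.05,
    regime_rate: float = 0.5,
    families: tuple[str, ...] = ("BM1", "BMS", "OU1", "OUM", "OUMV"),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate two-regime OUM data on the true history and rank families.

    Returns one row per replicate: AICc-best family plus the OUM optimum
    estimates for both regimes.
    """
    theta = np.asarray(theta, dtype=float)
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        tree = scale_tree(simulate_yule_tree(n_tips, rng=rng), 1.0)
        hist = simulate_regime_history(tree, er_rate_matrix(2, regime_rate), 0, rng=rng)
        x = simulate_trait(hist, theta, alpha, sigma2, root_value=theta[0], rng=rng)
        fits = [fit_ou(hist, x, fam) for fam in families]
        tab = compare_models(fits)
        oum = next(f for f in fits if f.family == "OUM")
        rows.append(
            {
                "rep": rep,
                "best_family": tab["family"].iloc[0],
                "theta0_hat": oum.theta.iloc[0],
                "theta1_hat": oum.theta.iloc[1],
                "alpha_hat": oum.alpha,
            }
        )
    return pd.DataFrame(rows)


def transition_coverage(
    n_tips: int = 200,
    n_states: int = 5,
    regime_rate: float = 0.45,
    n_maps: int = 1000,
    seed: int = 0,
) -> dict:
    """Coverage of stochastic-map transition intervals.

    Simulates one regime history, fits an Mk model to its tips, draws
    ``n_maps`` conditional maps, and reports the fraction of ordered state
    pairs whose realized true change count lies inside the across-map
    2.5-97.5% interval.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_hist, s_maps = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3)]
    tree = scale_tree(simulate_yule_tree(n_tips, seed=s_tree), 1.0)
    Q = er_rate_matrix(n_states, regime_rate)
    hist = simulate_regime_history(tree, Q, 0, seed=s_hist)
    true_counts = hist.count_transitions()
    tips = hist.tip_states()
    mk = fit_mk(tree, tips, state_labels=hist.state_labels)
    maps = stochastic_map(tree, tips, mk.Q, n_maps, seed=s_maps,
                          state_labels=mk.state_labels)
    summ = summarize_transitions(maps)
    off = ~np.eye(n_states, dtype=bool)
    inside = (summ.q025 <= true_counts) & (true_counts <= summ.q975)
    return {
        "bracket_fraction": float(inside[off].mean()),
        "true_total_changes": int(true_counts.sum()),
        "median_total_changes": float(np.median([m.count_transitions().sum() for m in maps])),
        "q_hat": float(mk.Q[0, 1]),
        "n_maps": n_maps,
    }
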