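"""Regime classification, Mk likelihoods, and stochastic character maps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from phyloenv.regimes import (
    RegimeThresholds, classify_regimes, ensemble_maps, expected_transition_counts,
    fit_mk, mk_loglik, stochastic_map, summarize_transitions,
    stationary_distribution, _sample_branch_path,
)
from phyloenv.synthetic import er_rate_matrix, scale_tree, simulate_regime_history
from phyloenv.trees import TreeEnsemble, read_newick, simulate_yule_tree


def enumeration_loglik(tree, tip_states, Q, labels, prior):
    """Brute-force sum over all internal-node state assignments."""
    k = Q.shape[0]
    P = [expm(Q * tree.branch_lengths[v]) for v in range(tree.n_nodes - 1)]
    obs = [labels.index(tip_states[lb]) for lb in tree.tip_labels]
    n_internal = tree.n_nodes - tree.n_tips
    total = 0.0
    for assign in itertools.product(range(k), repeat=n_internal):
        states = list(obs) + list(assign)
        pr = prior[states[tree.root]]
        for v in range(tree.n_nodes - 1):
            pr *= P[v][states[tree.parent[v]], states[v]]
        total += pr
    return np.log(total)


class TestClassification:
    def _traits(self, rows):
        return pd.DataFrame(
            rows, columns=["breeding_latitude", "migratory_status", "migratory_distance_km"],
            index=[f"sp{i}" for i in range(len(rows))],
        )

    def test_bands_and_boundaries(self):
        tr = self._traits([
            (10.0, "resident", 0.0),
            (-30.0, "resident", 0.0),
            (23.5, "resident", 0.0),   # boundary -> poleward bin
            (50.0, "resident", 0.0),   # upper medium boundary stays medium
            (61.0, "resident", 0.0),
            (40.0, "migrant", 1999.9),
            (40.0, "migrant", 2000.0),  # >= rule
        ])
        out = classify_regimes(tr)
        assert list(out["regime"]) == [
            "resident_low", "resident_medium", "resident_medium",
            "resident_medium", "resident_high", "migrant_short", "migrant_long",
        ]
        assert out.attrs["thresholds"].distance_split_km == 2000.0

    def test_custom_thresholds_echoed(self):
        tr = self._traits([(30.0, "resident", 0.0)])
        th = RegimeThresholds(lat_low=35.0)
        out = classify_regimes(tr, th)
        assert out["regime"].iloc[0] == "resident_low"
        assert out.attrs["thresholds"] is th

    def test_missing_fields_raise(self):
        with pytest.raises(ValueError, match="missing required"):
            classify_regimes(pd.DataFrame({"breeding_latitude": [1.0]}))
        tr = self._traits([(40.0, "migrant", np.nan)])
        with pytest.raises(ValueError, match="migrant"):
            classify_regimes(tr)


class TestMkLikelihood:
    @pytest.mark.parametrize("seed", range(6))
    def test_pruning_equals_enumeration_small_trees(self, seed):
        """Pruning likelihood = exhaustive enumeration on <= 6-tip trees."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        tree = simulate_yule_tree(n, seed=seed + 900)
        k = int(rng.integers(2, 4))
        labels = [f"s{i}" for i in range(k)]
        # random ARD generator
        Q = rng.uniform(0.2, 1.2, size=(k, k))
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        tip_states = pd.Series(
            [labels[i] for i in rng.integers(0, k, n)], index=tree.tip_labels
        )
        if tip_states.nunique() < 2:
            tip_states.iloc[0] = labels[0] if tip_states.iloc[1] != labels[0] else labels[1]
        prior = stationary_distribution(Q)
        got = mk_loglik(tree, tip_states, Q, labels, root_prior=prior)
        want = enumeration_loglik(tree, tip_states, Q, labels, prior)
        assert got == pytest.approx(want, abs=1e-10)

    def test_all_tips_identical_drives_rate_to_zero(self, yule50):
        tips = pd.Series(["a"] * 50, index=yule50.tip_labels)
        fit = fit_mk(yule50, tips, state_labels=["a", "b"])
        assert fit.Q[0, 1] < 1e-6
        # likelihood approaches the root-prior mass of the observed state
        assert fit.loglik >= np.log(0.5) - 1e-6

    def test_rate_recovery(self):
        """Median rate estimate within 20% of truth on 300-tip trees."""
        q_true, estimates = 0.5, []
        for seed in range(12):
            tree = scale_tree(simulate_yule_tree(300, seed=seed + 70), 1.0)
            h = simulate_regime_history(tree, er_rate_matrix(2, q_true), 0, seed=seed)
            fit = fit_mk(tree, h.tip_states(), state_labels=h.state_labels)
            estimates.append(fit.Q[0, 1])
        assert abs(np.median(estimates) - q_true) < 0.2 * q_true


class TestPathSampling:
    def test_two_state_jump_count_distribution(self):
        """For a 2-state equal-rates chain the number of jumps is Poisson(qt)
        and the end state flips with parity; conditioning on the endpoints
        truncates the Poisson to even/odd counts — the closed-form oracle."""
        q, b, reps = 1.2, 1.0, 20_000
        Q = er_rate_matrix(2, q)
        P_b = expm(Q * b)
        rng = np.random.default_rng(3)
        mu = q * b
        for s1, parity in ((0, 0), (1, 1)):
            counts = np.array([
                len(_sample_branch_path(0, s1, b, Q, P_b, rng)) - 1
                for _ in range(reps)
            ])
            assert np.all(counts % 2 == parity)
            # P(N = parity | parity class) from the truncated Poisson
            norm = np.cosh(mu) if parity == 0 else np.sinh(mu)
            p0 = (mu**parity / math.factorial(parity)) / norm
            phat = np.mean(counts == parity)
            se = np.sqrt(p0 * (1 - p0) / reps)
            assert abs(phat - p0) < 3.5 * se

    def test_uniformization_fallback_matches_rejection(self):
        """Endpoint-conditioned sampling must give the same jump-count law
        whether it comes from rejection or the uniformization bridge."""
        from phyloenv.regimes import _uniformized_path
        q, b, reps = 0.8, 1.5, 20_000
        Q = er_rate_matrix(2, q)
        P_b = expm(Q * b)
        rng = np.random.default_rng(4)
        counts = np.array([len(_uniformized_path(0, 1, b, Q, P_b, rng)) for _ in range(reps)])
        assert np.all(counts % 2 == 1)
        mu = q * b
        p1 = mu / np.sinh(mu)
        phat = np.mean(counts == 1)
        assert abs(phat - p1) < 3.5 * np.sqrt(p1 * (1 - p1) / reps)


class TestStochasticMap:
    def test_near_zero_rate_uniform_tips_no_transitions(self, yule50):
        tips = pd.Series(["a"] * 50, index=yule50.tip_labels)
        Q = er_rate_matrix(2, 1e-9)
        maps = stochastic_map(yule50, tips, Q, 5, seed=0, state_labels=["a", "b"])
        assert all(m.count_transitions().sum() == 0 for m in maps)

    def test_deterministic_under_seed(self, yule50):
        h = simulate_regime_history(yule50, er_rate_matrix(3, 0.4), 0, seed=1)
        tips = h.tip_states()
        Q = er_rate_matrix(3, 0.4)
        a = stochastic_map(yule50, tips, Q, 3, seed=5, state_labels=h.state_labels)
        b = stochastic_map(yule50, tips, Q, 3, seed=5, state_labels=h.state_labels)
        for m1, m2 in zip(a, b):
            assert m1.to_frame().equals(m2.to_frame())

    def test_maps_preserve_tip_states_and_validate(self, yule50):
        h = simulate_regime_history(yule50, er_rate_matrix(3, 0.5), 0, seed=2)
        tips = h.tip_states()
        maps = stochastic_map(yule50, tips, er_rate_matrix(3, 0.5), 4, seed=6,
                              state_labels=h.state_labels)
        for m in maps:
            m.validate()
            assert m.tip_states().equals(tips)

    def test_change_count_monotone_in_rate(self, yule50):
        h = simulate_regime_history(yule50, er_rate_matrix(2, 0.3), 0, seed=3)
        tips = h.tip_states()
        means = []
        for q in (0.1, 0.5, 1.0):
            maps = stochastic_map(yule50, tips, er_rate_matrix(2, q), 40, seed=7,
                                  state_labels=h.state_labels)
            means.append(np.mean([m.count_transitions().sum() for m in maps]))
        assert means[0] < means[1] < means[2]


class TestSummaries:
    def test_single_map_single_change(self):
        tree = read_newick("(A:1,B:1);")
        h = simulate_regime_history(tree, np.zeros((2, 2)), 0, seed=0,
                                    state_labels=["A_state", "B_state"])
        # paint one change on the branch to tip B by hand
        h.segments[1] = np.array([[0, 0.0, 0.4], [1, 0.4, 1.0]])
        s = summarize_transitions([h])
        assert s.median[0, 1] == 1 and s.q025[0, 1] == 1 and s.q975[0, 1] == 1
        assert s.median[1, 0] == 0

    def test_invariant_to_map_order_and_quantile_oracle(self, yule50):
        h = simulate_regime_history(yule50, er_rate_matrix(2, 0.5), 0, seed=4)
        maps = stochastic_map(yule50, h.tip_states(), er_rate_matrix(2, 0.5), 50,
                              seed=8, state_labels=h.state_labels)
        s1 = summarize_transitions(maps)
        s2 = summarize_transitions(maps[::-1])
        assert np.array_equal(s1.median, s2.median)
        counts01 = sorted(m.count_transitions()[0, 1] for m in maps)
        assert s1.q025[0, 1] == pytest.approx(np.percentile(counts01, 2.5))
        assert s1.q975[0, 1] == pytest.approx(np.percentile(counts01, 97.5))


class TestEnsemble:
    def test_provenance_bookkeeping(self):
        t1 = scale_tree(simulate_yule_tree(20, seed=1), 1.0)
        t2 = scale_tree(simulate_yule_tree(20, seed=2), 1.0)
        h = simulate_regime_history(t1, er_rate_matrix(2, 0.5), 0, seed=0)
        tips = h.tip_states()
        maps, fits, failures = ensemble_maps(
            TreeEnsemble([t1, t2]), tips, 3, seed=9, state_labels=h.state_labels
        )
        assert len(maps) == 6 and not failures
        prov = {(m.provenance["tree_index"], m.provenance["map_index"]) for m in maps}
        assert len(prov) == 6

    def test_identical_trees_identical_rates(self, yule50):
        h = simulate_regime_history(yule50, er_rate_matrix(2, 0.5), 0, seed=5)
        maps, fits, _ = ensemble_maps(
            TreeEnsemble([yule50, yule50.copy()]), h.tip_states(), 1, seed=10,
            state_labels=h.state_labels,
        )
        assert np.allclose(fits[0].Q, fits[1].Q, atol=1e-8)


def test_expected_transition_counts_zero_rate(yule50):
    counts = expected_transition_counts(yule50, np.zeros((3, 3)), root_prior=0)
    assert np.allclose(counts, 0.0)


def test_expected_transition_counts_match_simulation(yule50):
    Q = er_rate_matrix(2, 0.4)
    expected = expected_transition_counts(yule50, Q, root_prior=0)
    rng_counts = []
    rng = np.random.default_rng(11)
    for _ in range(300):
        h = simulate_regime_history(yule50, Q, 0, rng=rng)
        rng_counts.append(h.count_transitions())
    mean = np.mean(rng_counts, axis=0)
    se = np.std(rng_counts, axis=0, ddof=1) / np.sqrt(300)
    assert np.all(np.abs(mean - expected) < 3.5 * se + 1e-9)
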