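"""Selective-regime classification, Mk model fitting, and stochastic
character mapping.

Species are classified into five selective regimes (residency crossed with
latitude band, migration split by distance), a continuous-time Markov (Mk)
model is fitted to the tip regimes by maximum likelihood with the pruning
algorithm, and full character histories — including changes along branches,
not only at nodes — are sampled conditional on the tips by
forward-filtering/backward-sampling of node states followed by
endpoint-conditioned path sampling (rejection with a uniformization
fallback, so stiff branches terminate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import expm

from .trees import Phylogeny, TreeEnsemble
from .histories import RegimeHistory, summarize_transitions, TransitionSummary

__all__ = [
    "RegimeThresholds",
    "classify_regimes",
    "MkFit",
    "fit_mk",
    "stochastic_map",
    "ensemble_maps",
    "summarize_transitions",
    "expected_transition_counts",
    "REGIME_LABELS",
]

REGIME_LABELS = [
    "resident_low",
    "resident_medium",
    "resident_high",
    "migrant_short",
    "migrant_long",
]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class RegimeThresholds:
    """Latitude-band and migration-distance cutoffs.

    Defaults: tropics end at |lat| 23.5 deg, the high-latitude band starts
    above 50 deg, and migrants travelling >= 2,000 km are long-distance.
    These are conventions, echoed in the classification output so a run is
    auditable.
    """

    lat_low: float = 23.5
    lat_high: float = 50.0
    distance_split_km: float = 2000.0


def classify_regimes(
    traits: pd.DataFrame, thresholds: RegimeThresholds | None = None
) -> pd.DataFrame:
    """Assign each species one of the five selective regimes.

    Requires columns ``breeding_latitude``, ``migratory_status`` (values
    "resident"/"migrant") and, for migrants, ``migratory_distance_km``.
    Residents are binned by |breeding latitude|; the band boundaries belong
    to the poleward bin and the distance boundary to migrant_long (>= rule).
    Returns a frame with a ``regime`` column plus the thresholds used.
    """
    th = thresholds or RegimeThresholds()
    for col in ("breeding_latitude", "migratory_status"):
        if col not in traits.columns:
            raise ValueError(f"missing required column {col!r}")
    regimes = []
    for sp, row in traits.iterrows():
        status = row["migratory_status"]
        if status == "migrant":
            d = row.get("migratory_distance_km")
            if d is None or np.isnan(d):
                raise ValueError(f"{sp}: migrant without migratory_distance_km")
            regimes.append("migrant_long" if d >= th.distance_split_km else "migrant_short")
        elif status == "resident":
            alat = abs(row["breeding_latitude"])
            if np.isnan(alat):
                raise ValueError(f"{sp}: missing breeding latitude")
            if alat < th.lat_low:
                regimes.append("resident_low")
            elif alat <= th.lat_high:
                regimes.append("resident_medium")
            else:
                regimes.append("resident_high")
        else:
            raise ValueError(f"{sp}: migratory_status must be 'resident' or 'migrant'")
    out = traits.copy()
    out["regime"] = regimes
    out.attrs["thresholds"] = th
    return out


# ---------------------------------------------------------------------------
# Mk likelihood (pruning) and ML fitting
# ---------------------------------------------------------------------------

def _build_Q(params: np.ndarray, k: int, model: str) -> np.ndarray:
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = params[0]
    elif model == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = params
        Q.T[iu] = params
    elif model == "ARD":
        mask = ~np.eye(k, dtype=bool)
        Q[mask] = params
    else:
        raise ValueError("model must be ER, SYM or ARD")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _n_params(k: int, model: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[model]


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of Q normalised to a probability vector."""
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _tip_state_ids(tip_states: pd.Series, tree: Phylogeny, labels: list[str]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(labels)}
    try:
        return np.array([idx[tip_states[lb]] for lb in tree.tip_labels])
    except KeyError as exc:
        raise ValueError(f"tip state missing or unknown: {exc}") from exc


def _pruning(
    tree: Phylogeny, states: np.ndarray, Q: np.ndarray, root_prior: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Felsenstein pruning. Returns (loglik, partials L[v, s], branch P[v])."""
    k = Q.shape[0]
    P = np.empty((tree.n_nodes, k, k))
    for v in range(tree.n_nodes - 1):  # root has no branch
        P[v] = expm(Q * tree.branch_lengths[v])
    L = np.zeros((tree.n_nodes, k))
    scale = 0.0
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            L[v, states[v]] = 1.0
            continue
        vec = np.ones(k)
        for c in kids:
            vec = vec * (P[c] @ L[c])
        m = vec.max()
        if m <= 0:
            return -np.inf, L, P
        L[v] = vec / m
        scale += np.log(m)
    lik = float(root_prior @ L[tree.root])
    if lik <= 0:
        return -np.inf, L, P
    return float(np.log(lik) + scale), L, P


@dataclass
class MkFit:
    Q: np.ndarray
    state_labels: list[str]
    loglik: float
    model: str
    converged: bool
    root_prior: np.ndarray


def mk_loglik(
    tree: Phylogeny,
    tip_states: pd.Series,
    Q: np.ndarray,
    state_labels: list[str],
    root_prior: np.ndarray | str = "stationary",
) -> float:
    """Mk pruning log-likelihood of observed tip states under generator Q."""
    states = _tip_state_ids(tip_states, tree, state_labels)
    prior = _resolve_prior(root_prior, Q)
    return _pruning(tree, states, Q, prior)[0]


def _resolve_prior(root_prior, Q: np.ndarray) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "stationary":
            return stationary_distribution(Q)
        if root_prior == "flat":
            return np.full(Q.shape[0], 1.0 / Q.shape[0])
        raise ValueError("root_prior must be 'stationary', 'flat' or a vector")
    return np.asarray(root_prior, dtype=float)


def fit_mk(
    tree: Phylogeny,
    tip_states: pd.Series,
    model: str = "ER",
    state_labels: list[str] | None = None,
    root_prior: str = "stationary",
) -> MkFit:
    """Maximum-likelihood Mk rates for the observed tip regimes.

    The rate scale is searched in log space from several deterministic
    starting points spanning slow to fast evolution relative to the total
    tree length.  The root prior defaults to the stationary distribution of
    the fitted generator.
    """
    if state_labels is None:
        state_labels = sorted(pd.unique(tip_states))
    k = len(state_labels)
    if k < 2:
        raise ValueError("need at least 2 observed states")
    states = _tip_state_ids(tip_states, tree, state_labels)
    total_len = tree.total_branch_length()
    npar = _n_params(k, model)

    def nll(log_rates: np.ndarray) -> float:
        Q = _build_Q(np.exp(log_rates), k, model)
        prior = _resolve_prior(root_prior, Q)
        ll = _pruning(tree, states, Q, prior)[0]
        return -ll if np.isfinite(ll) else 1e12

    # starts: ~0.3, 3, 30 expected changes over the tree
    base = np.log(np.array([0.3, 3.0, 30.0]) / (total_len * (k - 1)))
    best = None
    converged = False
    lo, hi = np.log(1e-9 / total_len), np.log(1e4 / total_len)
    for b in base:
        res = optimize.minimize(
            nll, np.full(npar, b), method="L-BFGS-B",
            bounds=[(lo, hi)] * npar,
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        converged = converged or bool(res.success)
    Q = _build_Q(np.exp(best.x), k, model)
    return MkFit(
        Q=Q,
        state_labels=list(state_labels),
        loglik=-float(best.fun),
        model=model,
        converged=converged,
        root_prior=_resolve_prior(root_prior, Q),
    )


# ---------------------------------------------------------------------------
# endpoint-conditioned path sampling
# ---------------------------------------------------------------------------

def _forward_path(s0: int, b: float, Q: np.ndarray, rng) -> tuple[list, int]:
    leave = -np.diag(Q)
    t, s = 0.0, s0
    events = []
    while True:
        rate = leave[s]
        if rate <= 0:
            break
        dt = rng.exponential(1.0 / rate)
        if t + dt >= b:
            break
        t += dt
        probs = Q[s].clip(min=0.0)
        probs[s] = 0.0
        probs = probs / probs.sum()
        s = int(rng.choice(len(probs), p=probs))
        events.append((t, s))
    return events, s


def _uniformized_path(
    s0: int, s1: int, b: float, Q: np.ndarray, P_b: np.ndarray, rng,
    max_jumps: int = 200,
) -> list:
    """Sample jump events conditional on endpoints via uniformization."""
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        if s0 != s1:
            raise ValueError("impossible endpoint combination under Q")
        return []
    k = Q.shape[0]
    R = np.eye(k) + Q / mu
    # powers of R
    Rpow = [np.eye(k), R]
    target = P_b[s0, s1]
    if target <= 0:
        raise ValueError("impossible endpoint combination under Q")
    # sample number of uniformized jumps
    u = rng.uniform()
    cdf = 0.0
    logpois = -mu * b
    m = 0
    while True:
        term = np.exp(logpois) * Rpow[m][s0, s1] / target
        cdf += term
        if u <= cdf or m >= max_jumps:
            break
        m += 1
        logpois += np.log(mu * b) - np.log(m)
        while len(Rpow) <= m:
            Rpow.append(Rpow[-1] @ R)
    n_jumps = m
    while len(Rpow) <= n_jumps:
        Rpow.append(Rpow[-1] @ R)
    # state sequence of the uniformized chain, bridged to s1
    seq = [s0]
    for j in range(1, n_jumps):
        prev = seq[-1]
        w = R[prev, :] * Rpow[n_jumps - j][:, s1]
        w = np.clip(w, 0.0, None)
        w_sum = w.sum()
        if w_sum <= 0:
            raise ValueError("uniformization bridge failure")
        seq.append(int(rng.choice(k, p=w / w_sum)))
    if n_jumps >= 1:
        seq.append(s1)
    times = np.sort(rng.uniform(0.0, b, size=n_jumps))
    events = []
    cur = s0
    for t, s in zip(times, seq[1:]):
        if s != cur:  # drop virtual (self) jumps
            events.append((float(t), int(s)))
            cur = s
    return events


def _sample_branch_path(
    s0: int, s1: int, b: float, Q: np.ndarray, P_b: np.ndarray, rng,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Segments (state, t0, t1) for one branch conditioned on endpoints."""
    if b == 0.0:
        if s0 != s1:
            raise ValueError("state change on zero-length branch")
        return np.array([[s0, 0.0, 0.0]])
    events = None
    for _ in range(max_tries):
        ev, end = _forward_path(s0, b, Q, rng)
        if end == s1:
            events = ev
            break
    if events is None:
        events = _uniformized_path(s0, s1, b, Q, P_b, rng)
    segs = []
    cur, t_prev = s0, 0.0
    for t, s in events:
        segs.append((cur, t_prev, t))
        cur, t_prev = s, t
    segs.append((cur, t_prev, b))
    return np.asarray(segs, dtype=float)


def stochastic_map(
    tree: Phylogeny,
    tip_states: pd.Series,
    Q: np.ndarray,
    n_maps: int,
    seed: int | None = None,
    state_labels: list[str] | None = None,
    root_prior: str | np.ndarray = "stationary",
    rng: np.random.Generator | None = None,
) -> list[RegimeHistory]:
    """Sample ``n_maps`` full regime histories conditional on the tips.

    Node states are drawn from their exact conditional distributions (root
    from its posterior, then preorder given the sampled parent); branch
    paths are endpoint-conditioned CTMC bridges.  Tip states are preserved
    by construction and asserted.
    """
    if state_labels is None:
        state_labels = sorted(pd.unique(tip_states))
    k = len(state_labels)
    states = _tip_state_ids(tip_states, tree, state_labels)
    prior = _resolve_prior(root_prior, Q)
    ll, L, P = _pruning(tree, states, Q, prior)
    if not np.isfinite(ll):
        raise ValueError("tip states have zero likelihood under Q")
    if rng is None:
        rng = np.random.default_rng(seed)
    maps: list[RegimeHistory] = []
    for imap in range(n_maps):
        node_state = np.full(tree.n_nodes, -1, dtype=int)
        w = prior * L[tree.root]
        node_state[tree.root] = int(rng.choice(k, p=w / w.sum()))
        segments: list[np.ndarray] = [None] * tree.n_nodes
        segments[tree.root] = np.array([[node_state[tree.root], 0.0, 0.0]])
        for v in tree.preorder:
            if v == tree.root:
                continue
            sp = node_state[tree.parent[v]]
            w = P[v][sp, :] * L[v]
            node_state[v] = int(rng.choice(k, p=w / w.sum()))
            segments[v] = _sample_branch_path(
                sp, node_state[v], float(tree.branch_lengths[v]), Q, P[v], rng
            )
        assert np.array_equal(node_state[: tree.n_tips], states), "tip states not preserved"
        maps.append(
            RegimeHistory(
                tree, list(state_labels), segments,
                provenance={"map_index": imap, "seed": seed},
            )
        )
    return maps


def ensemble_maps(
    trees: TreeEnsemble,
    tip_states: pd.Series,
    n_maps_per_tree: int,
    seed: int = 0,
    model: str = "ER",
    state_labels: list[str] | None = None,
    root_prior: str = "stationary",
) -> tuple[list[RegimeHistory], list[MkFit], list[tuple[int, str]]]:
    """Fit an Mk model per tree and sample maps from each.

    Returns (maps with tree/map provenance, per-tree fits, per-tree
    failures); failures are logged and skipped rather than fatal.
    """
    if state_labels is None:
        state_labels = sorted(pd.unique(tip_states))
    maps: list[RegimeHistory] = []
    fits: list[MkFit] = []
    failures: list[tuple[int, str]] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(trees))
    for i, tree in enumerate(trees):
        try:
            fit = fit_mk(tree, tip_states, model=model, state_labels=state_labels,
                         root_prior=root_prior)
            tree_maps = stochastic_map(
                tree, tip_states, fit.Q, n_maps_per_tree,
                state_labels=state_labels, root_prior=root_prior,
                rng=np.random.default_rng(child_seeds[i]),
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append((i, str(exc)))
            continue
        for m in tree_maps:
            m.provenance.update({"tree_index": i, "seed": seed})
        maps.extend(tree_maps)
        fits.append(fit)
    return maps, fits, failures


# ---------------------------------------------------------------------------
# exact expected transition counts (diagnostic / oracle)
# ---------------------------------------------------------------------------

def expected_transition_counts(
    tree: Phylogeny, Q: np.ndarray, root_prior: np.ndarray | str | int = "stationary"
) -> np.ndarray:
    """Exact expected ordered-pair change counts of the unconditional CTMC.

    State-occupancy time is integrated along every branch with the augmented
    matrix exponential exp([[Q, I], [0, 0]] t), whose upper-right block is
    the integral of exp(Q s); expected i->j count = occupancy_i * q_ij.
    """
    k = Q.shape[0]
    if isinstance(root_prior, (int, np.integer)):
        p0 = np.zeros(k)
        p0[root_prior] = 1.0
    else:
        p0 = _resolve_prior(root_prior, Q)
    marg = np.zeros((tree.n_nodes, k))
    marg[tree.root] = p0
    occupancy = np.zeros(k)
    for v in tree.preorder:
        if v == tree.root:
            continue
        b = float(tree.branch_lengths[v])
        aug = np.zeros((2 * k, 2 * k))
        aug[:k, :k] = Q
        aug[:k, k:] = np.eye(k)
        E = expm(aug * b)
        occupancy += marg[tree.parent[v]] @ E[:k, k:]
        marg[v] = marg[tree.parent[v]] @ E[:k, :k]
    counts = occupancy[:, None] * Q
    np.fill_diagonal(counts, 0.0)
    return counts
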