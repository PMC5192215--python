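"""Brownian-motion and Ornstein-Uhlenbeck models on regime-painted trees.

The trait x follows dx = alpha (theta_r - x) dt + sigma_r dW along each
branch, where the regime r (and hence the optimum theta_r and diffusion rate
sigma_r^2) is given by a piecewise-constant paint.  Tip means and the tip
covariance matrix have closed forms obtained by accumulating per-segment
decay and variance along root-to-tip paths, so the likelihood is an exact
multivariate normal density — the same distribution the simulator in
:mod:`phyloenv.synthetic` draws from.

Families: BM1 (single rate), BMS (per-regime rates), OU1 (single optimum),
OUM (per-regime optima), OUMV (per-regime optima and rates), and OUMVA
(per-regime pull alpha) behind an off-by-default flag — multi-alpha fits are
prone to runaway optima and are excluded from standard reports.

The root trait sits at the root regime's optimum by default (stationarity
convention; identifiable on ultrametric trees); a free-root option exists
for sensitivity analysis.  theta is profiled by GLS and the overall variance
scale analytically, so the numeric search runs only over log alpha and log
rate ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .trees import Phylogeny, check_ultrametric_for_ou
from .histories import RegimeHistory
from .comparative import aicc_from_loglik, akaike_weights, pgls_fit

__all__ = [
    "OUModelSpec",
    "OUFitResult",
    "ou_moments",
    "ou_loglik",
    "fit_ou",
    "compare_models",
    "ensemble_fit",
    "EnsembleSummary",
    "relative_brain_residuals",
    "FAMILIES",
]

FAMILIES = ("BM1", "BMS", "OU1", "OUM", "OUMV")
_LOG2PI = np.log(2.0 * np.pi)


def family_n_params(family: str, k: int) -> int:
    """Free-parameter count: BM1 = 2 (x0, sigma^2), BMS = 1 + k, OU1 = 3
    (theta, alpha, sigma^2), OUM = k + 2, OUMV = 2k + 1, OUMVA = 3k."""
    return {
        "BM1": 2,
        "BMS": 1 + k,
        "OU1": 3,
        "OUM": k + 2,
        "OUMV": 2 * k + 1,
        "OUMVA": 3 * k,
    }[family]


@dataclass
class OUModelSpec:
    """A fully specified trait model on a painted tree.

    ``theta``/``sigma2``/``alpha`` may be scalars or per-regime arrays;
    Brownian families have ``alpha = 0`` and no optima (``theta`` is then
    the root/mean value).  ``root='optimum'`` pins the root trait at the
    root regime's optimum; ``root='free'`` adds an explicit root value x0.
    """

    family: str
    theta: float | np.ndarray | None = None
    alpha: float | np.ndarray = 0.0
    sigma2: float | np.ndarray = 1.0
    root: str = "optimum"
    x0: float | None = None


def _per_regime(value, k: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    return np.full(k, float(arr)) if arr.ndim == 0 else arr


class _OUEngine:
    """Path-integral accumulator for OU/BM moments on one painted tree.

    For a (possibly per-regime) pull vector a, computes per node the total
    decay exponent A = integral of a(s) ds along the root path, the
    per-regime variance integrals Vsh_r = integral e^{-2(A(node)-A(s))} ds,
    and per-regime attraction weights W_r = integral a e^{-(A-A(s))} ds.
    Tip covariance: V_ij = [sum_r s2_r Vsh_r(mrca)] e^{2A(mrca)-A_i-A_j}.
    """

    def __init__(self, history: RegimeHistory):
        self.history = history
        tree = history.tree
        self.tree = tree
        self.k = history.n_states
        self.mrca = tree.mrca_matrix()
        self.parent = tree.parent
        self.root_state = history.node_state(tree.root)
        self.T = tree.depth
        # flatten segments (non-root nodes) for vectorised evaluation
        seg_node, seg_state, seg_dt = [], [], []
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            seg = history.segments[v]
            seg_node.append(np.full(len(seg), v))
            seg_state.append(seg[:, 0].astype(int))
            seg_dt.append(seg[:, 2] - seg[:, 1])
        self.seg_node = np.concatenate(seg_node)
        self.seg_state = np.concatenate(seg_state)
        self.seg_dt = np.concatenate(seg_dt)
        # index of each node's final segment (segments are node-contiguous)
        counts = np.array([len(s) for s in seg_node])
        self.seg_last = np.cumsum(counts) - 1
        self.seg_last_node = self.seg_node[self.seg_last]
        # group nodes by topological level so the root-to-tip prefix pass is
        # a handful of vectorised steps rather than a per-node loop
        level = np.zeros(tree.n_nodes, dtype=int)
        for v in tree.preorder:
            if self.parent[v] >= 0:
                level[v] = level[self.parent[v]] + 1
        self.levels = [
            np.flatnonzero(level == l) for l in range(1, level.max() + 1)
        ]

    def parts(self, alpha_vec: np.ndarray):
        tree, k = self.tree, self.k
        a = alpha_vec[self.seg_state]
        adt = a * self.seg_dt
        # within-branch decay accumulated after each segment's end
        cs = np.cumsum(adt)
        node_dA = np.zeros(tree.n_nodes)
        np.add.at(node_dA, self.seg_node, adt)
        cum_to_node_end = np.zeros(tree.n_nodes)
        cum_to_node_end[self.seg_last_node] = cs[self.seg_last]
        after = cum_to_node_end[self.seg_node] - cs
        pos = a > 0
        var_seg = np.where(pos, -np.expm1(-2.0 * adt) / np.where(pos, 2.0 * a, 1.0), self.seg_dt)
        w_seg = -np.expm1(-adt)
        Vb = np.zeros((tree.n_nodes, k))
        Wb = np.zeros((tree.n_nodes, k))
        np.add.at(Vb, (self.seg_node, self.seg_state), np.exp(-2.0 * after) * var_seg)
        np.add.at(Wb, (self.seg_node, self.seg_state), np.exp(-after) * w_seg)
        A = np.zeros(tree.n_nodes)
        Vsh = np.zeros((tree.n_nodes, k))
        W = np.zeros((tree.n_nodes, k))
        for lvl in self.levels:
            p = self.parent[lvl]
            A[lvl] = A[p] + node_dA[lvl]
            e = np.exp(-node_dA[lvl])[:, None]
            Vsh[lvl] = Vsh[p] * e * e + Vb[lvl]
            W[lvl] = W[p] * e + Wb[lvl]
        return A, Vsh, W

    def design(self, A: np.ndarray, W: np.ndarray, root: str = "optimum"):
        """Tip-expectation design: columns are per-regime theta weights; the
        root contribution e^{-A_i} goes to the root regime's column
        (root='optimum') or to an extra x0 column (root='free')."""
        n = self.tree.n_tips
        D = W[:n].copy()
        rootw = np.exp(-A[:n])
        if root == "optimum":
            D[:, self.root_state] += rootw
            return D
        return np.column_stack([D, rootw])

    def covariance(self, A: np.ndarray, Vsh: np.ndarray, sigma2_vec: np.ndarray):
        n = self.tree.n_tips
        tot = Vsh @ sigma2_vec
        At = A[: n]
        expo = 2.0 * A[self.mrca] - At[:, None] - At[None, :]
        return tot[self.mrca] * np.exp(expo)


def ou_moments(history: RegimeHistory, spec: OUModelSpec):
    """Expected tip vector and tip covariance under a full model spec.

    Returns ``(mu, V)`` in tip order.  BM is the alpha -> 0 limit (variance
    accumulates as sigma^2 x time; the mean stays at the root value).
    """
    k = history.n_states
    alpha_vec = _per_regime(spec.alpha, k)
    if np.any(alpha_vec < 0):
        raise ValueError("alpha must be nonnegative")
    if np.any(alpha_vec > 0):
        check_ultrametric_for_ou(history.tree)
    eng = _OUEngine(history)
    A, Vsh, W = eng.parts(alpha_vec)
    sigma2_vec = _per_regime(spec.sigma2, k)
    V = eng.covariance(A, Vsh, sigma2_vec)
    theta = _per_regime(spec.theta if spec.theta is not None else 0.0, k)
    if spec.root == "free":
        if spec.x0 is None:
            raise ValueError("free root requires x0")
        D = eng.design(A, W, root="free")
        mu = D @ np.concatenate([theta, [spec.x0]])
    else:
        D = eng.design(A, W, root="optimum")
        mu = D @ theta
    return mu, V


def _mvn_loglik(x: np.ndarray, mu: np.ndarray, V: np.ndarray) -> float:
    n = len(x)
    jitter = 1e-12 * max(np.trace(V) / n, 1e-300)
    try:
        cf = linalg.cho_factor(V + jitter * np.eye(n), lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    r = x - mu
    z = linalg.cho_solve(cf, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * (n * _LOG2PI + logdet + r @ z))


def ou_loglik(history: RegimeHistory, x: pd.Series | np.ndarray, spec: OUModelSpec) -> float:
    """Exact multivariate-normal log-likelihood of tip trait values.

    Returns -inf when the implied covariance is numerically non-PSD."""
    xv = _align_trait(history, x)
    mu, V = ou_moments(history, spec)
    return _mvn_loglik(xv, mu, V)


def _align_trait(history: RegimeHistory, x) -> np.ndarray:
    if isinstance(x, pd.Series):
        missing = [lb for lb in history.tree.tip_labels if lb not in x.index]
        if missing:
            raise ValueError(f"trait missing for tips: {missing[:5]}")
        return x.loc[list(history.tree.tip_labels)].to_numpy(float)
    xv = np.asarray(x, dtype=float)
    if xv.shape != (history.tree.n_tips,):
        raise ValueError("trait vector length does not match tip count")
    return xv


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

@dataclass
class OUFitResult:
    family: str
    state_labels: list[str]
    theta: pd.Series | None       # per-regime optima (or single mean)
    alpha: float | pd.Series | None
    sigma2: pd.Series
    x0: float | None
    loglik: float
    n_params: int
    n: int
    aicc: float
    bic: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.flags)


def _profiled_gls(x: np.ndarray, D: np.ndarray, V0: np.ndarray):
    """ML of x ~ N(D theta, c V0) with theta and the scale c profiled out.

    Returns (loglik, theta, c); rank-deficient designs are handled by
    least squares in the whitened space."""
    n = len(x)
    jitter = 1e-12 * max(np.trace(V0) / n, 1e-300)
    try:
        L = np.linalg.cholesky(V0 + jitter * np.eye(n))
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(D.shape[1]), np.nan
    tx = linalg.solve_triangular(L, x, lower=True)
    tD = linalg.solve_triangular(L, D, lower=True)
    theta, *_ = np.linalg.lstsq(tD, tx, rcond=None)
    resid = tx - tD @ theta
    rss = float(resid @ resid)
    c = rss / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * (_LOG2PI + np.log(max(c, 1e-300)) + 1.0) + logdet)
    return float(ll), theta, c


_ALPHA_T_BOUNDS = (1e-3, 200.0)   # alpha x depth search window
_RATIO_LOG_BOUND = 12.0           # |log sigma-ratio| cap


def fit_ou(
    history: RegimeHistory,
    x: pd.Series | np.ndarray,
    family: str,
    root: str = "optimum",
    allow_oumva: bool = False,
) -> OUFitResult:
    """Maximum-likelihood fit of one trait-evolution family on one map.

    The search runs over log(alpha) and log rate ratios (optima and the
    variance scale are profiled analytically) from deterministic multi-start
    points spanning weak to strong pull.  Fits are flagged when alpha lands
    on a search bound or any optimum exceeds 10x the trait range — the
    runaway-optimum screen that also justifies keeping OUMVA off by default.
    """
    if family == "OUMVA" and not allow_oumva:
        raise ValueError("OUMVA is disabled by default (unstable optima); pass allow_oumva=True")
    if family not in FAMILIES + ("OUMVA",):
        raise ValueError(f"unknown family {family!r}")
    xv = _align_trait(history, x)
    eng = _OUEngine(history)
    k = eng.k
    n = len(xv)
    T = eng.T
    if family not in ("BM1", "BMS"):
        check_ultrametric_for_ou(history.tree)
    ones = np.ones((n, 1))
    lo, hi = np.log(_ALPHA_T_BOUNDS[0] / T), np.log(_ALPHA_T_BOUNDS[1] / T)

    def build(params: np.ndarray):
        """params -> (alpha_vec, weight_vec, design)"""
        if family == "BM1":
            return np.zeros(k), np.ones(k), ones
        if family == "BMS":
            w = np.exp(np.clip(np.concatenate([[0.0], params]), -_RATIO_LOG_BOUND, _RATIO_LOG_BOUND))
            return np.zeros(k), w, ones
        if family == "OUMVA":
            a = np.exp(np.clip(params[:k], lo, hi))
            w = np.exp(np.clip(np.concatenate([[0.0], params[k:]]), -_RATIO_LOG_BOUND, _RATIO_LOG_BOUND))
            return a, w, None
        a = np.full(k, np.exp(np.clip(params[0], lo, hi)))
        if family in ("OU1", "OUM"):
            return a, np.ones(k), None
        # OUMV
        w = np.exp(np.clip(np.concatenate([[0.0], params[1:]]), -_RATIO_LOG_BOUND, _RATIO_LOG_BOUND))
        return a, w, None

    def evaluate(params: np.ndarray):
        alpha_vec, w, D = build(np.atleast_1d(params))
        A, Vsh, W = eng.parts(alpha_vec)
        if D is None:
            D = eng.design(A, W, root=root)
            if family == "OU1":
                if root == "optimum":
                    D = D.sum(axis=1, keepdims=True)
                else:
                    D = np.column_stack([D[:, :k].sum(axis=1), D[:, k]])
        V0 = eng.covariance(A, Vsh, w)
        ll, theta, c = _profiled_gls(xv, D, V0)
        return ll, theta, c, alpha_vec, w

    def nll(params: np.ndarray) -> float:
        ll = evaluate(params)[0]
        return -ll if np.isfinite(ll) else 1e12

    n_free = {"BM1": 0, "OU1": 1, "OUM": 1, "BMS": k - 1, "OUMV": k, "OUMVA": 2 * k - 1}[family]
    converged = True
    if n_free == 0:
        best_params = np.empty(0)
    elif family in ("OU1", "OUM"):
        grid = np.log(np.array([0.05, 0.2, 0.8, 3.2, 12.8, 51.2]) / T)
        grid = np.clip(grid, lo, hi)
        vals = [nll(np.array([g])) for g in grid]
        i = int(np.argmin(vals))
        res = optimize.minimize_scalar(
            lambda g: nll(np.array([g])),
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
            method="bounded", options={"xatol": 1e-5},
        )
        best_params = np.array([res.x]) if res.fun <= min(vals) else np.array([grid[i]])
        converged = bool(res.success)
    else:
        starts = []
        if family == "BMS":
            starts = [np.zeros(k - 1), np.full(k - 1, 1.0), np.full(k - 1, -1.0)]
        elif family == "OUMV":
            # seed from the OUM pull estimate plus one moderate-pull start
            oum = fit_ou(history, xv, "OUM", root=root)
            if oum.alpha is not None and np.isfinite(oum.alpha) and oum.alpha > 0:
                starts.append(np.concatenate([[np.log(oum.alpha)], np.zeros(k - 1)]))
            starts.append(np.concatenate([[np.log(2.0 / T)], np.zeros(k - 1)]))
        else:
            for a0 in np.log(np.array([0.2, 2.0, 20.0]) / T):
                starts.append(np.concatenate([[a0], np.zeros(n_free - 1)]))
        best = None
        converged = False
        for s0 in starts:
            res = optimize.minimize(nll, s0, method="Nelder-Mead",
                                    options={"xatol": 3e-4, "fatol": 1e-6, "maxiter": 400})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            converged = converged or bool(res.success)
        best_params = np.atleast_1d(best.x)

    ll, theta, c, alpha_vec, w = evaluate(best_params)
    sigma2 = pd.Series(c * w, index=history.state_labels, name="sigma2")
    flags: list[str] = []
    if family in ("OU1", "OUM", "OUMV", "OUMVA"):
        a_hat = alpha_vec if family == "OUMVA" else float(alpha_vec[0])
        arr = np.atleast_1d(a_hat)
        if np.any(arr <= _ALPHA_T_BOUNDS[0] / T * 1.01) or np.any(arr >= _ALPHA_T_BOUNDS[1] / T * 0.99):
            flags.append("alpha_at_bound")
    else:
        a_hat = None
    screen = 10.0 * max(np.max(np.abs(xv)), 1e-12)
    theta_out: pd.Series | None
    x0 = None
    if family in ("BM1", "BMS"):
        x0 = float(theta[0])
        theta_out = None
    elif family == "OU1":
        theta_out = pd.Series(np.full(k, theta[0]), index=history.state_labels, name="theta")
        if root == "free":
            x0 = float(theta[1])
    else:
        th = theta[:k] if root == "free" else theta
        theta_out = pd.Series(th, index=history.state_labels, name="theta")
        if root == "free":
            x0 = float(theta[k])
    if theta_out is not None and np.any(np.abs(theta_out.to_numpy()) > screen):
        flags.append("theta_outside_range")
    kpar = family_n_params(family, k) + (1 if root == "free" and family not in ("BM1", "BMS") else 0)
    return OUFitResult(
        family=family,
        state_labels=list(history.state_labels),
        theta=theta_out,
        alpha=(pd.Series(a_hat, index=history.state_labels) if family == "OUMVA" else a_hat),
        sigma2=sigma2,
        x0=x0,
        loglik=float(ll),
        n_params=kpar,
        n=n,
        aicc=aicc_from_loglik(ll, kpar, n),
        bic=float(-2.0 * ll + kpar * np.log(n)),
        converged=converged,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# model comparison and ensemble summaries
# ---------------------------------------------------------------------------

def compare_models(fits: list[OUFitResult]) -> pd.DataFrame:
    """AICc/BIC ranking of fits on the same data; the ``best`` column is
    flagged only where the two criteria agree."""
    if not fits:
        raise ValueError("no fits to compare")
    if len({f.n for f in fits}) != 1:
        raise ValueError("fits are not on identical data (different n)")
    tab = pd.DataFrame(
        {
            "family": [f.family for f in fits],
            "loglik": [f.loglik for f in fits],
            "k": [f.n_params for f in fits],
            "aicc": [f.aicc for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    tab["weight"] = akaike_weights(tab["aicc"].to_numpy())
    tab["delta_bic"] = tab["bic"] - tab["bic"].min()
    best_aicc = tab.loc[tab["aicc"].idxmin(), "family"]
    best_bic = tab.loc[tab["bic"].idxmin(), "family"]
    tab["best"] = [
        (fam == best_aicc) and (best_aicc == best_bic) for fam in tab["family"]
    ]
    tab.attrs["best_aicc"] = best_aicc
    tab.attrs["best_bic"] = best_bic
    return tab.sort_values("aicc").reset_index(drop=True)


@dataclass
class EnsembleSummary:
    """Across-map model support and parameter intervals.

    ``mean_weights`` averages each family's per-map Akaike weight (weights
    are computed per map over that map's unflagged fits, so each map
    contributes a normalised vote).  ``theta_summary`` gives per-family,
    per-regime optimum mean, SE and 2.5/97.5% percentiles across maps.
    """

    mean_weights: pd.Series
    best_family: str
    theta_summary: pd.DataFrame
    n_maps: int
    n_excluded: pd.Series
    failures: list[tuple[int, str, str]] = field(default_factory=list)


def ensemble_fit(
    maps: list[RegimeHistory],
    x: pd.Series,
    families: tuple[str, ...] = FAMILIES,
    root: str = "optimum",
) -> EnsembleSummary:
    """Fit every family on every map and summarize across the ensemble.

    Fits failing the boundary screen (runaway optima or alpha on a search
    bound) are excluded from both the weight averages and the optimum
    intervals, with counts reported.
    """
    per_map_weights: list[pd.Series] = []
    thetas: dict[str, list[pd.Series]] = {f: [] for f in families}
    excluded = {f: 0 for f in families}
    failures: list[tuple[int, str, str]] = []
    for i, hist in enumerate(maps):
        fits = []
        for fam in families:
            try:
                fit = fit_ou(hist, x, fam, root=root)
            except (ValueError, np.linalg.LinAlgError) as exc:
                failures.append((i, fam, str(exc)))
                continue
            if fit.flagged:
                excluded[fam] += 1
                continue
            fits.append(fit)
            if fit.theta is not None:
                thetas[fam].append(fit.theta)
        if fits:
            w = akaike_weights(np.array([f.aicc for f in fits]))
            per_map_weights.append(pd.Series(w, index=[f.family for f in fits]))
    if not per_map_weights:
        raise ValueError("all fits failed for every map")
    weights = (
        pd.DataFrame(per_map_weights).fillna(0.0).mean(axis=0).reindex(list(families)).fillna(0.0)
    )
    weights /= weights.sum()
    rows = []
    for fam, series_list in thetas.items():
        if not series_list:
            continue
        mat = pd.DataFrame(series_list)
        for regime in mat.columns:
            vals = mat[regime].to_numpy()
            rows.append(
                {
                    "family": fam,
                    "regime": regime,
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                    "q2.5": float(np.percentile(vals, 2.5)),
                    "q97.5": float(np.percentile(vals, 97.5)),
                    "n_maps": len(vals),
                }
            )
    return EnsembleSummary(
        mean_weights=weights.rename("mean_weight"),
        best_family=str(weights.idxmax()),
        theta_summary=pd.DataFrame(rows),
        n_maps=len(maps),
        n_excluded=pd.Series(excluded, name="n_excluded"),
        failures=failures,
    )


def relative_brain_residuals(
    brain: pd.Series, body: pd.Series, tree: Phylogeny
) -> pd.Series:
    """Relative brain size: residuals of the log-log PGLS of brain on body
    with maximum-likelihood lambda, keyed by species."""
    fit = pgls_fit(brain, body.to_frame(name="log_body"), tree)
    return fit.residuals.rename("relative_brain")
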