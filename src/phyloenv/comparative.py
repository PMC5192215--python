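"""PGLS with maximum-likelihood Pagel's lambda, phylogenetic PCA, and
AICc all-subsets model selection.

The regression model is y = X b + e with e ~ N(0, sigma^2 C(lambda)), where
C is the shared-path-length matrix of the tree and C(lambda) scales its
off-diagonal entries by lambda in [0, 1] (0 = no residual phylogenetic
signal, 1 = Brownian).  sigma^2 and b are profiled analytically; lambda is
maximised on its profile log-likelihood by a dense scan plus bounded local
refinement, with boundary ties broken toward the interior.

For ultrametric trees C(lambda) = lambda*C + (1-lambda)*T*I shares C's
eigenvectors, so the whole lambda profile costs one eigendecomposition; the
generic Cholesky path handles non-ultrametric trees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import Phylogeny, PhyloCovariance, phylo_covariance, lambda_transform, warn_if_not_ultrametric

__all__ = [
    "PGLSFit",
    "pgls_fit",
    "pgls_r2",
    "phylo_pca",
    "PPCAResult",
    "model_selection",
    "SelectionTable",
    "aicc_from_loglik",
    "akaike_weights",
]

_LOG2PI = np.log(2.0 * np.pi)


def aicc_from_loglik(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc: np.ndarray) -> np.ndarray:
    delta = np.asarray(aicc, dtype=float) - np.min(aicc)
    w = np.exp(-0.5 * delta)
    return w / w.sum()


# ---------------------------------------------------------------------------
# profile-likelihood machinery
# ---------------------------------------------------------------------------

class _Profiler:
    """Evaluates the lambda profile of the GLS log-likelihood.

    Ultrametric fast path: rotate once into C's eigenbasis where C(lambda) is
    diagonal.  Fallback: Cholesky of C(lambda) per evaluation.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, C: np.ndarray):
        self.y, self.X, self.C = y, X, C
        self.n, self.p = X.shape
        d = np.diag(C)
        self.T = float(d.mean())
        self.ultrametric = np.ptp(d) <= 1e-8 * max(self.T, 1e-300)
        if self.ultrametric:
            e, U = np.linalg.eigh(C)
            self.e = np.clip(e, 0.0, None)
            self.ty = U.T @ y
            self.tX = U.T @ X

    def _wls(self, w: np.ndarray, ty: np.ndarray, tX: np.ndarray):
        sw = np.sqrt(w)
        Xw = tX / sw[:, None]
        yw = ty / sw
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < self.p:
            raise np.linalg.LinAlgError("singular design matrix in PGLS")
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        return beta, rss, Xw, yw

    def solve(self, lam: float):
        """Return (loglik, beta, rss, XtWX_inv, logdet) at this lambda."""
        if self.ultrametric:
            w = lam * self.e + (1.0 - lam) * self.T
            w = np.maximum(w, 1e-12 * self.T)
            beta, rss, Xw, _ = self._wls(w, self.ty, self.tX)
            logdet = float(np.sum(np.log(w)))
        else:
            V = lam * self.C + (1.0 - lam) * np.diag(np.diag(self.C))
            L = np.linalg.cholesky(V + 1e-12 * self.T * np.eye(self.n))
            ty = linalg.solve_triangular(L, self.y, lower=True)
            tX = linalg.solve_triangular(L, self.X, lower=True)
            beta, rss, Xw, _ = self._wls(np.ones(self.n), ty, tX)
            logdet = float(2.0 * np.sum(np.log(np.diag(L))))
        sigma2_ml = rss / self.n
        loglik = -0.5 * (self.n * (_LOG2PI + np.log(max(sigma2_ml, 1e-300)) + 1.0) + logdet)
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        return loglik, beta, rss, xtx_inv, logdet

    def loglik(self, lam: float) -> float:
        return self.solve(lam)[0]

    def rss_for_design(self, X: np.ndarray, lam: float) -> float:
        """Whitened residual sum of squares of an alternative design at the
        same lambda (used for R-squared computations)."""
        sub = _Profiler(self.y, X, self.C)
        return sub.solve(lam)[2]


def _maximize_lambda(prof: _Profiler, grid_size: int = 21) -> float:
    grid = np.linspace(0.0, 1.0, grid_size)
    vals = np.array([prof.loglik(l) for l in grid])
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda l: -prof.loglik(l), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    cands = [(float(res.x), -float(res.fun))] + [(float(g), float(v)) for g, v in zip(grid, vals)]
    best_lam, best_ll = max(cands, key=lambda t: t[1])
    # boundary ties resolved toward the interior
    if best_lam in (0.0, 1.0):
        interior = [(l, v) for l, v in cands if 0.0 < l < 1.0]
        if interior:
            l_int, v_int = max(interior, key=lambda t: t[1])
            if abs(v_int - best_ll) < 1e-6:
                best_lam = l_int
    return best_lam


# ---------------------------------------------------------------------------
# PGLS fit
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """A fitted phylogenetic regression.

    ``params`` holds one row per coefficient: estimate, SE, t value and
    two-sided p on n - p degrees of freedom.  ``r2`` is computed in the
    whitened (V^{-1/2}) space against the intercept-only model; see
    :func:`pgls_r2` for the body-size-removed partial R^2.
    """

    params: pd.DataFrame
    lambda_hat: float
    loglik: float
    n: int
    p: int
    r2: float
    sigma2: float
    aicc: float
    residuals: pd.Series
    fitted: pd.Series
    dropped: list[str] = field(default_factory=list)
    _y: np.ndarray | None = field(default=None, repr=False)
    _X: np.ndarray | None = field(default=None, repr=False)
    _C: np.ndarray | None = field(default=None, repr=False)
    _names: list[str] | None = field(default=None, repr=False)

    @property
    def coef(self) -> pd.Series:
        return self.params["estimate"]

    def summary(self) -> str:
        lines = [
            f"PGLS fit (n={self.n}, lambda={self.lambda_hat:.3f}, "
            f"logLik={self.loglik:.2f}, R2={self.r2:.3f}, AICc={self.aicc:.2f})",
            self.params.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def _align(y: pd.Series, X: pd.DataFrame, tip_labels: list[str]):
    df = pd.concat([y.rename("__y__"), X], axis=1, join="inner")
    df = df.loc[[s for s in tip_labels if s in df.index]]
    complete = df.dropna()
    dropped = sorted(set(tip_labels) - set(complete.index)) + sorted(
        set(df.index) - set(complete.index) - set(tip_labels)
    )
    return complete, dropped


def pgls_fit(
    y: pd.Series,
    X: pd.DataFrame | None,
    tree: Phylogeny | None = None,
    lambda_: str | float = "ML",
    C: PhyloCovariance | None = None,
    add_intercept: bool = True,
    k_extra: int = 2,
) -> PGLSFit:
    """Fit a phylogenetic GLS regression of ``y`` on ``X``.

    ``y`` and ``X`` are indexed by species; rows are matched to the tree's
    tips by exact label and incomplete cases are dropped (and reported in
    ``fit.dropped``).  ``lambda_`` is either "ML" (profile-likelihood
    maximisation over [0, 1]) or a fixed scalar.  ``k_extra`` is the number
    of variance-structure parameters counted in AICc (sigma^2 and lambda by
    default).
    """
    if C is None:
        if tree is None:
            raise ValueError("provide a tree or a precomputed covariance")
        warn_if_not_ultrametric(tree)
        C = phylo_covariance(tree)
    if X is None:
        X = pd.DataFrame(index=y.index)
    data, dropped = _align(y, X, C.tip_labels)
    species = list(data.index)
    pos = {lb: i for i, lb in enumerate(C.tip_labels)}
    sel = np.array([pos[s] for s in species])
    Cm = C.matrix[np.ix_(sel, sel)]
    yv = data["__y__"].to_numpy(float)
    Xd = data.drop(columns="__y__")
    names = list(Xd.columns)
    Xm = Xd.to_numpy(float)
    if add_intercept:
        Xm = np.column_stack([np.ones(len(yv)), Xm])
        names = ["intercept"] + names
    n, p = Xm.shape
    if n <= p + 1:
        raise ValueError(f"too few complete cases (n={n}) for {p} coefficients")

    prof = _Profiler(yv, Xm, Cm)
    if lambda_ == "ML":
        lam = _maximize_lambda(prof)
    else:
        lam = float(lambda_)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
    loglik, beta, rss, xtx_inv, _ = prof.solve(lam)

    sigma2_hat = rss / (n - p)  # unbiased scale for SEs
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2_hat, 0.0, None))
    tval = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pval = 2.0 * stats.t.sf(np.abs(tval), df=n - p)
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "t": tval, "p": pval}, index=names
    )

    rss_null = prof.rss_for_design(np.ones((n, 1)), lam)
    r2 = 1.0 - rss / rss_null if rss_null > 0 else 1.0
    fitted = Xm @ beta
    k = p + k_extra
    fit = PGLSFit(
        params=params,
        lambda_hat=lam,
        loglik=loglik,
        n=n,
        p=p,
        r2=float(r2),
        sigma2=rss / n,
        aicc=aicc_from_loglik(loglik, k, n),
        residuals=pd.Series(yv - fitted, index=species, name="residual"),
        fitted=pd.Series(fitted, index=species, name="fitted"),
        dropped=dropped,
        _y=yv, _X=Xm, _C=Cm, _names=names,
    )
    return fit


def pgls_r2(full: PGLSFit, reduced: PGLSFit) -> tuple[float, float]:
    """Full-model R^2 and partial R^2 with the reduced model's predictors
    removed, both in the whitened space of the full fit.

    partial R^2 = 1 - RSS(full) / RSS(reduced-design at the full fit's
    lambda); the reduced design must be a subset of the full design.
    """
    if not set(reduced._names) <= set(full._names):
        raise ValueError("models are not nested")
    if reduced.n != full.n or not np.allclose(reduced._y, full._y):
        raise ValueError("fits are not on the same response/observations")
    prof = _Profiler(full._y, full._X, full._C)
    rss_full = prof.solve(full.lambda_hat)[2]
    cols = [full._names.index(nm) for nm in reduced._names]
    rss_reduced = prof.rss_for_design(full._X[:, cols], full.lambda_hat)
    partial = 1.0 - rss_full / rss_reduced if rss_reduced > 0 else 0.0
    return full.r2, float(partial)


# ---------------------------------------------------------------------------
# phylogenetic PCA
# ---------------------------------------------------------------------------

@dataclass
class PPCAResult:
    loadings: pd.DataFrame          # variable x component correlations
    scores: pd.DataFrame            # species x component (C^-1-orthogonal)
    variance_explained: np.ndarray  # proportion per component
    evolutionary_mean: pd.Series    # the GLS mean vector a
    mode: str

    @property
    def standardized_scores(self) -> pd.DataFrame:
        """Scores z-standardized per column (for use as regression inputs)."""
        s = self.scores
        return (s - s.mean()) / s.std(ddof=0)


def phylo_pca(
    X: pd.DataFrame,
    tree: Phylogeny | None = None,
    mode: str = "correlation",
    C: PhyloCovariance | None = None,
    lam: float = 1.0,
) -> PPCAResult:
    """Phylogenetic PCA: eigendecompose the evolutionary (co)variance
    R = (X - 1a)' C^{-1} (X - 1a) / (n - 1) with a the GLS mean.

    Correlation mode (the default: the environmental variables live on
    different scales) standardises columns by the square root of R's
    diagonal before projection.  Loadings are reported as ordinary
    correlations between each variable and each score column; each component
    is sign-flipped so its largest-magnitude loading is positive.
    """
    if mode not in ("covariance", "correlation"):
        raise ValueError("mode must be 'covariance' or 'correlation'")
    if C is None:
        if tree is None:
            raise ValueError("provide a tree or covariance")
        C = phylo_covariance(tree)
    if lam != 1.0:
        C = lambda_transform(C, lam)
    data = X.loc[[s for s in C.tip_labels if s in X.index]].dropna()
    if data.shape[1] < 2:
        raise ValueError("need at least two variables")
    pos = {lb: i for i, lb in enumerate(C.tip_labels)}
    sel = np.array([pos[s] for s in data.index])
    Cm = C.matrix[np.ix_(sel, sel)]
    n = len(data)
    Xm = data.to_numpy(float)
    Ci = np.linalg.inv(Cm + 1e-12 * C.depth * np.eye(n))
    one = np.ones(n)
    a = (one @ Ci @ Xm) / (one @ Ci @ one)
    Xc = Xm - a
    R = Xc.T @ Ci @ Xc / (n - 1)
    if mode == "correlation":
        d = np.sqrt(np.diag(R))
        if np.any(d <= 0):
            raise ValueError("constant variable under correlation mode")
        Xc = Xc / d
        R = R / np.outer(d, d)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    scores = Xc @ evecs
    # correlation loadings + sign convention
    load = np.empty((Xm.shape[1], Xm.shape[1]))
    for j in range(Xm.shape[1]):
        sj = scores[:, j]
        sd = sj.std(ddof=0)
        for i in range(Xm.shape[1]):
            xi = Xm[:, i]
            denom = sd * xi.std(ddof=0)
            load[i, j] = np.corrcoef(xi, sj)[0, 1] if denom > 0 else 0.0
        imax = int(np.argmax(np.abs(load[:, j])))
        if load[imax, j] < 0:
            load[:, j] *= -1.0
            scores[:, j] *= -1.0
            evecs[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(Xm.shape[1])]
    return PPCAResult(
        loadings=pd.DataFrame(load, index=list(data.columns), columns=comp_names),
        scores=pd.DataFrame(scores, index=list(data.index), columns=comp_names),
        variance_explained=evals / evals.sum() if evals.sum() > 0 else evals,
        evolutionary_mean=pd.Series(a, index=list(data.columns), name="a"),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# all-subsets model selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionTable:
    """Per-model AICc ranking and per-variable Akaike-weight importance."""

    models: pd.DataFrame     # terms, k, loglik, aicc, delta_aicc, weight
    importance: pd.Series    # candidate variable -> summed weight
    forced: list[str]
    skipped: list[tuple[str, str]] = field(default_factory=list)


def model_selection(
    y: pd.Series,
    candidates: pd.DataFrame,
    tree: Phylogeny | None = None,
    forced: pd.DataFrame | None = None,
    C: PhyloCovariance | None = None,
) -> SelectionTable:
    """Fit every subset of ``candidates`` (forced predictors — body size in
    the standard analysis — always included), rank by AICc, and integrate
    Akaike weights per variable across all models containing it."""
    names = list(candidates.columns)
    if len(names) > 15:
        raise ValueError("more than 15 candidate predictors (2^k enumeration)")
    if C is None:
        C = phylo_covariance(tree)
    rows, weights_terms, skipped = [], [], []
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            parts = [forced] if forced is not None else []
            if combo:
                parts.append(candidates[list(combo)])
            Xd = pd.concat(parts, axis=1) if parts else None
            try:
                fit = pgls_fit(y, Xd, C=C)
            except (ValueError, np.linalg.LinAlgError) as exc:
                skipped.append(("+".join(combo) or "(null)", str(exc)))
                continue
            rows.append(
                {
                    "terms": "+".join(combo) if combo else "(forced only)",
                    "k": fit.p + 2,
                    "loglik": fit.loglik,
                    "aicc": fit.aicc,
                }
            )
            weights_terms.append(set(combo))
    models = pd.DataFrame(rows)
    w = akaike_weights(models["aicc"].to_numpy())
    models["delta_aicc"] = models["aicc"] - models["aicc"].min()
    models["weight"] = w
    importance = pd.Series(
        {nm: float(sum(wi for wi, terms in zip(w, weights_terms) if nm in terms)) for nm in names},
        name="importance",
    )
    models = models.sort_values("aicc").reset_index(drop=True)
    return SelectionTable(
        models=models,
        importance=importance,
        forced=list(forced.columns) if forced is not None else [],
        skipped=skipped,
    )
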