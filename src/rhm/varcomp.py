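"""Restricted maximum likelihood for linear mixed models with relationship-matrix components.

The model for one trait is

    y = X b + sum_k u_k + e,   u_k ~ N(0, sigma2_k K_k),   e ~ N(0, sigma2_e I),

where each K_k is a relationship matrix (genomic, regional or pedigree)
and the fixed part defaults to an intercept, since phenotypes are
pre-adjusted yield deviations.  Estimation is average-information (AI)
REML with step-halving on the restricted likelihood and EM-flavoured
fallback steps, so the likelihood never decreases and boundary solutions
(a component pinned at its lower bound) are returned as converged fits.

Two objective backends share the optimizer: a dense one for arbitrary
component sets, and a block-diagonal one used after rotating by the
eigenvectors of a single genomic relationship matrix.  The rotation makes
single-component fits (the scan's null model, the GRAMMAR adjustment) and
the bivariate genetic-correlation model O(n) per iteration instead of
O(n^3); both backends evaluate the identical restricted likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .kinship import RelationshipMatrix

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)

__all__ = [
    "VarCompModel",
    "VarCompFit",
    "BivariateFit",
    "RegionalEBV",
    "fit_reml",
    "loglik_restricted",
    "fit_bivariate",
    "blup_effects",
]


def _as_matrix(K) -> np.ndarray:
    if isinstance(K, RelationshipMatrix):
        return K.values
    return np.asarray(K, dtype=float)


@dataclass
class VarCompModel:
    """One trait, an intercept (plus optional extra fixed covariates) and named random components."""

    y: np.ndarray
    components: list  # [(name, RelationshipMatrix | ndarray), ...]
    X: np.ndarray | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        if self.X is None:
            self.X = np.ones((n, 1))
        else:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.ndim == 1:
                self.X = self.X[:, None]
        if self.X.shape[0] != n:
            raise ValueError("X and y lengths differ")
        for name, K in self.components:
            if _as_matrix(K).shape != (n, n):
                raise ValueError(f"component {name!r} matrix not {n}x{n}")
        if n < self.X.shape[1] + 2:
            raise ValueError("too few records for REML")

    @property
    def component_names(self) -> list[str]:
        return [name for name, _ in self.components]


@dataclass
class VarCompFit:
    """REML solution: variance components, restricted log-likelihood, heritabilities."""

    component_names: list[str]
    sigma2: np.ndarray            # one entry per named component
    sigma2_e: float
    loglik: float
    converged: bool
    n_iterations: int
    h2: dict                      # component name -> sigma2_k / total
    se: dict | None = None
    ids: np.ndarray | None = None
    _Py: np.ndarray | None = field(default=None, repr=False)
    _matrices: dict | None = field(default=None, repr=False)

    @property
    def total_variance(self) -> float:
        return float(np.sum(self.sigma2) + self.sigma2_e)

    @property
    def residual_fraction(self) -> float:
        return self.sigma2_e / self.total_variance

    def sigma2_of(self, name: str) -> float:
        return float(self.sigma2[self.component_names.index(name)])


@dataclass
class BivariateFit:
    """Two traits sharing one genomic component: genetic covariance matrix and rG."""

    var_g: np.ndarray       # 2x2 genetic covariance matrix
    var_e: np.ndarray       # 2x2 residual covariance matrix
    rg: float
    h2: tuple
    loglik: float
    converged: bool
    n_iterations: int


@dataclass
class RegionalEBV:
    """BLUP of one random component per individual (trait units)."""

    individual_ids: np.ndarray | None
    values: np.ndarray
    component: str


# ---------------------------------------------------------------------------
# objective backends
# ---------------------------------------------------------------------------


class _DenseObj:
    """Restricted likelihood and AI derivatives with explicit n x n algebra.

    Parameter vector: one variance per component followed by the residual
    variance (identity structure, kept implicit to save a matrix).
    """

    def __init__(self, y, X, Ks):
        self.y = y
        self.X = X
        self.Ks = Ks
        self.n, self.p = X.shape
        self.N = self.n
        self.n_par = len(Ks) + 1

    def _V(self, theta):
        V = np.zeros((self.n, self.n))
        for th, K in zip(theta[:-1], self.Ks):
            V += th * K
        V[np.diag_indices_from(V)] += theta[-1]
        return V

    def loglik(self, theta) -> float:
        V = self._V(theta)
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_y = linalg.cho_solve((c, low), self.y, check_finite=False)
        Vi_X = linalg.cho_solve((c, low), self.X, check_finite=False)
        XtVX = self.X.T @ Vi_X
        sign, logdetX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtVX, self.X.T @ Vi_y)
        r = Vi_y - Vi_X @ beta
        quad = float(self.y @ r)
        return -0.5 * (logdetV + logdetX + quad + (self.n - self.p) * _LOG2PI)

    def derivs(self, theta):
        V = self._V(theta)
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vi = linalg.cho_solve((c, low), np.eye(self.n), check_finite=False)
        W = Vi @ self.X
        XtVX = self.X.T @ W
        XtVX_inv = np.linalg.inv(XtVX)
        sign, logdetX = np.linalg.slogdet(XtVX)
        P = Vi - W @ XtVX_inv @ W.T
        r = P @ self.y
        quad = float(self.y @ r)
        ll = -0.5 * (logdetV + logdetX + quad + (self.n - self.p) * _LOG2PI)

        T = np.empty((self.n, self.n_par))
        trPB = np.empty(self.n_par)
        for k, K in enumerate(self.Ks):
            T[:, k] = K @ r
            trPB[k] = float(np.sum(P * K))
        T[:, -1] = r
        trPB[-1] = float(np.trace(P))
        S = P @ T
        score = -0.5 * (trPB - T.T @ r)
        AI = 0.5 * (T.T @ S)
        return ll, score, AI, r


class _BlockObj:
    """Block-diagonal restricted likelihood (after an eigen-rotation).

    Observations come in n independent blocks of size b: y_i ~ N(X_i beta,
    V_i(theta)) with V_i = sum_k theta_k B_{k,i}.  Components are given
    explicitly (no implicit residual).  All per-iteration work is O(n).
    """

    def __init__(self, yb, Xb, Bks):
        self.yb = yb              # (n, b)
        self.Xb = Xb              # (n, b, p)
        self.Bks = Bks            # list of (n, b, b)
        self.n, self.b = yb.shape
        self.p = Xb.shape[2]
        self.n_par = len(Bks)
        self.N = self.n * self.b

    def _V(self, theta):
        V = np.zeros((self.n, self.b, self.b))
        for th, B in zip(theta, self.Bks):
            V += th * B
        return V

    def _common(self, theta):
        V = self._V(theta)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
        Vi = np.linalg.inv(V)
        Vi_y = np.einsum("nij,nj->ni", Vi, self.yb)
        W = np.einsum("nij,njp->nip", Vi, self.Xb)
        XtVX = np.einsum("nbp,nbq->pq", self.Xb, W)
        sign, logdetX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return None
        beta = np.linalg.solve(XtVX, np.einsum("nbp,nb->p", self.Xb, Vi_y))
        r = Vi_y - np.einsum("nbp,p->nb", W, beta)
        quad = float(np.sum(self.yb * r))
        ll = -0.5 * (logdetV + logdetX + quad + (self.N - self.p) * _LOG2PI)
        return ll, Vi, W, XtVX, r

    def loglik(self, theta) -> float:
        common = self._common(theta)
        return -np.inf if common is None else common[0]

    def derivs(self, theta):
        common = self._common(theta)
        if common is None:
            raise np.linalg.LinAlgError("covariance not positive definite")
        ll, Vi, W, XtVX, r = common
        T = np.empty((self.n, self.b, self.n_par))
        trPB = np.empty(self.n_par)
        for k, B in enumerate(self.Bks):
            t = np.einsum("nij,nj->ni", B, r)
            T[:, :, k] = t
            trViB = float(np.einsum("nij,nij->", Vi, B))
            M = np.einsum("nbp,nbc,ncq->pq", W, B, W)
            trPB[k] = trViB - float(np.trace(np.linalg.solve(XtVX, M)))
        rT = np.einsum("nb,nbk->k", r, T)
        score = -0.5 * (trPB - rT)
        ViT = np.einsum("nij,njk->nik", Vi, T)
        WtT = np.einsum("nbp,nbk->pk", W, T)
        S = ViT - np.einsum("nbp,pk->nbk", W, np.linalg.solve(XtVX, WtT))
        AI = 0.5 * np.einsum("nbk,nbl->kl", T, S)
        return ll, score, AI, r


# ---------------------------------------------------------------------------
# the optimizer
# ---------------------------------------------------------------------------


def _ai_reml(obj, theta0, floors, *, tol_logl=1e-6, tol_param=1e-5,
             max_iter=200, scale=1.0):
    """Maximize the restricted likelihood with AI steps, step-halving and EM fallback.

    ``floors`` holds the lower bound per parameter (-inf for covariance
    parameters).  A parameter at its floor for 3 consecutive iterations is
    fixed there.  Returns (theta, loglik, converged, n_iter, r, AI).
    """
    theta = np.maximum(np.asarray(theta0, dtype=float), floors)
    ll, score, AI, r = obj.derivs(theta)
    pinned = np.zeros(theta.size, dtype=int)
    fixed = np.zeros(theta.size, dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        at_floor = np.isfinite(floors) & (theta <= floors * 1.0000001 + 1e-300)
        # a floored parameter whose gradient points outward stays put
        active = ~fixed & ~(at_floor & (score < 0.0))
        if not active.any():
            converged = True
            break
        delta = np.zeros_like(theta)
        sub = AI[np.ix_(active, active)]
        try:
            delta[active] = np.linalg.solve(
                sub + 1e-10 * np.eye(sub.shape[0]) * max(np.trace(sub), 1.0),
                score[active])
        except np.linalg.LinAlgError:
            delta[active] = score[active] / np.maximum(np.diag(AI)[active], 1e-8)
        # a near-singular AI matrix can propose astronomically long steps;
        # cap the proposal relative to the parameter scale before halving
        cap = 10.0 * max(float(np.max(np.abs(theta))), scale)
        biggest = float(np.max(np.abs(delta[active]), initial=0.0))
        if biggest > cap:
            delta *= cap / biggest

        def try_steps(direction, n_half):
            step = 1.0
            for _ in range(n_half):
                cand = theta.copy()
                cand[active] = theta[active] + step * direction[active]
                cand = np.maximum(cand, floors)
                ll_new = obj.loglik(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-9:
                    return cand, ll_new
                step *= 0.5
            return None, None

        cand, ll_new = try_steps(delta, 20)
        if cand is None:
            # EM-flavoured update for variance parameters; damped gradient otherwise
            fallback = np.zeros_like(theta)
            for k in np.flatnonzero(active):
                if np.isfinite(floors[k]):
                    fallback[k] = 2.0 * theta[k] ** 2 * score[k] / obj.N
                else:
                    fallback[k] = score[k] / max(AI[k, k], 1.0)
            cand, ll_new = try_steps(fallback, 20)
        if cand is None:
            cand, ll_new = theta, ll   # no progress possible this round

        d_ll = ll_new - ll
        rel = float(np.max(np.abs(cand - theta) /
                           np.maximum(np.abs(theta), 1e-3 * scale)))
        theta = cand
        ll, score, AI, r = obj.derivs(theta)
        at_floor = np.isfinite(floors) & (theta <= floors * 1.0000001 + 1e-300)
        # a clamp only counts when the likelihood really wants to go lower
        pinned = np.where(at_floor & (score <= 0.0), pinned + 1, 0)
        fixed |= pinned >= 3
        if abs(d_ll) < tol_logl and rel < tol_param:
            converged = True
            break
    return theta, ll, converged, it, r, AI


# ---------------------------------------------------------------------------
# public fits
# ---------------------------------------------------------------------------


def loglik_restricted(model: VarCompModel, sigma2_values) -> float:
    """Restricted log-likelihood at given variance values (components..., residual last).

    Deterministic; raises on a singular total covariance.
    """
    theta = np.asarray(sigma2_values, dtype=float).ravel()
    if theta.size != len(model.components) + 1:
        raise ValueError("need one value per component plus the residual")
    if np.any(theta < 0) or not np.any(theta > 0):
        raise ValueError("variances must be non-negative and not all zero")
    obj = _DenseObj(model.y, model.X, [_as_matrix(K) for _, K in model.components])
    ll = obj.loglik(theta)
    if not np.isfinite(ll):
        raise np.linalg.LinAlgError("total covariance singular at supplied values")
    return float(ll)


def fit_reml(model: VarCompModel, init=None, tol: float = 1e-6,
             max_iter: int = 200, compute_se: bool = False) -> VarCompFit:
    """AI-REML fit of ``model`` over non-negative variance components.

    Components are clamped at 1e-8 * var(y); boundary solutions are
    legitimate converged fits.  ``init`` optionally supplies starting
    values (components..., residual); the default splits the phenotypic
    variance equally across all components including the residual.
    """
    y, X = model.y, model.X
    n, p = X.shape
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValueError("constant phenotype: REML undefined")
    names = model.component_names
    K_mats = [_as_matrix(K) for _, K in model.components]
    nk = len(K_mats)

    if nk == 0:
        Q = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
        rss = float(y @ Q @ y)
        s2e = rss / (n - p)
        ll = _DenseObj(y, X, []).loglik(np.array([s2e]))
        return VarCompFit([], np.zeros(0), s2e, float(ll), True, 0,
                          {}, ids=model.ids, _Py=(Q @ y) / s2e, _matrices={})

    floors = np.full(nk + 1, 1e-8 * vy)
    theta0 = np.full(nk + 1, vy / (nk + 1)) if init is None \
        else np.asarray(init, dtype=float)

    rotate_back = None
    if nk == 1:
        # canonical transformation: one relationship matrix diagonalizes
        w, U = np.linalg.eigh(K_mats[0])
        w = np.clip(w, 0.0, None)
        yb = (U.T @ y)[:, None]
        Xb = (U.T @ X)[:, None, :] if p > 1 else (U.T @ X).reshape(n, 1, 1)
        B1 = w[:, None, None]
        B2 = np.ones((n, 1, 1))
        obj = _BlockObj(yb, Xb, [B1, B2])
        rotate_back = U
    else:
        obj = _DenseObj(y, X, K_mats)

    theta, ll, conv, nit, r, AI = _ai_reml(obj, theta0, floors, tol_logl=tol,
                                           max_iter=max_iter, scale=vy)
    if not conv:
        warnings.warn(f"REML did not converge in {nit} iterations", RuntimeWarning)
    if rotate_back is not None:
        r = rotate_back @ r[:, 0]

    sigma2 = theta[:-1].copy()
    s2e = float(theta[-1])
    total = float(sigma2.sum() + s2e)
    h2 = {name: float(s / total) for name, s in zip(names, sigma2)}
    se = None
    if compute_se:
        try:
            cov = np.linalg.pinv(AI)
            se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            se = {**{nm: float(v) for nm, v in zip(names, se_all[:-1])},
                  "residual": float(se_all[-1])}
        except np.linalg.LinAlgError:
            se = None
    return VarCompFit(names, sigma2, s2e, float(ll), conv, nit, h2, se=se,
                      ids=model.ids, _Py=r,
                      _matrices={nm: K for nm, K in zip(names, K_mats)})


def blup_effects(fit: VarCompFit, component_name: str) -> RegionalEBV:
    """BLUP of one random component: u_hat = sigma2_k K_k P y at the REML estimates."""
    if component_name not in fit.component_names:
        raise KeyError(f"no component named {component_name!r}")
    s2 = fit.sigma2_of(component_name)
    if fit._Py is None or fit._matrices is None:
        raise ValueError("fit does not carry BLUP information")
    K = fit._matrices[component_name]
    floor = 1e-7 * fit.total_variance
    if s2 <= floor:
        warnings.warn(f"component {component_name!r} variance at the boundary; "
                      "BLUPs are zero", RuntimeWarning)
        return RegionalEBV(fit.ids, np.zeros(K.shape[0]), component_name)
    return RegionalEBV(fit.ids, s2 * (K @ fit._Py), component_name)


def fit_bivariate(y1, y2, G, tol: float = 1e-6, max_iter: int = 200,
                  residual_cov: bool = False) -> BivariateFit:
    """Bivariate REML under one shared genomic component.

    The stacked model has covariance  Sigma_g (x) G + Sigma_e (x) I  with
    a full 2x2 genetic covariance matrix; the residual covariance matrix
    is diagonal by default (phenotypes here are pre-adjusted deviations
    whose cross-trait residual covariance is attributed to genetics), and
    ``residual_cov=True`` frees its off-diagonal.  Rotating both traits by
    the eigenvectors of G makes the likelihood a product over n
    independent 2x2 blocks.  Both traits must be aligned to the same
    individuals (the id intersection) beforehand.
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    Gm = _as_matrix(G)
    n = y1.size
    if y2.size != n or Gm.shape != (n, n):
        raise ValueError("y1, y2 and G must share one id ordering")
    v1 = float(np.var(y1, ddof=1))
    v2 = float(np.var(y2, ddof=1))

    w, U = np.linalg.eigh(Gm)
    w = np.clip(w, 0.0, None)
    yb = np.column_stack([U.T @ y1, U.T @ y2])
    u1 = U.T @ np.ones(n)
    Xb = u1[:, None, None] * np.eye(2)[None, :, :]   # intercept per trait

    E11 = np.array([[1.0, 0.0], [0.0, 0.0]])
    E12 = np.array([[0.0, 1.0], [1.0, 0.0]])
    E22 = np.array([[0.0, 0.0], [0.0, 1.0]])
    d = w[:, None, None]
    one = np.ones((n, 1, 1))
    Bks = [d * E11, d * E12, d * E22, one * E11, one * E22]
    floors = [1e-8 * v1, -np.inf, 1e-8 * v2, 1e-8 * v1, 1e-8 * v2]
    theta0 = [v1 / 2, 0.0, v2 / 2, v1 / 2, v2 / 2]
    if residual_cov:
        Bks.insert(4, one * E12)
        floors.insert(4, -np.inf)
        theta0.insert(4, 0.0)
    obj = _BlockObj(yb, Xb, Bks)
    theta, ll, conv, nit, _, _ = _ai_reml(obj, np.array(theta0),
                                          np.array(floors), tol_logl=tol,
                                          max_iter=max_iter,
                                          scale=np.sqrt(v1 * v2))
    if not conv:
        warnings.warn(f"bivariate REML did not converge in {nit} iterations",
                      RuntimeWarning)
    Sg = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
    e12 = theta[4] if residual_cov else 0.0
    Se = np.array([[theta[3], e12], [e12, theta[-1]]])
    denom = np.sqrt(max(Sg[0, 0], 0.0) * max(Sg[1, 1], 0.0))
    rg = float(np.clip(Sg[0, 1] / denom, -1.0, 1.0)) if denom > 0 else np.nan
    h2 = (float(Sg[0, 0] / (Sg[0, 0] + Se[0, 0])),
          float(Sg[1, 1] / (Sg[1, 1] + Se[1, 1])))
    return BivariateFit(Sg, Se, rg, h2, float(ll), conv, nit)
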