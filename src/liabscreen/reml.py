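"""Restricted maximum likelihood for variance components tied to GRMs.

The model is the standard GREML linear mixed model on the observed 0/1
scale,

    y ~ N(X b, sum_c s2_c A_c + s2_e I),

maximized by average-information (AI) REML with EM-REML fallback steps.
Estimates are unconstrained by default: a variance component may go
negative as long as the total covariance matrix V stays positive definite.
Case-control estimates are mapped to the liability scale with the
prevalence/ascertainment correction

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)),

where K is the population prevalence, P the sample case proportion and z
the standard-normal density at the liability threshold.

With a single GRM the solver works in the GRM's eigenbasis, which makes
every REML iteration O(n p^2) after one eigendecomposition; multi-component
models use dense Cholesky algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .grm import Grm

_LOG2PI = np.log(2.0 * np.pi)


class NotPositiveDefinite(Exception):
    pass


# ---------------------------------------------------------------------------
# Scalar helpers: liability transform, LRT, Wald
# ---------------------------------------------------------------------------

@dataclass
class LiabilityParams:
    """Prevalence K, sample case proportion P and the threshold density z."""

    K: float
    P: float

    def __post_init__(self) -> None:
        if not (0 < self.K < 1 and 0 < self.P < 1):
            raise ValueError("K and P must lie strictly in (0, 1)")

    @property
    def threshold(self) -> float:
        return float(stats.norm.isf(self.K))

    @property
    def z(self) -> float:
        return float(stats.norm.pdf(self.threshold))


def obs_to_liability(h2_obs: float, lp: LiabilityParams) -> float:
    """Observed-scale to liability-scale heritability (sign preserving)."""
    K, P, z = lp.K, lp.P, lp.z
    return h2_obs * K * K * (1 - K) * (1 - K) / (z * z * P * (1 - P))


def liability_to_obs(h2_liab: float, lp: LiabilityParams) -> float:
    K, P, z = lp.K, lp.P, lp.z
    return h2_liab * z * z * P * (1 - P) / (K * K * (1 - K) * (1 - K))


def lrt_p(logl_full: float, logl_reduced: float, df: int = 1, mixture: bool = False) -> float:
    """Likelihood-ratio P-value from restricted log-likelihoods.

    ``mixture=True`` uses the 50:50 mixture of chi2_0 and chi2_df appropriate
    when the component is constrained non-negative under the null.
    """
    stat = 2.0 * (logl_full - logl_reduced)
    if stat < -1e-6:
        raise ValueError(
            f"full model log-likelihood below reduced ({logl_full} < {logl_reduced}); "
            "models appear mis-nested"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    if mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return min(p, 1.0)


def wald_component_p(estimate: float, se: float) -> float:
    """Chi-square (1 df) P-value for (estimate / se)^2."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(stats.chi2.sf((estimate / se) ** 2, 1))


def null_restricted_logl(y: np.ndarray, X: np.ndarray) -> float:
    """Closed-form maximized restricted log-likelihood of y ~ N(Xb, s2 I)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    beta, rss_arr, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    # Harville restricted likelihood (includes -log|X'X|), so the value is
    # invariant to affine reparameterization of the covariate columns
    return -0.5 * (n - p) * (_LOG2PI + np.log(s2) + 1.0)


# ---------------------------------------------------------------------------
# Solvers: per-iteration REML quantities at a parameter point
# ---------------------------------------------------------------------------

@dataclass
class _Quantities:
    llf: float
    score: np.ndarray
    ai: np.ndarray
    beta: np.ndarray
    beta_cov: np.ndarray


class _DenseSolver:
    """General V = sum_c theta_c M_c (structure matrices given explicitly)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, mats: Sequence[np.ndarray]):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.mats = [np.asarray(m, float) for m in mats]
        self.n, self.p = self.X.shape
        _, self.ld_xx = np.linalg.slogdet(self.X.T @ self.X)

    def __call__(self, theta: np.ndarray) -> _Quantities:
        n, p = self.n, self.p
        V = sum(t * M for t, M in zip(theta, self.mats))
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError as e:
            raise NotPositiveDefinite(str(e))
        ld_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        VinvX = Vinv @ self.X
        B = self.X.T @ VinvX
        sign, ld_b = np.linalg.slogdet(B)
        if sign <= 0:
            raise NotPositiveDefinite("X'V^-1X not positive definite")
        Binv = np.linalg.inv(B)
        P = Vinv - VinvX @ Binv @ VinvX.T
        Py = P @ self.y
        yPy = float(self.y @ Py)
        llf = -0.5 * ((n - p) * _LOG2PI + ld_v + ld_b - self.ld_xx + yPy)
        K = len(self.mats)
        APy = [M @ Py for M in self.mats]
        PAPy = [P @ v for v in APy]
        tr = np.array([float(np.sum(P * M)) for M in self.mats])
        quad = np.array([float(Py @ v) for v in APy])
        score = -0.5 * (tr - quad)
        ai = 0.5 * np.array([[float(APy[i] @ PAPy[j]) for j in range(K)] for i in range(K)])
        beta = Binv @ (VinvX.T @ self.y)
        return _Quantities(llf, score, ai, beta, Binv)


class _EigenSolver:
    """Single GRM + residual, solved in the GRM eigenbasis: V = diag(t_g w + t_e)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, grm_values: np.ndarray,
                 eig: tuple | None = None):
        if eig is None:
            w, U = np.linalg.eigh(grm_values)
        else:
            w, U = eig
        self.w = w
        self.yt = U.T @ np.asarray(y, float)
        self.Xt = U.T @ np.asarray(X, float)
        self.n, self.p = self.Xt.shape
        _, self.ld_xx = np.linalg.slogdet(self.Xt.T @ self.Xt)

    def _pdot(self, v, d, Z, Bc):
        return v / d - Z @ linalg.cho_solve(Bc, Z.T @ v, check_finite=False)

    def __call__(self, theta: np.ndarray) -> _Quantities:
        tg, te = theta
        d = tg * self.w + te
        if np.min(d) <= 0:
            raise NotPositiveDefinite("V has a non-positive eigenvalue")
        n, p = self.n, self.p
        Z = self.Xt / d[:, None]
        B = self.Xt.T @ Z
        try:
            Bc = linalg.cho_factor(B, lower=True, check_finite=False)
        except linalg.LinAlgError as e:
            raise NotPositiveDefinite(str(e))
        ld_v = float(np.sum(np.log(d)))
        ld_b = 2.0 * float(np.sum(np.log(np.diag(Bc[0]))))
        Py = self._pdot(self.yt, d, Z, Bc)
        yPy = float(self.yt @ Py)
        llf = -0.5 * ((n - p) * _LOG2PI + ld_v + ld_b - self.ld_xx + yPy)

        diags = [self.w, np.ones(n)]
        tr = np.empty(2)
        for i, a in enumerate(diags):
            M = (Z * (a / d)[:, None]).T @ self.Xt  # X'V^-1 A V^-1 X
            tr[i] = float(np.sum(a / d)) - float(
                np.trace(linalg.cho_solve(Bc, M, check_finite=False))
            )
        APy = [a * Py for a in diags]
        PAPy = [self._pdot(v, d, Z, Bc) for v in APy]
        quad = np.array([float(Py @ v) for v in APy])
        score = -0.5 * (tr - quad)
        ai = 0.5 * np.array(
            [[float(APy[i] @ PAPy[j]) for j in range(2)] for i in range(2)]
        )
        Binv = linalg.cho_solve(Bc, np.eye(p), check_finite=False)
        beta = Binv @ (Z.T @ self.yt)
        return _Quantities(llf, score, ai, beta, Binv)


# ---------------------------------------------------------------------------
# The iteration
# ---------------------------------------------------------------------------

def _iterate_reml(solver, theta0, tol, max_iter, floor):
    """AI-REML with step-halving and EM fallback; returns final state."""
    theta = np.asarray(theta0, float).copy()
    q = solver(theta)
    converged = False
    n_iter = 0
    ai_singular = False
    for n_iter in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(q.ai, q.score)
        except np.linalg.LinAlgError:
            ai_singular = True
            delta = np.linalg.pinv(q.ai) @ q.score
        if np.linalg.cond(q.ai) > 1e10:
            ai_singular = True
        q_new = None
        step = 1.0
        for _ in range(16):
            cand = theta + step * delta
            if cand.sum() > floor:
                try:
                    trial = solver(cand)
                except NotPositiveDefinite:
                    trial = None
                if trial is not None and trial.llf >= q.llf - 1e-10:
                    q_new, theta_new = trial, cand
                    break
            step *= 0.5
        if q_new is None:
            # EM-REML fallback: theta_i += 2 theta_i^2 score_i / n
            n = getattr(solver, "n")
            cand = theta + 2.0 * theta**2 * q.score / n
            shrink = 1.0
            for _ in range(16):
                trial_theta = theta + shrink * (cand - theta)
                if trial_theta.sum() > floor:
                    try:
                        q_new = solver(trial_theta)
                        theta_new = trial_theta
                        break
                    except NotPositiveDefinite:
                        pass
                shrink *= 0.5
            if q_new is None:
                break  # stuck; report non-convergence at current point
        dll = q_new.llf - q.llf
        theta, q = theta_new, q_new
        if abs(dll) < tol:
            converged = True
            break
    return theta, q, converged, n_iter, ai_singular


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class VarianceComponentsModel:
    """GREML mixed model for one phenotype and one or more GRMs.

    Parameters
    ----------
    y : phenotype vector (0/1 case-control on the observed scale, or a
        continuous trait), aligned with the GRMs' sample order.
    X : fixed-effect design matrix (an intercept column is prepended unless
        ``add_intercept=False``); ``None`` means intercept only.
    grms : list of :class:`~liabscreen.grm.Grm` objects or raw square
        arrays, all on the same samples in the same order.
    names : labels for the genetic components (defaults V(G1), V(G2), ...).
    """

    def __init__(self, y, X=None, grms=(), names=None, add_intercept=True):
        self.y = np.asarray(y, float).ravel()
        n = self.y.size
        if X is None:
            X = np.empty((n, 0))
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        if add_intercept:
            X = np.column_stack([np.ones(n), X])
        if X.shape[0] != n:
            raise ValueError("X rows do not match y")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix X is rank deficient")
        self.X = X
        self.grm_objects = list(grms)
        self.grm_values = [
            g.values if isinstance(g, Grm) else np.asarray(g, float) for g in grms
        ]
        for A in self.grm_values:
            if A.shape != (n, n):
                raise ValueError("GRM dimensions do not match y")
        k = len(self.grm_values)
        self.names = list(names) if names is not None else [
            f"V(G{i + 1})" for i in range(k)
        ]
        self.names_full = self.names + ["V(e)"]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, pheno: str, covars: Sequence[str],
                       grms: Sequence[Grm], id_col: str = "sample_id"):
        """Build a model from a tidy table, aligning rows to the (shared)
        GRM sample order and dropping rows with any missing value."""
        ids = list(grms[0].sample_ids)
        sub = df.set_index(id_col).loc[ids, [pheno, *covars]].dropna()
        kept = list(sub.index)
        aligned = [g.subset(kept) for g in grms]
        model = cls(sub[pheno].to_numpy(), sub[list(covars)].to_numpy(), aligned)
        model.sample_ids = kept
        return model

    def fit(self, tol: float = 1e-8, max_iter: int = 100,
            constrain_nonnegative: bool = False,
            start: Sequence[float] | None = None) -> "VarianceComponentsResults":
        n = self.y.size
        k = len(self.grm_values)
        vp = float(np.var(self.y, ddof=1)) if n > 1 else 1.0
        if start is None:
            if k:
                theta0 = np.array([0.25 * vp / k] * k + [vp * (1 - 0.25)])
            else:
                theta0 = np.array([vp])
        else:
            theta0 = np.asarray(start, float)

        if k == 1:
            eig = self.grm_objects[0].eig() if isinstance(self.grm_objects[0], Grm) else None
            solver = _EigenSolver(self.y, self.X, self.grm_values[0], eig=eig)
        else:
            mats = self.grm_values + [np.eye(n)]
            solver = _DenseSolver(self.y, self.X, mats)

        floor = 1e-8 * max(vp, 1e-12)
        if constrain_nonnegative:
            theta, q, converged, n_iter, ai_singular = self._fit_constrained(
                solver, theta0, tol, max_iter, floor
            )
        else:
            theta, q, converged, n_iter, ai_singular = _iterate_reml(
                solver, theta0, tol, max_iter, floor
            )
        se = np.sqrt(np.maximum(np.diag(np.linalg.pinv(q.ai)), 0.0))
        return VarianceComponentsResults(
            model=self,
            vc=theta,
            vc_se=se,
            vc_cov=np.linalg.pinv(q.ai),
            fe=q.beta,
            fe_se=np.sqrt(np.diag(q.beta_cov)),
            llf=q.llf,
            converged=converged,
            n_iter=n_iter,
            ai_singular=ai_singular,
        )

    def _fit_constrained(self, solver, theta0, tol, max_iter, floor):
        # simple projected variant: clamp negative components to a tiny floor
        theta = np.asarray(theta0, float).copy()
        q = solver(theta)
        converged, it, ai_singular = False, 0, False
        tiny = max(floor, 1e-10)
        for it in range(1, max_iter + 1):
            try:
                delta = np.linalg.solve(q.ai, q.score)
            except np.linalg.LinAlgError:
                ai_singular = True
                delta = np.linalg.pinv(q.ai) @ q.score
            step, q_new = 1.0, None
            for _ in range(16):
                cand = np.maximum(theta + step * delta, tiny)
                try:
                    trial = solver(cand)
                except NotPositiveDefinite:
                    trial = None
                if trial is not None and trial.llf >= q.llf - 1e-10:
                    q_new, theta_new = trial, cand
                    break
                step *= 0.5
            if q_new is None:
                break
            dll = q_new.llf - q.llf
            theta, q = theta_new, q_new
            if abs(dll) < tol:
                converged = True
                break
        return theta, q, converged, it, ai_singular


@dataclass
class VarianceComponentsResults:
    """REML estimates with their average-information standard errors."""

    model: VarianceComponentsModel
    vc: np.ndarray
    vc_se: np.ndarray
    vc_cov: np.ndarray
    fe: np.ndarray
    fe_se: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    ai_singular: bool

    @property
    def n(self) -> int:
        return self.model.y.size

    @property
    def total_variance(self) -> float:
        return float(self.vc.sum())

    def h2_obs(self, component: int = 0) -> float:
        """Observed-scale variance ratio s2_c / sum(s2)."""
        return float(self.vc[component] / self.total_variance)

    @property
    def h2_obs_total(self) -> float:
        k = len(self.vc) - 1
        return float(self.vc[:k].sum() / self.total_variance)

    def h2_obs_se(self, component: int = 0) -> float:
        """Delta-method SE of the variance ratio for one component."""
        S = self.total_variance
        t = self.vc
        g = np.full(len(t), -t[component] / S**2)
        g[component] += 1.0 / S
        return float(np.sqrt(g @ self.vc_cov @ g))

    def h2_liability(self, K: float | None = None, P: float | None = None,
                     component: int = 0) -> tuple[float, float]:
        """Liability-scale heritability for one genetic component and its SE.

        K defaults to the sample case proportion (i.e., no ascertainment
        correction beyond the threshold-model factor); P defaults to the
        sample case proportion.
        """
        if P is None:
            P = float(np.mean(self.model.y))
        if K is None:
            K = P
        lp = LiabilityParams(K=K, P=P)
        h2 = self.h2_obs(component)
        se = self.h2_obs_se(component)
        factor = obs_to_liability(1.0, lp)
        return h2 * factor, se * factor

    def wald_p(self, component: int = 0) -> float:
        return wald_component_p(self.vc[component], self.vc_se[component])

    def summary(self) -> pd.DataFrame:
        names = self.model.names_full
        rows = []
        for i, name in enumerate(names):
            rows.append(
                {
                    "component": name,
                    "estimate": self.vc[i],
                    "se": self.vc_se[i],
                }
            )
        k = len(self.vc) - 1
        for i in range(k):
            rows.append(
                {
                    "component": f"{self.model.names[i]}/Vp",
                    "estimate": self.h2_obs(i),
                    "se": self.h2_obs_se(i),
                }
            )
        rows.append({"component": "Vp", "estimate": self.total_variance, "se": np.nan})
        rows.append({"component": "logL", "estimate": self.llf, "se": np.nan})
        return pd.DataFrame(rows)


def fit_reml(y, X, grms, tol: float = 1e-8, max_iter: int = 100,
             constrain_nonnegative: bool = False,
             add_intercept: bool = True) -> VarianceComponentsResults:
    """Functional wrapper around :class:`VarianceComponentsModel`."""
    model = VarianceComponentsModel(y, X, grms, add_intercept=add_intercept)
    return model.fit(tol=tol, max_iter=max_iter,
                     constrain_nonnegative=constrain_nonnegative)
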