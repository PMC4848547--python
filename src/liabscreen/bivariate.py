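"""Bivariate GREML: genetic covariance and correlation between two traits.

The two phenotype vectors are stacked and the joint covariance is built
from block structure matrices sharing one GRM A:

    V = | vG1*A11 + vE1*I    covG*A12 + covE*S  |
        | covG*A21 + covE*S' vG2*A22 + vE2*I    |

where A_rs are the GRM blocks for the two traits' (possibly different,
possibly overlapping) sample sets, and S marks samples present in both
traits (residual covariance is only estimable on the overlap and the covE
component is dropped when the sets are disjoint).  Fitting reuses the
dense AI-REML machinery; the genetic correlation is
rG = covG / sqrt(vG1 * vG2) with a delta-method standard error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grm import Grm
from .reml import _DenseSolver, _iterate_reml


class BivariateVarianceModel:
    """Two traits, one GRM, unconstrained (co)variance components.

    Parameters
    ----------
    y1, y2 : phenotype vectors for the two traits.
    X1, X2 : covariate matrices (intercepts prepended).
    grm : the shared :class:`Grm`.
    ids1, ids2 : sample ids for each trait (rows of y/X), all present in
        ``grm.sample_ids``.
    """

    def __init__(self, y1, y2, X1, X2, grm: Grm, ids1, ids2):
        self.y1 = np.asarray(y1, float).ravel()
        self.y2 = np.asarray(y2, float).ravel()
        n1, n2 = self.y1.size, self.y2.size
        ids1, ids2 = list(map(str, ids1)), list(map(str, ids2))
        if len(ids1) != n1 or len(ids2) != n2:
            raise ValueError("trait sample ids do not match phenotype lengths")

        lookup = pd.Index(grm.sample_ids)
        i1 = lookup.get_indexer(ids1)
        i2 = lookup.get_indexer(ids2)
        if (i1 < 0).any() or (i2 < 0).any():
            raise ValueError("trait sample ids missing from the GRM")
        A = grm.values
        A11 = A[np.ix_(i1, i1)]
        A22 = A[np.ix_(i2, i2)]
        A12 = A[np.ix_(i1, i2)]

        def _pad(top_left=None, top_right=None, bottom_right=None):
            M = np.zeros((n1 + n2, n1 + n2))
            if top_left is not None:
                M[:n1, :n1] = top_left
            if bottom_right is not None:
                M[n1:, n1:] = bottom_right
            if top_right is not None:
                M[:n1, n1:] = top_right
                M[n1:, :n1] = top_right.T
            return M

        S = (np.asarray(ids1)[:, None] == np.asarray(ids2)[None, :]).astype(float)
        self.has_overlap = bool(S.any())

        self.mats = [
            _pad(top_left=A11),                      # vG1
            _pad(bottom_right=A22),                  # vG2
            _pad(top_right=A12),                     # covG
            _pad(top_left=np.eye(n1)),               # vE1
            _pad(bottom_right=np.eye(n2)),           # vE2
        ]
        self.names = ["V(G1)", "V(G2)", "C(G12)", "V(e1)", "V(e2)"]
        if self.has_overlap:
            self.mats.append(_pad(top_right=S))      # covE
            self.names.append("C(e12)")

        def _design(X, n):
            if X is None:
                X = np.empty((n, 0))
            X = np.asarray(X, float)
            if X.ndim == 1:
                X = X[:, None]
            return np.column_stack([np.ones(n), X])

        D1, D2 = _design(X1, n1), _design(X2, n2)
        X = np.zeros((n1 + n2, D1.shape[1] + D2.shape[1]))
        X[:n1, : D1.shape[1]] = D1
        X[n1:, D1.shape[1]:] = D2
        self.X = X
        self.y = np.concatenate([self.y1, self.y2])
        self.ids1, self.ids2 = ids1, ids2

    def fit(self, constrain_rg_zero: bool = False, tol: float = 1e-8,
            max_iter: int = 100) -> "BivariateResults":
        v1 = float(np.var(self.y1, ddof=1))
        v2 = float(np.var(self.y2, ddof=1))
        start = {
            "V(G1)": 0.25 * v1, "V(G2)": 0.25 * v2, "C(G12)": 0.0,
            "V(e1)": 0.75 * v1, "V(e2)": 0.75 * v2, "C(e12)": 0.0,
        }
        active = [
            k for k in range(len(self.mats))
            if not (constrain_rg_zero and self.names[k] == "C(G12)")
        ]
        mats = [self.mats[k] for k in active]
        names = [self.names[k] for k in active]
        theta0 = np.array([start[nm] for nm in names])
        solver = _DenseSolver(self.y, self.X, mats)
        floor = 1e-8 * max(v1 + v2, 1e-12)
        theta, q, converged, n_iter, ai_singular = _iterate_reml(
            solver, theta0, tol, max_iter, floor
        )
        full = dict(zip(names, theta))
        cov = np.linalg.pinv(q.ai)
        se = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
        return BivariateResults(
            model=self,
            params=full,
            param_se=se,
            param_names=names,
            param_cov=cov,
            llf=q.llf,
            converged=converged,
            n_iter=n_iter,
            ai_singular=ai_singular,
            constrained=constrain_rg_zero,
        )


@dataclass
class BivariateResults:
    model: BivariateVarianceModel
    params: dict
    param_se: dict
    param_names: list
    param_cov: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    ai_singular: bool
    constrained: bool

    @property
    def vg1(self) -> float:
        return self.params["V(G1)"]

    @property
    def vg2(self) -> float:
        return self.params["V(G2)"]

    @property
    def covg(self) -> float:
        return self.params.get("C(G12)", 0.0)

    @property
    def rg_defined(self) -> bool:
        return self.vg1 > 0 and self.vg2 > 0

    @property
    def rg(self) -> float:
        """Genetic correlation; NaN (flagged via rg_defined) when either
        genetic variance estimate is non-positive.  Values beyond +-1 are
        reported as estimated, not clamped."""
        if not self.rg_defined:
            return float("nan")
        return float(self.covg / np.sqrt(self.vg1 * self.vg2))

    @property
    def rg_se(self) -> float:
        """Delta-method SE of rG from the AI covariance of (vG1, vG2, covG)."""
        if not self.rg_defined or self.constrained:
            return float("nan")
        idx = [self.param_names.index(k) for k in ("V(G1)", "V(G2)", "C(G12)")]
        C = self.param_cov[np.ix_(idx, idx)]
        r = self.rg
        g = np.array([-r / (2 * self.vg1), -r / (2 * self.vg2),
                      1.0 / np.sqrt(self.vg1 * self.vg2)])
        var = float(g @ C @ g)
        return float(np.sqrt(max(var, 0.0)))

    def summary(self) -> pd.DataFrame:
        rows = [
            {"component": nm, "estimate": self.params[nm], "se": self.param_se[nm]}
            for nm in self.param_names
        ]
        rows.append({"component": "rG", "estimate": self.rg, "se": self.rg_se})
        rows.append({"component": "logL", "estimate": self.llf, "se": np.nan})
        return pd.DataFrame(rows)


def fit_bivariate_reml(y1, y2, X1, X2, grm: Grm, ids1, ids2,
                       constrain_rg_zero: bool = False,
                       tol: float = 1e-8, max_iter: int = 100) -> BivariateResults:
    """Functional wrapper around :class:`BivariateVarianceModel`."""
    model = BivariateVarianceModel(y1, y2, X1, X2, grm, ids1, ids2)
    return model.fit(constrain_rg_zero=constrain_rg_zero, tol=tol, max_iter=max_iter)


def rg_lrt_p(fit_free: BivariateResults, fit_constrained: BivariateResults) -> float:
    """Chi-square (1 df) P-value for the LRT of rG = 0."""
    stat = 2.0 * (fit_free.llf - fit_constrained.llf)
    if stat < -1e-6:
        raise ValueError("constrained log-likelihood exceeds the free fit")
    return float(stats.chi2.sf(max(stat, 0.0), 1))
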