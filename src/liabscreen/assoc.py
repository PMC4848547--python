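"""Additive logistic association scans and fixed-effect meta-analysis.

Per SNP, ``logit P(case) = b0 + b1 * dosage + covariates`` is fitted by
iteratively reweighted least squares on complete cases; the Wald standard
error comes from the observed information at convergence.  Study-level
odds ratios printed with 95% confidence intervals are pooled on the
log-odds scale with inverse-variance weights, the standard errors being
recovered from the CI half-width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeDataset, StudySummary

Z95 = float(stats.norm.isf(0.025))  # two-sided 95% normal quantile, 1.959964...
SEPARATION_BETA = 15.0


# ---------------------------------------------------------------------------
# Logistic regression core
# ---------------------------------------------------------------------------

def _logistic_irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 50) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS logistic fit; returns (beta, se, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    XtX = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        Xw = X * w[:, None]
        H = X.T @ Xw
        g = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"singular information matrix: {e}")
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            XtX = H
            break
        XtX = H
    cov = np.linalg.pinv(XtX)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, se, converged


ASSOC_COLUMNS = [
    "snp_id", "chrom", "pos", "allele", "n_used", "maf_cases", "maf_controls",
    "beta", "se", "or", "ci_low", "ci_high", "p", "converged", "separation",
]


def _scan(dosage_matrix, snp_meta, status, covars, maf_min=None):
    status = np.asarray(status, float).ravel()
    if not np.all(np.isin(status[~np.isnan(status)], [0.0, 1.0])):
        raise ValueError("status must be binary 0/1")
    n = status.size
    C = None
    if covars is not None:
        C = np.asarray(covars, float)
        if C.ndim == 1:
            C = C[:, None]
        full = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ValueError("collinear covariate columns in the design")
    rows = []
    n_filtered = 0
    for j in range(dosage_matrix.shape[1]):
        x = np.asarray(dosage_matrix[:, j], float)
        ok = ~np.isnan(x) & ~np.isnan(status)
        if C is not None:
            ok &= ~np.isnan(C).any(axis=1)
        xs, ys = x[ok], status[ok]
        freq = xs.mean() / 2.0 if xs.size else np.nan
        if maf_min is not None:
            maf = min(freq, 1 - freq) if np.isfinite(freq) else 0.0
            if not maf > maf_min:
                n_filtered += 1
                continue
        meta = snp_meta.iloc[j]
        row = {
            "snp_id": meta["snp_id"], "chrom": meta.get("chrom", ""),
            "pos": meta.get("pos", 0), "allele": meta.get("a1", ""),
            "n_used": int(ok.sum()),
            "maf_cases": float(xs[ys == 1].mean() / 2) if (ys == 1).any() else np.nan,
            "maf_controls": float(xs[ys == 0].mean() / 2) if (ys == 0).any() else np.nan,
        }
        design = np.column_stack([np.ones(ok.sum()), xs])
        if C is not None:
            design = np.column_stack([design, C[ok]])
        try:
            if xs.std() == 0:
                raise ValueError("monomorphic dosage column")
            beta, se, conv = _logistic_irls(design, ys)
        except ValueError as e:
            row.update(beta=np.nan, se=np.nan, p=np.nan, converged=False,
                       separation=False, **{"or": np.nan, "ci_low": np.nan,
                                            "ci_high": np.nan})
            rows.append(row)
            continue
        b, s = float(beta[1]), float(se[1])
        separated = abs(b) > SEPARATION_BETA
        p = np.nan if separated else float(2 * stats.norm.sf(abs(b) / s)) if s > 0 else np.nan
        row.update(
            beta=b, se=s, p=p, converged=conv, separation=separated,
            **{"or": float(np.exp(b)), "ci_low": float(np.exp(b - Z95 * s)),
               "ci_high": float(np.exp(b + Z95 * s))},
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS), n_filtered


def logistic_assoc(
    ds: GenotypeDataset | np.ndarray,
    status: Sequence[float],
    covars: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP additive logistic association scan (complete cases per SNP).

    Returns one row per SNP with log-odds, Wald SE, OR with 95% CI, the
    two-sided P-value, and counted-allele frequencies in cases and controls.
    Quasi-separated fits (|beta| > 15) are flagged and their P withheld.
    """
    if isinstance(ds, GenotypeDataset):
        out, _ = _scan(ds.dosages, ds.snps, status, covars)
    else:
        d = np.asarray(ds, float)
        meta = pd.DataFrame({"snp_id": [f"snp{j + 1}" for j in range(d.shape[1])]})
        out, _ = _scan(d, meta, status, covars)
    return out


def hla_dosage_assoc(
    dosages: pd.DataFrame | np.ndarray,
    status: Sequence[float],
    covars: np.ndarray | None = None,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Association scan over imputed allele dosages (real values in [0, 2]).

    Same engine as :func:`logistic_assoc`; alleles with dosage frequency
    implying MAF <= ``maf_min`` are excluded (count reported via warning).
    """
    if isinstance(dosages, pd.DataFrame):
        mat = dosages.to_numpy(float)
        meta = pd.DataFrame({"snp_id": list(dosages.columns)})
    else:
        mat = np.asarray(dosages, float)
        meta = pd.DataFrame({"snp_id": [f"allele{j + 1}" for j in range(mat.shape[1])]})
    if np.nanmin(mat) < 0 or np.nanmax(mat) > 2:
        raise ValueError("allele dosages must lie in [0, 2]")
    out, n_filtered = _scan(mat, meta, status, covars, maf_min=maf_min)
    if n_filtered:
        warnings.warn(f"hla_dosage_assoc: {n_filtered} alleles below MAF filter",
                      stacklevel=2)
    return out


def genomewide_filter(results: pd.DataFrame, alpha: float = 5e-8) -> pd.DataFrame:
    """Rows with P strictly below ``alpha``, sorted ascending by P."""
    hits = results[results["p"] < alpha]
    return hits.sort_values("p", kind="mergesort").reset_index(drop=True)


def replication_check(p: float, beta: float, discovery_beta_sign: float,
                      alpha: float = 0.05) -> bool:
    """Replicated iff P < alpha and the effect direction matches discovery."""
    return bool(p < alpha and np.sign(beta) == np.sign(discovery_beta_sign))


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------

def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Log-odds SE recovered from a printed OR confidence interval."""
    if not (0 < ci_low < ci_high):
        raise ValueError("need 0 < ci_low < ci_high")
    z = float(stats.norm.isf((1 - level) / 2))
    return float((np.log(ci_high) - np.log(ci_low)) / (2 * z))


@dataclass
class MetaResult:
    """Pooled fixed-effect estimate on the log-odds scale."""

    pooled_beta: float
    pooled_se: float
    z: float
    p: float
    weights: np.ndarray  # normalized study weights
    n_studies: int

    @property
    def or_point(self) -> float:
        return float(np.exp(self.pooled_beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.pooled_beta - Z95 * self.pooled_se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.pooled_beta + Z95 * self.pooled_se))

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "or": self.or_point, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "beta": self.pooled_beta,
                "se": self.pooled_se, "z": self.z, "p": self.p,
                "n_studies": self.n_studies,
            }
        )


def fixed_effect_meta(studies: Sequence) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis.

    ``studies`` is a list of :class:`StudySummary` (OR + 95% CI, SEs
    recovered from the interval) or of ``(beta, se)`` pairs on the log-odds
    scale.
    """
    if len(studies) < 2:
        raise ValueError("meta-analysis needs at least two studies")
    betas, ses = [], []
    for s in studies:
        if isinstance(s, StudySummary):
            betas.append(np.log(s.or_point))
            ses.append(se_from_ci(s.ci_low, s.ci_high))
        else:
            b, se = s
            betas.append(float(b))
            ses.append(float(se))
    betas = np.asarray(betas)
    ses = np.asarray(ses)
    if np.any(ses <= 0):
        raise ValueError("study standard errors must be positive")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaResult(pooled, pooled_se, float(z), p, w / w.sum(), len(studies))
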