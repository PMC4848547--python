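"""Phenome-wide screening: phenotype derivation, per-phenotype GREML,
Benjamini-Hochberg FDR, HLA variance partitioning, MHC class localization,
enrichment tallies and batch genetic correlations.

Each phenotype gets its own matched case-control cohort (all cases plus
frequency-matched controls at a configurable ratio), a single-GRM REML fit
with a likelihood-ratio test against the no-GRM null, and optionally a
two-GRM HLA/rest partition and a four-GRM MHC-class model.  Per-phenotype
failures are recorded, never allowed to abort the batch.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bivariate import BivariateVarianceModel, rg_lrt_p
from .data import GenotypeDataset
from .grm import Grm
from .reml import VarianceComponentsModel, lrt_p, null_restricted_logl

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Phenotype derivation from code events
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeDefinition:
    """A clinical phenotype as a collection of billing-code ids."""

    phenotype_id: str
    codes: set[str]
    label: str = ""
    min_cases: int = 50

    def __post_init__(self) -> None:
        self.codes = set(map(str, self.codes))
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")


def derive_case_status(
    code_events: pd.DataFrame,
    defn: PhenotypeDefinition,
    all_samples: Iterable[str],
) -> pd.Series:
    """Classify each sample as case / control-eligible / excluded.

    Case: two or more constituent-code events on at least two distinct
    dates.  Control-eligible: no events of any constituent code.  A single
    event (or repeats on one date) excludes the sample from both groups.
    """
    ev = code_events[code_events["code"].astype(str).isin(defn.codes)]
    dates = pd.to_datetime(ev["date"])
    distinct = (
        pd.DataFrame({"sample": ev["sample_id"].astype(str), "date": dates})
        .drop_duplicates()
        .groupby("sample")
        .size()
    )
    out = {}
    for sid in map(str, all_samples):
        k = int(distinct.get(sid, 0)) if sid in distinct.index else 0
        if k >= 2:
            out[sid] = "case"
        elif sid in set(ev["sample_id"].astype(str)):
            out[sid] = "excluded"
        else:
            out[sid] = "control-eligible"
    return pd.Series(out, name=defn.phenotype_id)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Screen configuration and cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class ScreenConfig:
    min_cases: int = 50
    control_ratio: int = 2
    covariates: tuple[str, ...] = ("age", "sex")
    n_pcs: int = 0
    fdr_threshold: float = 0.05
    rg_fdr_threshold: float = 0.1
    seed: int = 0
    max_iter: int = 100
    tol: float = 1e-8


def _pheno_rng(master_seed: int, phenotype_id: str) -> np.random.Generator:
    sub = zlib.crc32(phenotype_id.encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed, sub]))


def _design(samples: pd.DataFrame, ids: list[str], covariates, pcs=None, n_pcs=0):
    meta = samples.set_index("sample_id").loc[ids]
    cols = []
    for c in covariates:
        if c == "sex":
            cols.append((meta["sex"] == "male").astype(float).to_numpy())
        else:
            cols.append(meta[c].astype(float).to_numpy())
    if n_pcs and pcs is not None:
        pcmat = pcs.loc[ids].to_numpy()[:, :n_pcs]
        cols.extend(pcmat.T)
    return np.column_stack(cols) if cols else None


def assemble_cohort(
    status: pd.Series,
    samples: pd.DataFrame,
    config: ScreenConfig,
    phenotype_id: str,
) -> tuple[list[str], np.ndarray]:
    """All cases plus frequency-matched controls; returns (ids, y)."""
    from .simulate import sample_matched_controls

    cases = sorted(status.index[status == "case"].astype(str))
    pool = sorted(status.index[status == "control-eligible"].astype(str))
    rng = _pheno_rng(config.seed, phenotype_id)
    controls = sample_matched_controls(
        cases, pool, samples, ratio=config.control_ratio, seed=rng
    )
    ids = cases + controls
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
    return ids, y


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------

SCREEN_COLUMNS = [
    "phenotype_id", "n_cases", "n_controls", "h2_obs", "h2_obs_se",
    "h2_liab", "h2_liab_se", "logl_full", "logl_null", "lrt_p", "q_value",
    "converged", "skipped", "reason",
]


def run_screen(
    statuses: Mapping[str, pd.Series],
    ds: GenotypeDataset,
    grm: Grm,
    config: ScreenConfig | None = None,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Single-GRM liability screen over a collection of phenotypes.

    ``statuses`` maps phenotype id to a per-sample series with values
    case / control-eligible / excluded (as from :func:`derive_case_status`).
    Returns one row per phenotype with estimates on both scales, the LRT
    P-value against the no-GRM null and BH q-values across phenotypes.
    """
    config = config or ScreenConfig()
    rows = []
    for pid in statuses:
        status = statuses[pid]
        n_cases = int((status == "case").sum())
        row = {c: np.nan for c in SCREEN_COLUMNS}
        row.update(phenotype_id=pid, n_cases=n_cases, skipped=False, reason="")
        if n_cases < config.min_cases:
            row.update(skipped=True, reason=f"fewer than {config.min_cases} cases")
            rows.append(row)
            continue
        try:
            ids, y = assemble_cohort(status, ds.samples, config, pid)
            X = _design(ds.samples, ids, config.covariates, pcs, config.n_pcs)
            sub_grm = grm.subset(ids)
            model = VarianceComponentsModel(y, X, [sub_grm])
            res = model.fit(tol=config.tol, max_iter=config.max_iter)
            logl_null = null_restricted_logl(model.y, model.X)
            h2l, h2l_se = res.h2_liability()
            row.update(
                n_controls=int(len(ids) - n_cases),
                h2_obs=res.h2_obs(0),
                h2_obs_se=res.h2_obs_se(0),
                h2_liab=h2l,
                h2_liab_se=h2l_se,
                logl_full=res.llf,
                logl_null=logl_null,
                lrt_p=lrt_p(res.llf, logl_null),
                converged=res.converged,
            )
        except Exception as e:  # never abort the batch
            logger.warning("phenotype %s failed: %s", pid, e)
            row.update(skipped=True, reason=f"fit failed: {e}")
        rows.append(row)
    out = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    ok = ~out["skipped"] & out["lrt_p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(out.loc[ok, "lrt_p"].to_numpy())
    out["q_value"] = q
    return out


def hla_partition_screen(
    results: pd.DataFrame,
    statuses: Mapping[str, pd.Series],
    ds: GenotypeDataset,
    hla_grm: Grm,
    rest_grm: Grm,
    config: ScreenConfig | None = None,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-GRM HLA/rest partition for each screened phenotype.

    Adds per-phenotype HLA and rest variance shares, the LRT P-value from
    dropping the HLA GRM (full two-GRM model vs rest-only model, refit), BH
    q-values across phenotypes, and a flag at q < ``fdr_threshold``.
    """
    config = config or ScreenConfig()
    out = results.copy()
    for col in ("h2_hla", "h2_hla_se", "h2_rest", "h2_rest_se", "hla_lrt_p"):
        out[col] = np.nan
    for i, prow in out.iterrows():
        if prow["skipped"]:
            continue
        pid = prow["phenotype_id"]
        try:
            ids, y = assemble_cohort(statuses[pid], ds.samples, config, pid)
            X = _design(ds.samples, ids, config.covariates, pcs, config.n_pcs)
            full = VarianceComponentsModel(
                y, X, [hla_grm.subset(ids), rest_grm.subset(ids)],
                names=["V(HLA)", "V(rest)"],
            ).fit(tol=config.tol, max_iter=config.max_iter)
            reduced = VarianceComponentsModel(y, X, [rest_grm.subset(ids)]).fit(
                tol=config.tol, max_iter=config.max_iter
            )
            out.loc[i, "h2_hla"] = full.h2_obs(0)
            out.loc[i, "h2_hla_se"] = full.h2_obs_se(0)
            out.loc[i, "h2_rest"] = full.h2_obs(1)
            out.loc[i, "h2_rest_se"] = full.h2_obs_se(1)
            out.loc[i, "hla_lrt_p"] = lrt_p(full.llf, reduced.llf)
        except Exception as e:
            logger.warning("HLA partition failed for %s: %s", pid, e)
            out.loc[i, "reason"] = f"partition failed: {e}"
    ok = out["hla_lrt_p"].notna()
    out["hla_q"] = np.nan
    if ok.any():
        out.loc[ok, "hla_q"] = bh_fdr(out.loc[ok, "hla_lrt_p"].to_numpy())
    out["hla_flag"] = out["hla_q"] < config.fdr_threshold
    return out


def class_localization(
    phenotype_ids: Sequence[str],
    statuses: Mapping[str, pd.Series],
    ds: GenotypeDataset,
    class_grms: Mapping[str, Grm],
    config: ScreenConfig | None = None,
    pcs: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Four-GRM MHC class model with per-class Wald component tests.

    ``class_grms`` must provide GRMs for ``classI``, ``classII``,
    ``otherHLA`` and ``rest`` built from disjoint SNP sets.  A class is
    flagged when its Wald P < ``alpha``; non-convergence leaves the class
    P-values unavailable (NaN).
    """
    config = config or ScreenConfig()
    required = ("classI", "classII", "otherHLA", "rest")
    for key in required:
        if key not in class_grms:
            raise ValueError(f"class GRM '{key}' missing")
        if class_grms[key] is None or class_grms[key].n_snps == 0:
            raise ValueError(f"class GRM '{key}' built from an empty SNP set")
    rows = []
    for pid in phenotype_ids:
        row = {"phenotype_id": pid}
        try:
            ids, y = assemble_cohort(statuses[pid], ds.samples, config, pid)
            X = _design(ds.samples, ids, config.covariates, pcs, config.n_pcs)
            grms = [class_grms[k].subset(ids) for k in required]
            res = VarianceComponentsModel(
                y, X, grms, names=[f"V({k})" for k in required]
            ).fit(tol=config.tol, max_iter=config.max_iter)
            row["converged"] = res.converged
            for j, key in enumerate(required[:3]):
                if res.converged and res.vc_se[j] > 0:
                    p = res.wald_p(j)
                else:
                    p = np.nan
                row[f"{key}_p"] = p
                row[f"{key}_flag"] = bool(p < alpha) if np.isfinite(p) else False
                row[f"{key}_h2"] = res.h2_obs(j)
        except Exception as e:
            logger.warning("class localization failed for %s: %s", pid, e)
            row["converged"] = False
            for key in required[:3]:
                row[f"{key}_p"] = np.nan
                row[f"{key}_flag"] = False
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Enrichment tally
# ---------------------------------------------------------------------------

def enrichment_tally(
    results: pd.DataFrame,
    labels: Mapping[str, str],
    p_bins: Sequence[float],
    p_column: str = "lrt_p",
) -> pd.DataFrame:
    """Count positively labelled phenotypes per P-value bin.

    ``p_bins`` gives bin edges (ascending); phenotypes with P in
    ``[edge_i, edge_{i+1})`` land in bin i.  Unlabelled phenotypes count as
    "other".  Returns per-bin (n_positive, n_total).
    """
    edges = list(p_bins)
    sub = results[results[p_column].notna()]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = sub[(sub[p_column] >= lo) & (sub[p_column] < hi)]
        pos = sum(
            1 for pid in in_bin["phenotype_id"]
            if labels.get(pid, "other") == "autoimmune"
        )
        rows.append({"bin_low": lo, "bin_high": hi,
                     "n_positive": pos, "n_total": len(in_bin)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Batch genetic correlations
# ---------------------------------------------------------------------------

def rg_batch(
    pairs: Sequence[tuple[str, str]],
    statuses: Mapping[str, pd.Series],
    ds: GenotypeDataset,
    grm: Grm,
    config: ScreenConfig | None = None,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bivariate REML genetic correlation for each phenotype pair.

    Each trait keeps its own matched cohort; overlap between the cohorts is
    handled through a residual covariance component.  Rows with an undefined
    rG (non-positive genetic variance) are flagged and excluded from the BH
    adjustment; the flag column marks pairs with q < ``rg_fdr_threshold``.
    """
    config = config or ScreenConfig()
    rows = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-pair ({a}, {a}) is not a valid input")
        row = {"pheno1": a, "pheno2": b, "rg": np.nan, "rg_se": np.nan,
               "p": np.nan, "defined": False, "converged": False}
        try:
            ids1, y1 = assemble_cohort(statuses[a], ds.samples, config, a)
            ids2, y2 = assemble_cohort(statuses[b], ds.samples, config, b)
            X1 = _design(ds.samples, ids1, config.covariates, pcs, config.n_pcs)
            X2 = _design(ds.samples, ids2, config.covariates, pcs, config.n_pcs)
            model = BivariateVarianceModel(y1, y2, X1, X2, grm, ids1, ids2)
            free = model.fit(tol=config.tol, max_iter=config.max_iter)
            con = model.fit(constrain_rg_zero=True, tol=config.tol,
                            max_iter=config.max_iter)
            row["converged"] = free.converged and con.converged
            if free.rg_defined:
                row.update(defined=True, rg=free.rg, rg_se=free.rg_se,
                           p=rg_lrt_p(free, con))
            else:
                logger.warning("pair (%s, %s): rG undefined (vG <= 0)", a, b)
        except Exception as e:
            logger.warning("pair (%s, %s) failed: %s", a, b, e)
        rows.append(row)
    out = pd.DataFrame(rows)
    ok = out["defined"] & out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["flag"] = out["q"] < config.rg_fdr_threshold
    return out
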