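"""Synthetic genotypes and liability-threshold case-control phenotypes.

The generator emulates the statistical structure the screening pipeline
assumes: common SNPs (ancestral MAF uniform on a configurable range,
Balding-Nichols subpopulation differentiation when requested), a dense
"HLA" SNP block on chromosome 6 (by default 6.3% of SNPs inside
chr6:26-34 Mb, matching the density of HLA SNPs on an exome array),
binary phenotypes produced by thresholding a unit-variance liability
(genetic + environmental), and birth-decade/sex frequency-matched
control sampling at a 2:1 control:case ratio.

All randomness flows from a single master seed fanned out into named
substreams, so each stage is independently reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeDataset, RegionSet, make_sample_table
from .grm import snps_in_regions

logger = logging.getLogger(__name__)

HLA_WINDOW = ("6", 26_000_000, 34_000_000)


def default_hla_regions() -> RegionSet:
    """The HLA screening window plus synthetic MHC class sub-windows.

    The class windows are stand-ins sized so that class I / class II /
    other-HLA SNP counts fall in roughly the proportions seen on a real
    exome array (a few percent each, the bulk in "other").
    """
    return RegionSet.from_records(
        [
            ("6", 26_000_000, 34_000_000, "HLA"),
            ("6", 29_600_000, 30_200_000, "MHC_classI"),
            ("6", 32_400_000, 33_100_000, "MHC_classII"),
        ]
    )


def substreams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Named independent random substreams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n: int,
    m: int,
    maf_low: float = 0.01,
    maf_high: float = 0.5,
    n_subpops: int = 1,
    fst: float = 0.0,
    seed: int = 0,
    hla_fraction: float = 0.063,
) -> GenotypeDataset:
    """Simulate unlinked genotypes with an HLA block and sample metadata.

    Ancestral allele frequencies are uniform on [maf_low, maf_high]; with
    ``n_subpops > 1`` subpopulation frequencies are drawn from the
    Balding-Nichols beta model with differentiation ``fst`` and samples are
    assigned to subpopulations in round-robin order.  The first
    ``round(hla_fraction * m)`` SNPs are placed evenly across the HLA window
    on chromosome 6; the rest round-robin across the other autosomes.
    """
    if n <= 0 or m <= 0:
        raise ValueError("n and m must be positive")
    if not (0.01 <= maf_low <= maf_high <= 0.5):
        raise ValueError("need 0.01 <= maf_low <= maf_high <= 0.5")
    if not (0.0 <= fst <= 0.2):
        raise ValueError("fst must lie in [0, 0.2]")

    rngs = substreams(seed, "freqs", "genotypes", "metadata")
    p_anc = rngs["freqs"].uniform(maf_low, maf_high, size=m)

    subpop = np.arange(n) % max(n_subpops, 1)
    if n_subpops > 1 and fst > 0:
        a = p_anc * (1 - fst) / fst
        b = (1 - p_anc) * (1 - fst) / fst
        p_sub = rngs["freqs"].beta(a[None, :], b[None, :], size=(n_subpops, m))
    else:
        p_sub = np.tile(p_anc, (max(n_subpops, 1), 1))
    dosages = rngs["genotypes"].binomial(2, p_sub[subpop, :]).astype(np.float32)

    # SNP map: leading block inside the HLA window, remainder elsewhere
    n_hla = int(round(hla_fraction * m))
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    c6, start, end = HLA_WINDOW
    if n_hla:
        chrom[:n_hla] = c6
        pos[:n_hla] = start + ((np.arange(n_hla) + 0.5) * (end - start) / n_hla).astype(
            np.int64
        )
    other_chroms = [str(c) for c in range(1, 23) if c != 6]
    n_rest = m - n_hla
    for j in range(n_rest):
        chrom[n_hla + j] = other_chroms[j % len(other_chroms)]
        pos[n_hla + j] = 1_000_000 + 5_000 * (j // len(other_chroms) + 1)

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:06d}" for j in range(m)],
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pos,
            "a1": "A",
            "a2": "B",
        }
    )

    md = rngs["metadata"]
    sex = np.where(md.random(n) < 0.5, "female", "male")
    decade = md.choice(np.arange(1930, 2000, 10), size=n)
    age = 2010 - decade - md.integers(0, 10, size=n)
    samples = make_sample_table([f"s{i + 1:05d}" for i in range(n)], sex, decade, age)
    samples["subpop"] = subpop
    return GenotypeDataset(samples, snps, dosages)


# ---------------------------------------------------------------------------
# Liability phenotypes
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Per-region genetic architecture of a liability-threshold phenotype.

    ``region_shares`` maps a region label to ``(h2_share, n_causal)``; the
    label is resolved against a :class:`RegionSet` (``"all"`` means every
    SNP, ``"rest"`` means SNPs outside every listed region).  Shares sum to
    the total liability-scale heritability; ``prevalence`` is the population
    prevalence K defining the liability threshold.
    """

    region_shares: dict[str, tuple[float, int]]
    prevalence: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence K must lie in (0, 1)")
        if self.total_h2 >= 1 or self.total_h2 < 0:
            raise ValueError("total h2 must lie in [0, 1)")

    @property
    def total_h2(self) -> float:
        return float(sum(s for s, _ in self.region_shares.values()))


@dataclass
class TruthRecord:
    """Ground truth of one simulated phenotype for recovery tests."""

    h2_nominal: dict[str, float]
    h2_realized: dict[str, float]
    causal_effects: dict[str, float]
    threshold: float
    prevalence: float
    seed: int
    case_fraction: float
    true_rg: float | None = None

    @property
    def total_h2_realized(self) -> float:
        return float(sum(self.h2_realized.values()))


def _resolve_region_snps(ds: GenotypeDataset, label: str, regions: RegionSet) -> list[str]:
    if label == "all":
        return list(ds.snp_ids)
    in_any = set(snps_in_regions(ds.snps, regions))
    if label == "rest":
        return [s for s in ds.snp_ids if s not in in_any]
    if label not in set(regions.regions["label"]):
        raise ValueError(f"unknown region label '{label}'")
    return snps_in_regions(ds.snps, regions.select([label]))


def _standardized(
    ds: GenotypeDataset, snp_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    sub = ds.take_snps(snp_ids)
    p = sub.allele_freqs()
    ok = (p > 0) & (p < 1)
    if not ok.all():
        sub = sub.take_snps(sub.snp_ids[ok])
        p = p[ok]
    d = sub.dosages.astype(np.float64)
    d = np.where(np.isnan(d), 2 * p, d)
    return (d - 2 * p) / np.sqrt(2 * p * (1 - p)), list(sub.snp_ids)


def simulate_liability_phenotype(
    ds: GenotypeDataset,
    arch: ArchitectureSpec,
    seed: int = 0,
    regions: RegionSet | None = None,
) -> tuple[np.ndarray, TruthRecord]:
    """Draw a 0/1 phenotype from the liability-threshold model.

    Causal effects act on standardized genotypes with per-region variance
    ``h2_share / n_causal``, the environmental term has variance
    ``1 - total_h2``, and a sample is a case iff its liability exceeds the
    threshold Phi^-1(1 - K).
    """
    regions = regions if regions is not None else default_hla_regions()
    rngs = substreams(seed, "effects", "environment")
    n = ds.n_samples
    genetic = np.zeros(n)
    h2_nominal: dict[str, float] = {}
    h2_realized: dict[str, float] = {}
    effects: dict[str, float] = {}
    for label, (share, n_causal) in arch.region_shares.items():
        pool = _resolve_region_snps(ds, label, regions)
        if len(pool) < n_causal:
            raise ValueError(
                f"region '{label}' has {len(pool)} SNPs but {n_causal} causal requested"
            )
        causal = list(rngs["effects"].choice(pool, size=n_causal, replace=False))
        W, kept = _standardized(ds, causal)
        beta = rngs["effects"].normal(0.0, np.sqrt(share / n_causal), size=len(kept))
        g = W @ beta
        genetic += g
        h2_nominal[label] = share
        h2_realized[label] = float(np.var(g, ddof=1)) if n > 1 else share
        effects.update(dict(zip(kept, beta)))

    env = rngs["environment"].normal(0.0, np.sqrt(max(1.0 - arch.total_h2, 0.0)), size=n)
    liability = genetic + env
    threshold = float(stats.norm.isf(arch.prevalence))
    status = (liability > threshold).astype(np.int8)
    truth = TruthRecord(
        h2_nominal=h2_nominal,
        h2_realized=h2_realized,
        causal_effects=effects,
        threshold=threshold,
        prevalence=arch.prevalence,
        seed=seed,
        case_fraction=float(status.mean()),
    )
    return status, truth


def simulate_bivariate(
    ds: GenotypeDataset,
    arch1: ArchitectureSpec,
    arch2: ArchitectureSpec,
    rho_effects: float,
    seed: int = 0,
    regions: RegionSet | None = None,
) -> tuple[np.ndarray, np.ndarray, TruthRecord]:
    """Two liability phenotypes with shared causal SNPs and correlated effects.

    Both architectures must name the same regions with the same causal
    counts; per-SNP effect pairs are bivariate normal with correlation
    ``rho_effects`` (the true genetic correlation).
    """
    if abs(rho_effects) > 1:
        raise ValueError("|rho_effects| must be <= 1")
    if (set(arch1.region_shares) != set(arch2.region_shares)
            or any(arch1.region_shares[k][1] != arch2.region_shares[k][1]
                   for k in arch1.region_shares)):
        raise ValueError(
            "bivariate simulation requires matching regions and causal counts "
            "(shared causal SNPs with correlated effects)"
        )
    regions = regions if regions is not None else default_hla_regions()
    rngs = substreams(seed, "effects", "environment1", "environment2")
    n = ds.n_samples
    g1 = np.zeros(n)
    g2 = np.zeros(n)
    effects: dict[str, float] = {}
    for label in arch1.region_shares:
        share1, n_causal = arch1.region_shares[label]
        share2, _ = arch2.region_shares[label]
        pool = _resolve_region_snps(ds, label, regions)
        if len(pool) < n_causal:
            raise ValueError(f"region '{label}' too small for {n_causal} causal SNPs")
        causal = list(rngs["effects"].choice(pool, size=n_causal, replace=False))
        W, kept = _standardized(ds, causal)
        v1, v2 = share1 / n_causal, share2 / n_causal
        cov = rho_effects * np.sqrt(v1 * v2)
        betas = rngs["effects"].multivariate_normal(
            [0.0, 0.0], [[v1, cov], [cov, v2]], size=len(kept)
        )
        g1 += W @ betas[:, 0]
        g2 += W @ betas[:, 1]
        effects.update(dict(zip(kept, betas[:, 0])))

    e1 = rngs["environment1"].normal(0, np.sqrt(max(1 - arch1.total_h2, 0)), size=n)
    e2 = rngs["environment2"].normal(0, np.sqrt(max(1 - arch2.total_h2, 0)), size=n)
    t1 = float(stats.norm.isf(arch1.prevalence))
    t2 = float(stats.norm.isf(arch2.prevalence))
    s1 = (g1 + e1 > t1).astype(np.int8)
    s2 = (g2 + e2 > t2).astype(np.int8)
    truth = TruthRecord(
        h2_nominal={k: v[0] for k, v in arch1.region_shares.items()},
        h2_realized={"trait1": float(np.var(g1, ddof=1)), "trait2": float(np.var(g2, ddof=1))},
        causal_effects=effects,
        threshold=t1,
        prevalence=arch1.prevalence,
        seed=seed,
        case_fraction=float(s1.mean()),
        true_rg=rho_effects,
    )
    return s1, s2, truth


# ---------------------------------------------------------------------------
# Matched control sampling
# ---------------------------------------------------------------------------

def sample_matched_controls(
    cases: set[str] | list[str],
    pool: set[str] | list[str],
    samples: pd.DataFrame,
    ratio: int = 2,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Birth-decade- and sex-frequency-matched control sampling.

    Controls are drawn per (sex, birth_decade) stratum in proportion to the
    case distribution, targeting ``ratio`` controls per case.  When a
    stratum's pool is exhausted, the deficit is drawn from the nearest
    birth-decade stratum of the same sex (logged).
    """
    cases = sorted(set(map(str, cases)))
    pool = sorted(set(map(str, pool)))
    if not pool:
        raise ValueError("empty control pool")
    if set(cases) & set(pool):
        raise ValueError("control pool overlaps cases")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    meta = samples.set_index("sample_id")
    strata_of = lambda sid: (str(meta.at[sid, "sex"]), float(meta.at[sid, "birth_decade"]))
    case_cells: dict[tuple, int] = {}
    for sid in cases:
        case_cells[strata_of(sid)] = case_cells.get(strata_of(sid), 0) + 1
    pool_cells: dict[tuple, list[str]] = {}
    for sid in pool:
        pool_cells.setdefault(strata_of(sid), []).append(sid)

    chosen: list[str] = []
    for cell in sorted(case_cells):
        sex, decade = cell
        want = ratio * case_cells[cell]
        avail = pool_cells.get(cell, [])
        take = min(want, len(avail))
        picked = list(rng.choice(avail, size=take, replace=False)) if take else []
        chosen.extend(picked)
        pool_cells[cell] = [s for s in avail if s not in set(picked)]
        deficit = want - take
        if deficit > 0:
            # borrow from nearest birth decades of the same sex
            others = sorted(
                (c for c in pool_cells if c[0] == sex and c != cell and pool_cells[c]),
                key=lambda c: (abs(c[1] - decade), c[1]),
            )
            for other in others:
                if deficit == 0:
                    break
                avail = pool_cells[other]
                take = min(deficit, len(avail))
                picked = list(rng.choice(avail, size=take, replace=False))
                chosen.extend(picked)
                pool_cells[other] = [s for s in avail if s not in set(picked)]
                deficit -= take
                logger.info(
                    "stratum (%s, %s): borrowed %d controls from decade %s",
                    sex, decade, take, other[1],
                )
            if deficit > 0:
                warnings.warn(
                    f"stratum ({sex}, {decade:g}): short {deficit} controls",
                    stacklevel=2,
                )
    return sorted(chosen)
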