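"""SNP QC, genetic relationship matrices, relatedness pruning, region and
LD-based SNP subsetting, and principal components.

The GRM is the standard realized-relationship estimator on standardized
dosages,

    A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

with p_i the sample frequency of the counted allele.  Missing genotypes
contribute zero to the numerator and the per-pair denominator m is reduced
to the number of SNPs non-missing in both samples.  The diagonal uses the
same formula as the off-diagonals (no inbreeding adjustment; under HWE the
two agree in expectation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import lgamma
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import GenotypeDataset, IntegrityError, RegionSet


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact Hardy-Weinberg P-value (two-sided, Wigginton-style, no mid-P).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.
    """
    n = n_hom_a1 + n_het + n_hom_a2
    if n == 0:
        return 1.0
    n_a = 2 * n_hom_a1 + n_het  # copies of allele 1
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a shared constant
    logp = np.array(
        [
            h * np.log(2.0)
            - lgamma((n_a - h) // 2 + 1)
            - lgamma(h + 1)
            - lgamma((n_b - h) // 2 + 1)
            for h in hets
        ]
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = n_het
    if obs not in hets:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = p[np.searchsorted(hets, obs)]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# SNP QC
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    n_input: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int


def snp_qc(
    ds: GenotypeDataset,
    maf_min: float = 0.01,
    hwe_p_min: float = 0.001,
    return_report: bool = False,
):
    """Retain SNPs with sample MAF > ``maf_min`` and HWE exact P > ``hwe_p_min``.

    The HWE test uses hard-call genotype counts (fractional dosages are
    rounded for counting).  Removal counts are attributed to the first
    failing filter (MAF, then HWE).
    """
    if ds.n_snps == 0:
        raise ValueError("empty dataset")
    freqs = ds.allele_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    pass_maf = maf > maf_min

    pass_hwe = np.ones(ds.n_snps, dtype=bool)
    d = ds.dosages
    for j in np.nonzero(pass_maf)[0]:
        col = d[:, j]
        col = col[~np.isnan(col)]
        g = np.rint(col).astype(int)
        counts = np.bincount(g, minlength=3)
        pass_hwe[j] = hwe_exact_p(counts[2], counts[1], counts[0]) > hwe_p_min

    keep = pass_maf & pass_hwe
    report = QcReport(
        n_input=ds.n_snps,
        n_removed_maf=int((~pass_maf).sum()),
        n_removed_hwe=int((pass_maf & ~pass_hwe).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        warnings.warn("snp_qc removed every SNP", stacklevel=2)
    out = ds.take_snps(ds.snp_ids[keep])
    return (out, report) if return_report else out


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

@dataclass
class Grm:
    """Realized genetic relationship matrix with sample ids."""

    sample_ids: np.ndarray
    values: np.ndarray
    n_snps: int
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise IntegrityError("GRM shape does not match sample ids")
        if not np.isfinite(self.values).all():
            raise IntegrityError("GRM contains non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise IntegrityError("GRM not symmetric")
        if self.n_snps <= 0:
            raise IntegrityError("n_snps must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, ids: Iterable[str]) -> "Grm":
        ids = list(ids)
        lookup = pd.Index(self.sample_ids)
        idx = lookup.get_indexer(ids)
        if (idx < 0).any():
            raise IntegrityError("subset ids not all present in GRM")
        return Grm(np.asarray(ids), self.values[np.ix_(idx, idx)], self.n_snps)

    def eig(self):
        """Cached eigendecomposition (ascending eigenvalues)."""
        if self._eig is None:
            w, u = np.linalg.eigh(self.values)
            self._eig = (w, u)
        return self._eig

    # -- GCTA-compatible binary triplet ------------------------------------
    def write_gcta(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        n = self.n_samples
        il = np.tril_indices(n)
        self.values[il].astype("<f4").tofile(str(prefix) + ".grm.bin")
        np.full(il[0].shape, self.n_snps, dtype="<f4").tofile(
            str(prefix) + ".grm.N.bin"
        )
        with open(str(prefix) + ".grm.id", "w") as fh:
            for sid in self.sample_ids:
                fh.write(f"{sid}\t{sid}\n")

    @classmethod
    def read_gcta(cls, prefix: str | Path) -> "Grm":
        prefix = str(Path(prefix))
        ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None, dtype=str)
        n = len(ids)
        tri = np.fromfile(prefix + ".grm.bin", dtype="<f4").astype(np.float64)
        if tri.size != n * (n + 1) // 2:
            raise IntegrityError("grm.bin size inconsistent with grm.id")
        nsnp = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
        vals = np.zeros((n, n))
        il = np.tril_indices(n)
        vals[il] = tri
        vals = vals + np.tril(vals, -1).T
        return cls(ids[1].to_numpy(), vals, int(round(float(nsnp[0]))))

    def write_text(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"#n_snps {self.n_snps}\n")
            fh.write("sample_id " + " ".join(self.sample_ids) + "\n")
            for i, sid in enumerate(self.sample_ids):
                fh.write(sid + " " + " ".join(format(v, ".10g") for v in self.values[i]) + "\n")

    @classmethod
    def read_text(cls, path: str | Path) -> "Grm":
        with Path(path).open() as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        n_snps = int(lines[0].split()[1])
        ids = lines[1].split()[1:]
        vals = np.array([[float(v) for v in ln.split()[1:]] for ln in lines[2:]])
        vals = (vals + vals.T) / 2.0  # text round-trip symmetrization
        return cls(np.asarray(ids), vals, n_snps)


def compute_grm(
    ds: GenotypeDataset, snp_ids: Sequence[str] | None = None
) -> Grm:
    """GRM from the standardized-dosage estimator over ``snp_ids`` (default all).

    Monomorphic SNPs (p in {0, 1}) are excluded with a warning.
    """
    sub = ds if snp_ids is None else ds.take_snps(snp_ids)
    if sub.n_snps == 0:
        raise ValueError("no SNPs selected for GRM")
    p = sub.allele_freqs()
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    if not poly.all():
        warnings.warn(
            f"compute_grm: excluding {int((~poly).sum())} monomorphic SNPs",
            stacklevel=2,
        )
        sub = sub.take_snps(sub.snp_ids[poly])
        p = p[poly]
    m = sub.n_snps
    if m == 0:
        raise ValueError("no polymorphic SNPs for GRM")
    d = sub.dosages.astype(np.float64)
    miss = np.isnan(d)
    W = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    W[miss] = 0.0
    num = W @ W.T
    if miss.any():
        obs = (~miss).astype(np.float64)
        pair_m = obs @ obs.T
        pair_m[pair_m == 0] = np.nan
        vals = num / pair_m
        if np.isnan(vals).any():
            raise IntegrityError("sample pair with no jointly observed SNPs")
    else:
        vals = num / m
    vals = (vals + vals.T) / 2.0
    return Grm(sub.sample_ids.copy(), vals, m)


def merge_grms(grms: Sequence[Grm]) -> Grm:
    """SNP-count-weighted average of GRMs computed on disjoint SNP subsets.

    Equals the GRM on the union subset when there is no missingness and all
    parts used the same samples/frequencies.
    """
    ids = grms[0].sample_ids
    for g in grms[1:]:
        if not np.array_equal(g.sample_ids, ids):
            raise IntegrityError("GRMs to merge must share sample ids/order")
    total = sum(g.n_snps for g in grms)
    vals = sum(g.values * g.n_snps for g in grms) / total
    return Grm(ids.copy(), vals, total)


# ---------------------------------------------------------------------------
# Relatedness pruning
# ---------------------------------------------------------------------------

def prune_related(
    grm: Grm,
    cutoff: float = 0.07,
    missing_rates: Sequence[float] | None = None,
) -> list[str]:
    """Greedily drop samples until no retained off-diagonal exceeds ``cutoff``.

    At each step the sample in the most over-cutoff pairs is removed; ties are
    broken by higher genotype missingness, then by removing the
    lexicographically larger id.  Returns retained sample ids in input order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = grm.n_samples
    miss = np.zeros(n) if missing_rates is None else np.asarray(missing_rates, float)
    adj = np.abs(grm.values) > cutoff
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    ids = grm.sample_ids
    while True:
        deg = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max(initial=0) == 0:
            break
        top = deg == deg.max()
        cand = np.nonzero(top)[0]
        worst_miss = miss[cand].max()
        cand = cand[miss[cand] == worst_miss]
        victim = cand[np.argmax(ids[cand])]  # lexicographically larger id removed
        alive[victim] = False
    return [ids[i] for i in range(n) if alive[i]]


# ---------------------------------------------------------------------------
# Region and LD subsetting
# ---------------------------------------------------------------------------

def snps_in_regions(
    snps: pd.DataFrame, regions: RegionSet, flank: int = 0
) -> list[str]:
    """SNP ids with position in ``[start - flank, end + flank]`` of any region
    on the matching chromosome (1-based inclusive)."""
    hits = np.zeros(len(snps), dtype=bool)
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    for r in regions.regions.itertuples(index=False):
        hits |= (chrom == r.chrom) & (pos >= r.start - flank) & (pos <= r.end + flank)
    return list(snps["snp_id"].to_numpy()[hits])


def ld_r2(ds: GenotypeDataset, snp_a: str, snp_b: str) -> float:
    """Composite-genotype r^2: squared Pearson correlation of dosage vectors
    over samples non-missing at both SNPs."""
    lookup = pd.Index(ds.snps["snp_id"])
    ja, jb = lookup.get_loc(snp_a), lookup.get_loc(snp_b)
    a, b = ds.dosages[:, ja], ds.dosages[:, jb]
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok].astype(float), b[ok].astype(float)
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        raise ValueError(
            f"zero dosage variance for ({snp_a}, {snp_b}) after missingness intersection"
        )
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def exclude_catalog_linked(
    ds: GenotypeDataset,
    catalog_snp_ids: Iterable[str],
    r2_thresh: float = 0.2,
) -> set[str]:
    """Catalog SNPs plus same-chromosome SNPs with r^2 > ``r2_thresh`` to any
    of them.  Catalog ids absent from the dataset are logged and skipped."""
    present = set(ds.snp_ids)
    catalog = [s for s in catalog_snp_ids if s in present]
    skipped = [s for s in catalog_snp_ids if s not in present]
    if skipped:
        warnings.warn(
            f"exclude_catalog_linked: {len(skipped)} catalog ids absent, skipped",
            stacklevel=2,
        )
    excluded = set(catalog)
    snp_chrom = dict(zip(ds.snps["snp_id"], ds.snps["chrom"]))
    by_chrom: dict[str, list[str]] = {}
    for s in catalog:
        by_chrom.setdefault(snp_chrom[s], []).append(s)
    for other in ds.snp_ids:
        if other in excluded:
            continue
        for cat in by_chrom.get(snp_chrom[other], []):
            try:
                if ld_r2(ds, other, cat) > r2_thresh:
                    excluded.add(other)
                    break
            except ValueError:
                continue
    return excluded


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

@dataclass
class PcSet:
    sample_ids: np.ndarray
    components: np.ndarray  # n x k, orthonormal columns
    eigenvalues: np.ndarray  # length k, non-increasing

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.components[:, i] for i in range(self.components.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols}).set_index("sample_id")


def compute_pcs(grm: Grm, k: int = 20) -> PcSet:
    """Top-k eigenvectors of the GRM (PCA of standardized genotypes).

    Eigenvector signs are fixed so each column's largest-magnitude loading is
    positive.
    """
    if k >= grm.n_samples:
        raise ValueError("k must be < n_samples")
    w, u = grm.eig()
    order = np.argsort(w)[::-1][:k]
    vals = w[order]
    vecs = u[:, order]
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PcSet(grm.sample_ids.copy(), vecs, vals)
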