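"""Core in-memory containers shared across the package.

Genotypes are held as an ``n_samples x n_snps`` additive dosage matrix
(``float32``; dosage counts the A1 allele of each SNP, ``NaN`` marks a
missing call).  Sample and SNP metadata ride along as pandas DataFrames,
which keeps alignment explicit and subsetting cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "sex", "birth_decade", "age"]
SNP_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]

SEX_LEVELS = ("male", "female", "unknown")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class IntegrityError(ValueError):
    """Contents are self-inconsistent (dimension or id mismatches, conflicts)."""


def make_sample_table(
    sample_ids: Sequence[str],
    sex: Sequence[str] | None = None,
    birth_decade: Sequence | None = None,
    age: Sequence | None = None,
) -> pd.DataFrame:
    n = len(sample_ids)
    tbl = pd.DataFrame(
        {
            "sample_id": pd.Series(sample_ids, dtype=str),
            "sex": pd.Series(sex if sex is not None else ["unknown"] * n, dtype=str),
            "birth_decade": pd.Series(
                birth_decade if birth_decade is not None else [np.nan] * n, dtype=float
            ),
            "age": pd.Series(age if age is not None else [np.nan] * n, dtype=float),
        }
    )
    return tbl


def make_snp_table(
    snp_ids: Sequence[str],
    chrom: Sequence[str] | str = "1",
    pos: Sequence[int] | None = None,
    a1: Sequence[str] | str = "A",
    a2: Sequence[str] | str = "B",
) -> pd.DataFrame:
    m = len(snp_ids)
    if isinstance(chrom, str):
        chrom = [chrom] * m
    if pos is None:
        pos = np.arange(1, m + 1)
    if isinstance(a1, str):
        a1 = [a1] * m
    if isinstance(a2, str):
        a2 = [a2] * m
    return pd.DataFrame(
        {
            "snp_id": pd.Series(snp_ids, dtype=str),
            "chrom": pd.Series(chrom, dtype=str),
            "pos": pd.Series(pos, dtype=np.int64),
            "a1": pd.Series(a1, dtype=str),
            "a2": pd.Series(a2, dtype=str),
        }
    )


@dataclass
class GenotypeDataset:
    """Samples x SNPs additive genotype dosages plus metadata.

    Parameters
    ----------
    samples : DataFrame with columns sample_id, sex, birth_decade, age.
    snps : DataFrame with columns snp_id, chrom, pos, a1, a2.  ``a1`` is the
        counted allele: a dosage of 2 means homozygous for ``a1``.
    dosages : float array of shape (n_samples, n_snps); values in [0, 2]
        (hard calls 0/1/2 or fractional imputed dosages); NaN = missing.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        n, m = self.dosages.shape
        if len(self.samples) != n or len(self.snps) != m:
            raise IntegrityError(
                f"dosage matrix is {n}x{m} but metadata describes "
                f"{len(self.samples)} samples and {len(self.snps)} SNPs"
            )
        if self.samples["sample_id"].duplicated().any():
            raise IntegrityError("duplicate sample ids")
        if self.snps["snp_id"].duplicated().any():
            raise IntegrityError("duplicate SNP ids")
        if len(self.snps) and (self.snps["pos"] < 1).any():
            raise IntegrityError("SNP positions must be >= 1 (1-based)")

    # -- basic views -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP sample frequency of the counted (a1) allele, missing ignored."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def snp_missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    # -- subsetting --------------------------------------------------------
    def take_samples(self, ids: Iterable[str]) -> "GenotypeDataset":
        ids = list(ids)
        lookup = pd.Index(self.samples["sample_id"])
        idx = lookup.get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise IntegrityError(f"unknown sample ids: {missing[:5]}")
        return GenotypeDataset(
            self.samples.iloc[idx], self.snps, self.dosages[idx, :]
        )

    def take_snps(self, ids: Iterable[str]) -> "GenotypeDataset":
        ids = list(ids)
        lookup = pd.Index(self.snps["snp_id"])
        idx = lookup.get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise IntegrityError(f"unknown SNP ids: {missing[:5]}")
        return GenotypeDataset(
            self.samples, self.snps.iloc[idx], self.dosages[:, idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        same_meta = self.samples[SAMPLE_COLUMNS].astype(str).equals(
            other.samples[SAMPLE_COLUMNS].astype(str)
        ) and self.snps[SNP_COLUMNS].astype(str).equals(
            other.snps[SNP_COLUMNS].astype(str)
        )
        if not same_meta or self.dosages.shape != other.dosages.shape:
            return False
        a, b = self.dosages, other.dosages
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))


@dataclass
class RegionSet:
    """Genomic regions, 1-based and inclusive on both ends."""

    regions: pd.DataFrame  # chrom, start, end, label

    def __post_init__(self) -> None:
        self.regions = self.regions.reset_index(drop=True)
        if len(self.regions):
            if (self.regions["start"] > self.regions["end"]).any():
                raise FormatError("region with start > end")
            if self.regions["label"].duplicated().any():
                raise IntegrityError("duplicate region labels")

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "RegionSet":
        df = pd.DataFrame(records, columns=["chrom", "start", "end", "label"])
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        return cls(df)

    def __len__(self) -> int:
        return len(self.regions)

    def select(self, labels: Iterable[str]) -> "RegionSet":
        labels = set(labels)
        return RegionSet(self.regions[self.regions["label"].isin(labels)])


@dataclass
class StudySummary:
    """One study's odds-ratio result, as printed (OR with a 95% Wald CI)."""

    study_id: str
    or_point: float
    ci_low: float
    ci_high: float
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.or_point <= self.ci_high):
            raise IntegrityError(
                f"study {self.study_id}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket OR {self.or_point}"
            )
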