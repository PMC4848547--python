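"""Readers and writers for the file formats the pipeline consumes.

PLINK bed (v1.0, SNP-major) is decoded directly: each SNP occupies
``ceil(n/4)`` bytes, two bits per sample starting from the least
significant pair, with codes ``00`` = homozygous A1 (dosage 2), ``01`` =
missing, ``10`` = heterozygous (1), ``11`` = homozygous A2 (0).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    FormatError,
    GenotypeDataset,
    IntegrityError,
    RegionSet,
    StudySummary,
    make_sample_table,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of the A1 allele; NaN = missing (code 01)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0], dtype=np.float32)

_SEX_FROM_FAM = {"1": "male", "2": "female"}
_SEX_TO_FAM = {"male": "1", "female": "2", "unknown": "0"}


# ---------------------------------------------------------------------------
# PLINK triplet
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a ``prefix.bed/.bim/.fam`` triplet into a :class:`GenotypeDataset`.

    Dosages count the bim A1 allele.  An optional ``prefix.sample_info.tsv``
    sidecar (written by :func:`write_plink`) restores birth decade and age,
    which the fam format cannot carry.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{prefix}.bed: bad magic bytes {raw[:3]!r} (expected PLINK v1.0 SNP-major)"
        )
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * m:
        raise IntegrityError(
            f"{prefix}.bed payload is {payload.size} bytes; expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    dosages = np.empty((n, m), dtype=np.float32)
    if m:
        blocks = payload.reshape(m, bytes_per_snp)
        # unpack the four 2-bit fields of each byte, sample-index order
        codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
        for k in range(4):
            codes[:, k::4] = (blocks >> (2 * k)) & 0b11
        dosages[:] = _CODE_TO_DOSAGE[codes[:, :n]].T

    samples = make_sample_table(
        fam["iid"].tolist(),
        sex=[_SEX_FROM_FAM.get(s, "unknown") for s in fam["sex"]],
    )
    sidecar = prefix.parent / (prefix.name + ".sample_info.tsv")
    if sidecar.exists():
        info = pd.read_csv(sidecar, sep="\t", dtype={"sample_id": str})
        samples = samples.drop(columns=["birth_decade", "age"]).merge(
            info[["sample_id", "birth_decade", "age"]], on="sample_id", how="left"
        )
    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "a1": bim["a1"],
            "a2": bim["a2"],
        }
    )
    return GenotypeDataset(samples, snps, dosages)


def write_plink(ds: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``ds`` as a PLINK bed/bim/fam triplet (plus metadata sidecar).

    Hard calls only: fractional dosages are rejected.  ``read_plink`` of the
    written files reproduces (samples, snps, dosages) exactly.
    """
    prefix = Path(prefix)
    d = ds.dosages
    finite = d[~np.isnan(d)]
    if finite.size and not np.all(np.isin(finite, [0.0, 1.0, 2.0])):
        raise ValueError("bed format stores hard calls; dosages must be 0/1/2 or missing")

    n, m = d.shape
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    dT = d.T
    codes[dT == 2.0] = 0b00
    codes[dT == 1.0] = 0b10
    codes[dT == 0.0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 0b01, dtype=np.uint8)
    padded[:, :n] = codes
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())

    fam = pd.DataFrame(
        {
            "fid": ds.samples["sample_id"],
            "iid": ds.samples["sample_id"],
            "father": "0",
            "mother": "0",
            "sex": [_SEX_TO_FAM.get(s, "0") for s in ds.samples["sex"]],
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": ds.snps["chrom"],
            "snp_id": ds.snps["snp_id"],
            "cm": 0,
            "pos": ds.snps["pos"],
            "a1": ds.snps["a1"],
            "a2": ds.snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    ds.samples.to_csv(
        prefix.parent / (prefix.name + ".sample_info.tsv"), sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Text genotype dialect (human-readable fixtures)
# ---------------------------------------------------------------------------

def write_geno_text(ds: GenotypeDataset, path: str | Path) -> None:
    """Whitespace-delimited dialect: ``#snp`` metadata lines, then a header of
    SNP ids and one row of dosages per sample (NA = missing)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in ds.snps.itertuples(index=False):
            fh.write(f"#snp {r.snp_id} {r.chrom} {r.pos} {r.a1} {r.a2}\n")
        fh.write("sample_id " + " ".join(ds.snp_ids) + "\n")
        for i, sid in enumerate(ds.sample_ids):
            row = ["NA" if np.isnan(v) else format(float(v), "g") for v in ds.dosages[i]]
            fh.write(sid + " " + " ".join(row) + "\n")


def read_geno_text(path: str | Path) -> GenotypeDataset:
    path = Path(path)
    snp_meta = {}
    header = None
    rows: list[list[str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#snp"):
                _, sid, chrom, pos, a1, a2 = line.split()
                snp_meta[sid] = (chrom, int(pos), a1, a2)
            elif header is None:
                header = line.split()
                if header[0] != "sample_id":
                    raise FormatError("text genotype header must start with 'sample_id'")
            else:
                rows.append(line.split())
    if header is None:
        raise FormatError("empty text genotype file")
    snp_ids = header[1:]
    sample_ids = [r[0] for r in rows]
    d = np.full((len(rows), len(snp_ids)), np.nan, dtype=np.float32)
    for i, r in enumerate(rows):
        if len(r) != len(snp_ids) + 1:
            raise IntegrityError(f"row for sample {r[0]} has {len(r) - 1} dosages")
        for j, v in enumerate(r[1:]):
            if v != "NA":
                d[i, j] = float(v)
    from .data import make_snp_table

    if snp_meta:
        snps = pd.DataFrame(
            [(s, *snp_meta.get(s, ("1", j + 1, "A", "B"))) for j, s in enumerate(snp_ids)],
            columns=["snp_id", "chrom", "pos", "a1", "a2"],
        )
        snps["pos"] = snps["pos"].astype(np.int64)
    else:
        snps = make_snp_table(snp_ids)
    return GenotypeDataset(make_sample_table(sample_ids), snps, d)


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

_STATUS_MAP = {
    "2": "case",
    "1": "control",
    "case": "case",
    "control": "control",
    "na": None,
    "nan": None,
    "-9": None,
    "0": None,
    "": None,
}


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a wide phenotype table: first column sample ids, one column per
    phenotype, PLINK-convention statuses (2=case, 1=control, NA/-9/0=missing).

    Returns a DataFrame indexed by sample_id with string values ``case`` /
    ``control`` / NaN.  Unknown codes become missing with a warning; a sample
    appearing twice with conflicting statuses is an error.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    raw = pd.read_csv(path, sep=sep, dtype=str)
    id_col = raw.columns[0]
    out = raw.set_index(id_col)
    mapped = pd.DataFrame(index=out.index, columns=out.columns, dtype=object)
    for col in out.columns:
        vals = out[col].astype(str).str.strip().str.lower()
        unknown = ~vals.isin(_STATUS_MAP)
        if unknown.any():
            warnings.warn(
                f"phenotype {col}: {int(unknown.sum())} unknown status codes -> missing",
                stacklevel=2,
            )
        mapped[col] = [
            _STATUS_MAP.get(v) if v in _STATUS_MAP else None for v in vals
        ]
    if mapped.index.duplicated().any():
        dup = mapped.index[mapped.index.duplicated(keep=False)]
        for sid in dup.unique():
            sub = mapped.loc[[sid]]
            for col in sub.columns:
                statuses = {s for s in sub[col] if s is not None}
                if len(statuses) > 1:
                    raise IntegrityError(
                        f"conflicting status for sample {sid}, phenotype {col}"
                    )
        mapped = mapped.groupby(level=0, sort=False).first()
    mapped.index.name = "sample_id"
    return mapped


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariate table: first column sample ids, remaining columns numeric."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    raw = pd.read_csv(path, sep=sep)
    id_col = raw.columns[0]
    raw[id_col] = raw[id_col].astype(str)
    out = raw.set_index(id_col)
    out.index.name = "sample_id"
    return out.astype(float)


# ---------------------------------------------------------------------------
# Regions and study summaries
# ---------------------------------------------------------------------------

def read_regions(path: str | Path) -> RegionSet:
    """Read a BED-like file (0-based half-open) into 1-based inclusive regions."""
    records = []
    with Path(path).open() as fh:
        for k, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"line {k + 1}: BED needs >=3 columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else f"region{len(records) + 1}"
            start, end = start0 + 1, end0  # 0-based half-open -> 1-based inclusive
            if start > end:
                raise FormatError(f"line {k + 1}: empty/negative region after conversion")
            records.append((chrom, start, end, label))
    if not records:
        return RegionSet(
            pd.DataFrame(columns=["chrom", "start", "end", "label"]).astype(
                {"start": np.int64, "end": np.int64}
            )
        )
    return RegionSet.from_records(records)


def write_regions(rs: RegionSet, path: str | Path) -> None:
    """Write regions back to BED (internal 1-based inclusive -> 0-based half-open)."""
    with Path(path).open("w") as fh:
        for r in rs.regions.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")


def read_study_summaries(path: str | Path) -> list[StudySummary]:
    """Read a CSV/TSV of per-study odds ratios: columns study, or, ci_low,
    ci_high and optionally n_cases, n_controls."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    raw = pd.read_csv(path, sep=sep)
    cols = {c.lower().replace("-", "_"): c for c in raw.columns}
    for need in ("study", "or", "ci_low", "ci_high"):
        if need not in cols:
            raise FormatError(f"study summary table missing column '{need}'")
    out = []
    for r in raw.itertuples(index=False):
        rec = dict(zip((c.lower().replace("-", "_") for c in raw.columns), r))
        out.append(
            StudySummary(
                study_id=str(rec["study"]),
                or_point=float(rec["or"]),
                ci_low=float(rec["ci_low"]),
                ci_high=float(rec["ci_high"]),
                n_cases=int(rec["n_cases"]) if "n_cases" in rec and pd.notna(rec["n_cases"]) else None,
                n_controls=int(rec["n_controls"]) if "n_controls" in rec and pd.notna(rec["n_controls"]) else None,
            )
        )
    return out
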