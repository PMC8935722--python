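"""Genotype/phenotype containers, SNP codings, and delimited-text I/O.

Genotypes are stored additively as minor-allele counts in {0, 1, 2}.  Two
derived codings are provided: the identity additive coding used by
penalized regression and random forests, and the dominant/recessive
binarization (``SNP_D = 1(SNP != 0)``, ``SNP_R = 1(SNP = 2)``) required by
logic regression.  Missing genotypes are rejected at load time; the data
model has no missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNPMatrix",
    "PhenotypeVector",
    "BinaryEncodedMatrix",
    "encode_dominant_recessive",
    "decode_dominant_recessive",
    "encode_additive",
    "read_genotype_table",
    "write_genotype_table",
    "GenotypeLoadError",
]


class GenotypeLoadError(ValueError):
    """Raised when a genotype table violates the {0,1,2}/no-missing contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} identifiers must be unique")


@dataclass
class SNPMatrix:
    """N x p matrix of minor-allele counts with sample and SNP identifiers.

    Every entry must lie in {0, 1, 2}; no missing values are allowed.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype matrix must be two-dimensional")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("genotype matrix must have at least one sample and one SNP")
        if not np.issubdtype(self.values.dtype, np.integer):
            floats = np.asarray(self.values, dtype=float)
            ints = floats.astype(np.int64)
            if not np.array_equal(floats, ints):
                raise ValueError("genotype entries must be integers in {0, 1, 2}")
            self.values = ints
        bad = (self.values < 0) | (self.values > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype entry {self.values[i, j]} at sample row {i}, SNP column {j} "
                "is outside {0, 1, 2}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        if not self.snp_ids:
            self.snp_ids = [f"SNP{j + 1}" for j in range(p)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(self.snp_ids) != p:
            raise ValueError("snp_ids length does not match matrix columns")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.snp_ids, "SNP")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class PhenotypeVector:
    """Binary case/control outcome, entries in {0, 1} (1 = case)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("phenotype must be one-dimensional")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("phenotype entries must be 0 or 1")
        self.values = self.values.astype(np.int64)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def case_fraction(self) -> float:
        return float(self.values.mean())


@dataclass
class BinaryEncodedMatrix:
    """N x 2p dominant/recessive binarization of a genotype matrix.

    Columns are ordered (SNP1_D, SNP1_R, SNP2_D, SNP2_R, ...).  The
    recessive column is elementwise <= its dominant sibling.
    """

    values: np.ndarray
    feature_ids: list[str]
    source_map: list[tuple[int, str]]  # feature index -> (snp index, "dominant"/"recessive")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def encode_dominant_recessive(g: SNPMatrix) -> BinaryEncodedMatrix:
    """Split each SNP into dominant (SNP != 0) and recessive (SNP == 2) indicators."""
    vals = g.values
    n, p = vals.shape
    out = np.empty((n, 2 * p), dtype=np.int8)
    out[:, 0::2] = (vals != 0).astype(np.int8)
    out[:, 1::2] = (vals == 2).astype(np.int8)
    feature_ids: list[str] = []
    source_map: list[tuple[int, str]] = []
    for j, sid in enumerate(g.snp_ids):
        feature_ids.extend([f"{sid}_D", f"{sid}_R"])
        source_map.extend([(j, "dominant"), (j, "recessive")])
    return BinaryEncodedMatrix(values=out, feature_ids=feature_ids, source_map=source_map)


def decode_dominant_recessive(b: BinaryEncodedMatrix, snp_ids: Optional[list[str]] = None) -> SNPMatrix:
    """Invert :func:`encode_dominant_recessive` (R=1 -> 2; D=1,R=0 -> 1; else 0)."""
    d = b.values[:, 0::2]
    r = b.values[:, 1::2]
    vals = np.where(r == 1, 2, np.where(d == 1, 1, 0))
    if snp_ids is None:
        snp_ids = [fid[:-2] for fid in b.feature_ids[0::2]]
    return SNPMatrix(values=vals, snp_ids=snp_ids)


def encode_additive(g: SNPMatrix) -> np.ndarray:
    """Identity pass-through: minor-allele counts as ordered numeric features."""
    return np.asarray(g.values, dtype=np.float64)


_RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotype_table(
    path: str | Path,
    dialect: str = "csv",
    phenotype_column: str = "phenotype",
    environment_columns: Optional[Sequence[str]] = None,
):
    """Read a delimited genotype table.

    ``dialect`` is one of ``csv``/``tsv`` (header of column names, first
    column taken as the sample identifier) or ``raw`` (PLINK .raw-style:
    FID IID PAT MAT SEX PHENOTYPE followed by additive SNP columns, with
    PHENOTYPE coded 1=control/2=case).

    Returns ``(SNPMatrix, PhenotypeVector | None, environment DataFrame | None)``.
    """
    path = Path(path)
    if dialect == "raw":
        df = pd.read_csv(path, sep=r"\s+")
        missing_meta = [c for c in _RAW_META_COLS if c not in df.columns]
        if missing_meta:
            raise GenotypeLoadError(f".raw file is missing columns {missing_meta}")
        snp_cols = [c for c in df.columns if c not in _RAW_META_COLS]
        pheno_raw = df["PHENOTYPE"]
        if pheno_raw.isna().any() or not pheno_raw.isin((1, 2)).all():
            raise GenotypeLoadError(
                ".raw PHENOTYPE must be 1 (control) or 2 (case); 0/-9/NA are treated as missing"
            )
        phenotype = PhenotypeVector((pheno_raw.to_numpy() == 2).astype(int))
        sample_ids = [str(s) for s in df["IID"].tolist()]
        geno_df = df[snp_cols]
        env = None
    elif dialect in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if dialect == "csv" else "\t", index_col=0)
        env_cols = list(environment_columns or [])
        phenotype = None
        if phenotype_column in df.columns:
            ph = df[phenotype_column]
            if ph.isna().any() or not ph.isin((0, 1)).all():
                raise GenotypeLoadError(f"phenotype column '{phenotype_column}' must be 0/1 with no missing values")
            phenotype = PhenotypeVector(ph.to_numpy().astype(int))
        snp_cols = [c for c in df.columns if c != phenotype_column and c not in env_cols]
        env = df[env_cols].copy() if env_cols else None
        sample_ids = [str(s) for s in df.index.tolist()]
        geno_df = df[snp_cols]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    geno = geno_df.to_numpy()
    if pd.isna(geno_df).to_numpy().any():
        i, j = np.argwhere(pd.isna(geno_df).to_numpy())[0]
        raise GenotypeLoadError(
            f"missing genotype at sample '{sample_ids[i]}', SNP '{snp_cols[j]}'"
        )
    valid = np.isin(geno, (0, 1, 2))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise GenotypeLoadError(
            f"genotype entry {geno[i, j]!r} at sample '{sample_ids[i]}', SNP '{snp_cols[j]}' "
            "is not in {0, 1, 2}"
        )
    matrix = SNPMatrix(values=geno.astype(np.int64), sample_ids=sample_ids, snp_ids=[str(c) for c in snp_cols])
    return matrix, phenotype, env


def write_genotype_table(
    path: str | Path,
    g: SNPMatrix,
    phenotype: Optional[PhenotypeVector] = None,
    environment: Optional[pd.DataFrame] = None,
    dialect: str = "csv",
    phenotype_column: str = "phenotype",
) -> None:
    """Write a genotype table readable back by :func:`read_genotype_table`."""
    if dialect not in ("csv", "tsv"):
        raise ValueError("writer supports the csv/tsv dialects")
    df = pd.DataFrame(g.values, index=pd.Index(g.sample_ids, name="sample_id"), columns=g.snp_ids)
    if phenotype is not None:
        df[phenotype_column] = phenotype.values
    if environment is not None:
        for col in environment.columns:
            df[col] = np.asarray(environment[col])
    df.to_csv(path, sep="," if dialect == "csv" else "\t")
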