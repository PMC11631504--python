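"""Readers and writers for the plain-table dialects of the toolkit.

Genotypes: CSV/TSV, first column line IDs, header row marker IDs, numeric
dosages; missing cells are mean-imputed per marker column (logged).
Phenotypes: CSV/TSV, line-ID column plus one numeric column per trait,
missing allowed (per-trait complete-case masks are taken downstream).
Genomic relationship matrices: square CSV with line IDs as both header
and index.  All floating-point output uses 17 significant digits so runs
can be compared byte-for-byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_grm",
    "write_grm",
    "align",
]

FLOAT_FMT = "%.17g"


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    df.index = df.index.astype(str)
    return df


def _require_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"non-numeric cell in {path} at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    return df


def read_genotypes(path, transpose: bool = False) -> pd.DataFrame:
    """Read a lines x markers dosage table; mean-impute missing cells.

    ``transpose=True`` reads a markers x lines file into the same layout.
    """
    df = _require_numeric(_read_table(path), path)
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate line IDs: {dups}")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("imputing %d missing genotype cell(s) with column means",
                       n_missing)
        df = df.fillna(df.mean())
        if df.isna().any().any():
            raise ValueError("column(s) entirely missing; cannot impute")
    return df.astype(float)


def write_genotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a line x trait phenotype table; drop all-missing traits."""
    df = _require_numeric(_read_table(path), path)
    if df.index.duplicated().any():
        raise ValueError("duplicate line IDs in phenotype table")
    empty = [c for c in df.columns if df[c].isna().all()]
    if empty:
        logger.warning("excluding trait(s) with no observations: %s", empty)
        df = df.drop(columns=empty)
    if df.shape[1] == 0:
        raise ValueError("no usable traits in phenotype table")
    return df.astype(float)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT)


def read_grm(path) -> pd.DataFrame:
    """Read a square genomic-relationship CSV with matching ID header/index."""
    df = _require_numeric(_read_table(path), path)
    if df.shape[0] != df.shape[1] or list(df.index) != [str(c) for c in df.columns]:
        raise ValueError("G matrix must be square with identical row/column IDs")
    return df.astype(float)


def write_grm(G: pd.DataFrame, path) -> None:
    G.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FMT)


def align(genotypes: pd.DataFrame, phenotypes: pd.DataFrame, trait: str):
    """Match genotype and phenotype rows by line ID, order-independent.

    Returns ``(X, y, ids)`` restricted to lines with both a genotype row
    and a non-missing value of ``trait``.
    """
    if trait not in phenotypes.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    pheno = phenotypes[trait].dropna()
    common = genotypes.index.intersection(pheno.index)
    if len(common) == 0:
        raise ValueError("no overlapping line IDs between genotypes and phenotypes")
    common = sorted(common)
    X = genotypes.loc[common].to_numpy(dtype=float)
    y = pheno.loc[common].to_numpy(dtype=float)
    return X, y, list(common)
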