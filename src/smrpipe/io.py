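"""Readers and writers for GWAS/eQTL summary statistics and SMR result tables.

GWAS input follows the GCTA-COJO ``.ma`` dialect: a whitespace-delimited
text file with header ``SNP A1 A2 freq b se p N`` where A1 is the effect
allele, ``b``/``se`` the per-allele effect and its standard error, and N
the per-SNP sample size.  eQTL input is a TSV keyed by (gene, SNP) carrying
either a Z-score column or ``b``+``se`` (Z is derived as b/se on load).

All tables are returned as pandas DataFrames with lowercase canonical
columns; every record is validated against the field invariants on read and
a violation raises :class:`~smrpipe.exceptions.ValidationError` naming the
offending SNP (or line) and field — loading never silently drops a row.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical GWAS columns (``.ma`` header maps onto these, in order)
GWAS_COLUMNS = ["snp", "a1", "a2", "freq", "b", "se", "p", "n"]
_MA_HEADER = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]

#: canonical eQTL columns after loading (z always populated)
EQTL_COLUMNS = ["gene", "snp", "a1", "a2", "freq", "z", "p", "n"]
_EQTL_HEADER_Z = ["gene", "SNP", "A1", "A2", "freq", "Z", "p", "N"]
_EQTL_HEADER_B = ["gene", "SNP", "A1", "A2", "freq", "b", "se", "p", "N"]

#: fixed column order of the SMR results table
RESULT_COLUMNS = [
    "gene", "SNP", "A1", "b_zx", "se_zx", "b_zy", "se_zy",
    "b_xy", "se_xy", "T_SMR", "p_SMR", "significant",
]

_SMALLEST_P = float(np.finfo(float).tiny)


def _coerce_numeric(df: pd.DataFrame, columns: list[str], path: str) -> pd.DataFrame:
    """Convert columns to float, raising with a 1-based file line number on failure."""
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: line {row + 2}: field '{col}' has non-numeric "
                f"value {df[col].iloc[row]!r}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValidationError(f"{path}: line {row + 2}: field '{col}' is missing")
        df[col] = converted
    return df


def _check_alleles(df: pd.DataFrame, label_col: str, path: str) -> None:
    for col in ("a1", "a2"):
        bad = ~df[col].isin(list(VALID_ALLELES))
        if bad.any():
            who = df.loc[bad, label_col].iloc[0]
            raise ValidationError(
                f"{path}: record {who!r}: field '{col}' value "
                f"{df.loc[bad, col].iloc[0]!r} is not a single base in A/C/G/T"
            )
    same = df["a1"] == df["a2"]
    if same.any():
        who = df.loc[same, label_col].iloc[0]
        raise ValidationError(
            f"{path}: record {who!r}: effect and other allele are identical"
        )


def _clamp_zero_p(df: pd.DataFrame, path: str) -> None:
    zero = df["p"] == 0
    if zero.any():
        logger.warning(
            "%s: %d record(s) with p=0 clamped to %.3g (underflow in source file)",
            path, int(zero.sum()), _SMALLEST_P,
        )
        df.loc[zero, "p"] = _SMALLEST_P


def _validate_common(df: pd.DataFrame, label_col: str, path: str) -> None:
    checks = [
        ("freq", ~df["freq"].between(0, 1, inclusive="neither"),
         "effect-allele frequency must lie strictly in (0, 1)"),
        ("p", ~((df["p"] > 0) & (df["p"] <= 1)), "p-value must lie in (0, 1]"),
        ("n", df["n"] < 1, "sample size must be >= 1"),
    ]
    for field, bad, msg in checks:
        if bad.any():
            who = df.loc[bad, label_col].iloc[0]
            raise ValidationError(
                f"{path}: record {who!r}: field '{field}': {msg} "
                f"(got {df.loc[bad, field].iloc[0]!r})"
            )


def read_gwas(path, dialect: str = "ma") -> pd.DataFrame:
    """Read one cohort's GWAS summary statistics.

    Parameters
    ----------
    path : str or Path
        Whitespace-delimited file with header ``SNP A1 A2 freq b se p N``.
    dialect : {"ma"}
        Input dialect; only the GCTA-COJO ``.ma`` layout is supported.

    Returns
    -------
    pandas.DataFrame
        Columns :data:`GWAS_COLUMNS`, row order preserved, alleles
        uppercased, every invariant checked.
    """
    if dialect != "ma":
        raise ValueError(f"unknown GWAS dialect {dialect!r}; supported: 'ma'")
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if list(df.columns) != _MA_HEADER:
        raise SchemaError(
            f"{path}: expected header {' '.join(_MA_HEADER)!r}, "
            f"got {' '.join(map(str, df.columns))!r}"
        )
    df.columns = GWAS_COLUMNS
    if df.empty:
        return df.astype({c: float for c in ("freq", "b", "se", "p", "n")})
    df = _coerce_numeric(df, ["freq", "b", "se", "p", "n"], str(path))
    for col in ("a1", "a2"):
        df[col] = df[col].str.upper()
    _check_alleles(df, "snp", str(path))
    _clamp_zero_p(df, str(path))
    bad_se = df["se"] <= 0
    if bad_se.any():
        who = df.loc[bad_se, "snp"].iloc[0]
        raise ValidationError(
            f"{path}: record {who!r}: field 'se': standard error must be > 0 "
            f"(got {df.loc[bad_se, 'se'].iloc[0]!r})"
        )
    _validate_common(df, "snp", str(path))
    return df.reset_index(drop=True)


def read_eqtl(path) -> pd.DataFrame:
    """Read eQTL summary statistics (TSV keyed by gene, SNP).

    Accepts either a ``Z`` column or ``b``+``se``; the returned table always
    carries ``z`` (derived as b/se where needed).  A duplicated (gene, SNP)
    pair is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols == _EQTL_HEADER_Z:
        has_z = True
    elif cols == _EQTL_HEADER_B:
        has_z = False
    else:
        raise SchemaError(
            f"{path}: header must be {' '.join(_EQTL_HEADER_Z)!r} or "
            f"{' '.join(_EQTL_HEADER_B)!r}; got {' '.join(map(str, cols))!r} "
            "(neither a Z column nor b+se found)"
        )
    df.columns = (["gene", "snp", "a1", "a2", "freq", "z", "p", "n"] if has_z
                  else ["gene", "snp", "a1", "a2", "freq", "b", "se", "p", "n"])
    if df.empty:
        out = pd.DataFrame(columns=EQTL_COLUMNS)
        return out.astype({c: float for c in ("freq", "z", "p", "n")})
    numeric = ["freq", "z", "p", "n"] if has_z else ["freq", "b", "se", "p", "n"]
    df = _coerce_numeric(df, numeric, str(path))
    for col in ("a1", "a2"):
        df[col] = df[col].str.upper()
    dup = df.duplicated(subset=["gene", "snp"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["gene", "snp"]].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (gene, SNP) pair ({pair['gene']!r}, {pair['snp']!r})"
        )
    if not has_z:
        bad_se = df["se"] <= 0
        if bad_se.any():
            who = df.loc[bad_se, "snp"].iloc[0]
            raise ValidationError(
                f"{path}: record {who!r}: field 'se': standard error must be > 0"
            )
        df["z"] = df["b"] / df["se"]
    _check_alleles(df, "snp", str(path))
    _clamp_zero_p(df, str(path))
    _validate_common(df, "snp", str(path))
    return df[EQTL_COLUMNS].reset_index(drop=True)


def write_results(results: pd.DataFrame, path) -> None:
    """Write an SMR results table as TSV in the fixed column order.

    Floats are printed at 12 significant digits so a write/read round trip
    preserves every field to better than 1e-10 relative error.
    """
    if results is None:
        raise ValueError("results must not be None")
    out = results.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            raise SchemaError(f"results table is missing column {col!r}")
    out = out[RESULT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "SNP": str, "A1": str})
    if list(df.columns) != RESULT_COLUMNS:
        raise SchemaError(
            f"{path}: expected results header {RESULT_COLUMNS}, got {list(df.columns)}"
        )
    df["significant"] = df["significant"].astype(bool)
    return df


def write_gwas(df: pd.DataFrame, path) -> None:
    """Write a GWAS table (canonical columns) in the ``.ma`` dialect."""
    out = df[GWAS_COLUMNS].copy()
    out.columns = _MA_HEADER
    out.to_csv(path, sep=" ", index=False, float_format="%.12g")


def write_eqtl(df: pd.DataFrame, path) -> None:
    """Write an eQTL table (canonical columns, Z form) as TSV."""
    out = df[EQTL_COLUMNS].copy()
    out.columns = _EQTL_HEADER_Z
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")
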