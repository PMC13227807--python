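"""Plain-text I/O for expression matrices, phenotype tables and candidate sets.

All on-disk formats are tab-separated text:

* expression matrix — first column ``feature_id``, remaining columns one per
  sample (header row of sample IDs), values are intensities (raw or log2);
  missing cells are empty fields;
* phenotype table — columns ``sample_id, diagnosis, age, sex, apoe4``;
* candidate sets — columns ``feature_id, direction`` with direction in
  ``{positive, negative}``.
"""

from __future__ import annotations

import os

import pandas as pd

DIAGNOSIS_LEVELS = ("AD", "control")
SEX_LEVELS = ("male", "female")


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    """Read a features x samples expression matrix from TSV.

    Returns a DataFrame indexed by feature ID with sample IDs as columns;
    empty fields become NaN.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except OSError as exc:
        raise OSError(f"cannot read expression matrix at {path!r}: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "feature")
    _check_unique(df.columns, "sample")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | os.PathLike) -> str:
    """Write a features x samples matrix as TSV (NaN as empty field)."""
    out = expr.copy()
    out.index.name = "feature_id"
    try:
        out.to_csv(path, sep="\t", na_rep="")
    except OSError as exc:
        raise OSError(f"cannot write expression matrix to {path!r}: {exc}") from exc
    return str(path)


def read_phenotype(path: str | os.PathLike) -> pd.DataFrame:
    """Read a phenotype table; validates diagnosis/sex levels and apoe4 codes."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except OSError as exc:
        raise OSError(f"cannot read phenotype table at {path!r}: {exc}") from exc
    df = df.set_index("sample_id")
    validate_phenotype(df)
    return df


def write_phenotype(pheno: pd.DataFrame, path: str | os.PathLike) -> str:
    validate_phenotype(pheno)
    out = pheno.copy()
    out.index.name = "sample_id"
    try:
        out.to_csv(path, sep="\t")
    except OSError as exc:
        raise OSError(f"cannot write phenotype table to {path!r}: {exc}") from exc
    return str(path)


def read_candidate_sets(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read candidate sets as ``{"positive": [...], "negative": [...]}``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    bad = set(df["direction"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"unknown candidate-set direction(s): {sorted(bad)}")
    return {
        d: df.loc[df["direction"] == d, "feature_id"].tolist()
        for d in ("positive", "negative")
    }


def write_candidate_sets(
    positive: list[str], negative: list[str], path: str | os.PathLike
) -> str:
    df = pd.DataFrame(
        {
            "feature_id": list(positive) + list(negative),
            "direction": ["positive"] * len(positive) + ["negative"] * len(negative),
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def validate_phenotype(pheno: pd.DataFrame) -> None:
    missing = {"diagnosis", "age", "sex", "apoe4"} - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if pheno["diagnosis"].isna().any():
        raise ValueError("phenotype table has missing diagnosis values")
    bad = set(pheno["diagnosis"].dropna()) - set(DIAGNOSIS_LEVELS)
    if bad:
        raise ValueError(f"diagnosis must be one of {DIAGNOSIS_LEVELS}, got {bad}")
    bad = set(pheno["sex"].dropna()) - set(SEX_LEVELS)
    if bad:
        raise ValueError(f"sex must be one of {SEX_LEVELS}, got {bad}")
    bad = set(pheno["apoe4"].dropna()) - {0, 1, 2}
    if bad:
        raise ValueError(f"apoe4 allele count must be 0, 1 or 2, got {bad}")
    if not pheno.index.is_unique:
        raise ValueError("duplicate sample IDs in phenotype table")


def check_aligned(expr: pd.DataFrame, pheno: pd.DataFrame) -> None:
    """Require identical sample ID sets between matrix columns and phenotype rows."""
    if set(expr.columns) != set(pheno.index):
        only_e = sorted(set(expr.columns) - set(pheno.index))[:5]
        only_p = sorted(set(pheno.index) - set(expr.columns))[:5]
        raise ValueError(
            "expression and phenotype sample IDs differ "
            f"(matrix-only: {only_e}, phenotype-only: {only_p})"
        )


def _check_unique(ids, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} IDs: {dups}")
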