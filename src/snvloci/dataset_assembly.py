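"""Assembly of labeled feature tables.

Feature tables are pandas DataFrames with a variant key (gene, chromosome,
position, wt_aa, mut_aa), a ``label`` column in {Benign, Pathogenic}, the
11 structure-based and 5 sequence-based loci features, and optional
mutation-difference columns. This module merges the per-stage outputs,
learns train-side imputation statistics (column mean for numeric, mode for
binary), applies the rare-variant / rare-disease filters, and produces
stratified train/validation splits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "KEY_COLUMNS", "LABEL_COLUMN", "LABELS",
    "STRUCTURE_FEATURES", "SEQUENCE_FEATURES", "STR_NONEIGH_FEATURES",
    "MUTATION_FEATURES", "ALL_PRIOR_FEATURES", "BINARY_FEATURES",
    "ImputationModel", "assemble_rows", "fit_imputer", "apply_imputer",
    "rare_variant_filter", "split_train_validation", "load_supplementary_csv",
]

KEY_COLUMNS = ["gene", "chromosome", "position", "wt_aa", "mut_aa"]
LABEL_COLUMN = "label"
LABELS = ("Benign", "Pathogenic")

STRUCTURE_FEATURES = [
    "KDmean", "RSAmax", "nRSA", "nNum", "Bstddev", "nB", "nKD", "nSC",
    "nBinding", "Binding", "Mapreg",
]
SEQUENCE_FEATURES = ["PSIC", "Nobs", "MinDJxn", "CodPos", "SeqCons"]
STR_NONEIGH_FEATURES = ["KDmean", "RSAmax", "Bstddev", "Binding", "Mapreg"]
MUTATION_FEATURES = ["delta_psic", "grantham", "delta_kd"]
ALL_PRIOR_FEATURES = SEQUENCE_FEATURES + STRUCTURE_FEATURES
#: features treated as binary (mode-imputed)
BINARY_FEATURES: Set[str] = {"Mapreg"}

# label harmonization applied by the supplementary-schema adapter
_LABEL_COLLAPSE = {
    "benign": "Benign", "likely benign": "Benign", "neutral": "Benign",
    "pathogenic": "Pathogenic", "likely pathogenic": "Pathogenic",
    "deleterious": "Pathogenic",
}


def _normalize_key_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in KEY_COLUMNS:
        if col not in out.columns:
            continue
        if col == "position":
            out[col] = out[col].astype(int)
        else:
            out[col] = out[col].astype(str)
    return out


def _check_unique_keys(df: pd.DataFrame) -> None:
    keys = [c for c in KEY_COLUMNS if c in df.columns]
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        pairs = df.loc[dup, keys].drop_duplicates().to_dict("records")
        raise ValueError(f"duplicate variant keys: {pairs}")


def assemble_rows(
    variants: pd.DataFrame,
    struct_features: pd.DataFrame,
    seq_features: pd.DataFrame,
    mutation_features: Optional[pd.DataFrame] = None,
    keep_unmapped: bool = False,
) -> pd.DataFrame:
    """Inner-join per-stage feature frames on the variant key.

    Rows whose entire structure block is missing (no homologous structure
    could be mapped) are dropped unless ``keep_unmapped`` is set, in which
    case their structure features stay missing for downstream imputation.
    """
    variants = _normalize_key_dtypes(variants)
    struct_features = _normalize_key_dtypes(struct_features)
    seq_features = _normalize_key_dtypes(seq_features)
    if mutation_features is not None:
        mutation_features = _normalize_key_dtypes(mutation_features)
    for df in (variants, struct_features, seq_features, mutation_features):
        if df is not None:
            _check_unique_keys(df)
    keys = [c for c in KEY_COLUMNS if c in variants.columns]
    out = variants.merge(struct_features, on=keys, how="left")
    out = out.merge(seq_features, on=keys, how="inner")
    if mutation_features is not None:
        out = out.merge(mutation_features, on=keys, how="left")
    struct_cols = [c for c in STRUCTURE_FEATURES if c in out.columns]
    if struct_cols and not keep_unmapped:
        unmapped = out[struct_cols].isna().all(axis=1)
        if unmapped.any():
            logger.info("dropping %d variants without structure mapping", unmapped.sum())
        out = out.loc[~unmapped]
    return out.reset_index(drop=True)


@dataclass
class ImputationModel:
    """Training-set fill values: mean for numeric, mode for binary columns."""

    fills: Dict[str, float] = field(default_factory=dict)
    binary_columns: Set[str] = field(default_factory=set)


def fit_imputer(
    train: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    binary_columns: Optional[Set[str]] = None,
) -> ImputationModel:
    """Learn per-column fill values from training rows only.

    An all-missing column falls back to 0 with a warning.
    """
    if train.empty:
        raise ValueError("cannot fit imputer on an empty table")
    if binary_columns is None:
        binary_columns = BINARY_FEATURES
    if columns is None:
        columns = [
            c for c in train.columns
            if c not in KEY_COLUMNS + [LABEL_COLUMN]
            and pd.api.types.is_numeric_dtype(train[c])
        ]
    model = ImputationModel(binary_columns=set(binary_columns) & set(columns))
    for col in columns:
        series = train[col]
        if series.notna().sum() == 0:
            warnings.warn(f"column {col!r} is entirely missing in training; filling 0")
            model.fills[col] = 0.0
        elif col in binary_columns:
            model.fills[col] = float(series.mode(dropna=True).iloc[0])
        else:
            model.fills[col] = float(series.mean(skipna=True))
    return model


def apply_imputer(model: ImputationModel, table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing values with training statistics (idempotent)."""
    out = table.copy()
    for col, fill in model.fills.items():
        if col in out.columns:
            out[col] = out[col].fillna(fill)
    return out


def _diseases_of(value) -> List[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    if isinstance(value, str):
        return [d.strip() for d in value.split(";") if d.strip()]
    return list(value)


def rare_variant_filter(
    rows: pd.DataFrame,
    rare_disease_list: Optional[Iterable[str]] = None,
    maf_threshold: float = 0.01,
    maf_column: str = "maf",
    disease_column: str = "diseases",
) -> pd.DataFrame:
    """Keep rare variants associated with rare diseases.

    Rows with MAF above the threshold (default 1%) are dropped; a missing
    MAF counts as rare (kept, logged). When a rare-disease list is given,
    a row is kept only if its disease annotations intersect it.
    """
    out = rows
    if maf_column in out.columns:
        maf = pd.to_numeric(out[maf_column], errors="coerce")
        n_missing = maf.isna().sum()
        if n_missing:
            logger.warning("%d rows lack MAF; treated as rare and kept", n_missing)
        out = out.loc[maf.isna() | (maf <= maf_threshold)]
    if rare_disease_list is not None and disease_column in out.columns:
        rare = set(rare_disease_list)
        keep = out[disease_column].map(
            lambda v: bool(set(_diseases_of(v)) & rare)
        )
        out = out.loc[keep]
    return out.reset_index(drop=True)


def split_train_validation(
    table: pd.DataFrame,
    fraction: float = 0.2,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-label random split; ``fraction`` goes to validation."""
    if len(table) < 5:
        raise ValueError("need at least 5 rows to split")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    labels = table[LABEL_COLUMN]
    if labels.nunique() < 2:
        raise ValueError("cannot split a single-class table")
    train, val = train_test_split(
        table, test_size=fraction, random_state=seed, stratify=labels
    )
    return train.reset_index(drop=True), val.reset_index(drop=True)


def load_supplementary_csv(
    path,
    column_map: Optional[Dict[str, str]] = None,
    label_column: str = "label",
) -> pd.DataFrame:
    """Load a benchmark feature CSV into the canonical schema.

    ``column_map`` renames file columns to canonical names (Table-2 feature
    symbols pass through unchanged). Clinical labels are harmonized:
    likely benign -> Benign, likely pathogenic -> Pathogenic. Extra numeric
    columns (e.g. precomputed mutation features) pass through untouched.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if label_column != LABEL_COLUMN and label_column in df.columns:
        df = df.rename(columns={label_column: LABEL_COLUMN})
    if LABEL_COLUMN in df.columns:
        df[LABEL_COLUMN] = (
            df[LABEL_COLUMN].astype(str).str.strip().str.lower().map(_LABEL_COLLAPSE)
        )
        if df[LABEL_COLUMN].isna().any():
            bad = df.loc[df[LABEL_COLUMN].isna()]
            raise ValueError(f"unrecognized labels in {path}: {len(bad)} rows")
    _check_unique_keys(df)
    return df
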