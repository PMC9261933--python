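"""Reading, aligning, encoding and standardizing subject-level tables.

Radiomics analyses start from two files: a subject-by-feature table of
numeric imaging features and a clinical table holding covariates
(confounders) and the outcome. Everything downstream works on
centered-and-scaled numeric matrices, so this module owns the mapping
from raw CSV/TSV tables to those matrices: dummy-encoding of categorical
confounders, complete-case alignment across tables, and column
standardization with the transform parameters retained for reuse on
resampled or new data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_KINDS = ("numeric", "binary", "categorical")

_NA_VALUES = ["", "NA"]


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table: first column subject_id, remaining columns numeric.

    Delimiter is inferred from the extension (``.tsv`` -> tab, else comma).
    Returns a DataFrame indexed by subject_id (as strings).
    """
    df = _read_table(path)
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_clinical_table(path) -> pd.DataFrame:
    """Read a clinical table: first column subject_id, covariates/outcomes by name."""
    return _read_table(path)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str}, na_values=_NA_VALUES,
                     keep_default_na=True)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "subject_id"
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject_id values: {dupes}")
    return df


@dataclass
class ConfounderMatrix:
    """Dummy-encoded design matrix for the confounders X.

    ``values`` is indexed by subject_id so it can be aligned with the
    feature table; ``encoding_map`` records, per source covariate, how
    levels were mapped to columns (for reproducibility and for applying
    the same encoding to new data).
    """

    values: pd.DataFrame
    encoding_map: dict = field(default_factory=dict)

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)


def encode_confounders(table: pd.DataFrame, covariate_schema) -> ConfounderMatrix:
    """Build the confounder design matrix from named covariates.

    Parameters
    ----------
    table:
        Clinical table indexed by subject_id.
    covariate_schema:
        Sequence of ``(name, kind)`` pairs (or ``"name:kind"`` strings) with
        kind one of ``numeric``, ``binary``, ``categorical``.

    Encoding rules: numeric columns pass through; a binary covariate becomes
    one 0/1 column with the lexicographically first observed level as 0; a
    categorical covariate with L observed levels becomes L-1 dummy columns
    against the lexicographically first level.
    """
    schema = [_parse_schema_entry(s) for s in covariate_schema]
    if not schema:
        raise ValueError("covariate schema is empty")
    cols: dict[str, pd.Series] = {}
    encoding_map: dict[str, dict] = {}
    for name, kind in schema:
        if name not in table.columns:
            raise KeyError(f"covariate '{name}' not found in clinical table")
        if kind not in VALID_KINDS:
            raise ValueError(f"unknown covariate kind '{kind}' for '{name}'")
        col = table[name]
        if kind == "numeric":
            cols[name] = pd.to_numeric(col, errors="raise").astype(float)
            encoding_map[name] = {"kind": "numeric"}
            continue
        levels = sorted(col.dropna().astype(str).unique())
        if len(levels) < 2:
            raise ValueError(
                f"covariate '{name}' has a single observed level; "
                "cannot encode a constant confounder"
            )
        if kind == "binary":
            if len(levels) != 2:
                raise ValueError(
                    f"binary covariate '{name}' has {len(levels)} observed levels: {levels}"
                )
            ref, pos = levels
            mapped = col.astype(str).where(col.notna())
            cols[name] = mapped.map({ref: 0.0, pos: 1.0})
            encoding_map[name] = {"kind": "binary", "reference": ref, "positive": pos}
        else:  # categorical: L-1 dummies vs first sorted level
            ref = levels[0]
            dummy_cols = []
            str_col = col.astype(str).where(col.notna())
            for lev in levels[1:]:
                cname = f"{name}{lev}"
                cols[cname] = (str_col == lev).astype(float).where(col.notna())
                dummy_cols.append({"level": lev, "column": cname})
            encoding_map[name] = {"kind": "categorical", "reference": ref,
                                  "dummies": dummy_cols}
    values = pd.DataFrame(cols, index=table.index)
    return ConfounderMatrix(values=values, encoding_map=encoding_map)


def _parse_schema_entry(entry):
    if isinstance(entry, str):
        name, _, kind = entry.partition(":")
        if not kind:
            raise ValueError(f"schema entry '{entry}' must look like 'name:kind'")
        return name.strip(), kind.strip()
    name, kind = entry
    return name, kind


@dataclass
class CompleteCaseReport:
    dropped_count: int
    dropped_ids: list[str]
    n_used: int


def complete_cases(features: pd.DataFrame, confounders: ConfounderMatrix,
                   clinical: pd.DataFrame, outcome_columns) -> tuple:
    """Align the three tables on shared subjects and drop incomplete rows.

    Takes the intersection of subject ids, then removes any subject with a
    missing value in any feature, encoded confounder, or outcome column.
    Returns ``(features, confounders, clinical, report)`` with identical
    row order, plus a report of dropped subjects.
    """
    outcome_columns = list(outcome_columns)
    for col in outcome_columns:
        if col not in clinical.columns:
            raise KeyError(f"outcome column '{col}' not found in clinical table")

    ids = features.index.intersection(confounders.values.index)
    ids = ids.intersection(clinical.index)
    all_ids = features.index.union(confounders.values.index).union(clinical.index)

    feat = features.loc[ids]
    conf = confounders.values.loc[ids]
    clin = clinical.loc[ids, outcome_columns]

    keep = feat.notna().all(axis=1) & conf.notna().all(axis=1) & clin.notna().all(axis=1)
    kept_ids = ids[keep.to_numpy()]
    dropped = sorted(set(all_ids) - set(kept_ids))
    if len(kept_ids) == 0:
        raise ValueError("no complete cases remain after filtering")
    report = CompleteCaseReport(dropped_count=len(dropped), dropped_ids=dropped,
                                n_used=len(kept_ids))
    if dropped:
        logger.info("complete_cases dropped %d subjects: %s",
                    len(dropped), dropped)
    out_conf = ConfounderMatrix(values=conf.loc[kept_ids],
                                encoding_map=confounders.encoding_map)
    return feat.loc[kept_ids], out_conf, clinical.loc[kept_ids], report


@dataclass
class StandardizedMatrix:
    """A column-standardized matrix with its affine parameters.

    Each retained column has sample mean 0 and sample standard deviation 1
    (n-1 denominator). ``transform`` applies the training-set affine map to
    new rows; ``inverse_transform`` undoes it.
    """

    values: np.ndarray
    col_means: np.ndarray
    col_scales: np.ndarray
    column_names: list[str]
    dropped_columns: list[tuple[str, str]]

    def transform(self, new: np.ndarray) -> np.ndarray:
        new = np.asarray(new, dtype=float)
        if new.ndim == 1:
            new = new[None, :]
        if new.shape[1] != self.col_means.size:
            raise ValueError(
                f"expected {self.col_means.size} columns, got {new.shape[1]}"
            )
        return (new - self.col_means) / self.col_scales

    def inverse_transform(self, std: np.ndarray) -> np.ndarray:
        return np.asarray(std, dtype=float) * self.col_scales + self.col_means


def standardize(matrix, column_names=None, on_constant: str = "drop",
                ) -> StandardizedMatrix:
    """Center and scale columns to mean 0, sd 1 (n-1 denominator).

    Zero-variance columns are dropped with a warning when
    ``on_constant='drop'`` (the right behavior for high-dimensional feature
    blocks, which routinely contain constants) or raise when
    ``on_constant='error'`` (a constant confounder is a user mistake).
    """
    if isinstance(matrix, pd.DataFrame):
        column_names = list(matrix.columns)
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("standardize expects a 2-D matrix")
    n, d = matrix.shape
    if n < 3:
        raise ValueError(f"need at least 3 rows to standardize, got {n}")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite values")
    if column_names is None:
        column_names = [f"col{j}" for j in range(d)]

    means = matrix.mean(axis=0)
    scales = matrix.std(axis=0, ddof=1)
    constant = scales <= 1e-12 * np.maximum(1.0, np.abs(means))
    if constant.all():
        raise ValueError("all columns have zero variance")
    dropped = [(column_names[j], "zero variance") for j in np.nonzero(constant)[0]]
    if dropped:
        if on_constant == "error":
            raise ValueError(
                "zero-variance columns: " + ", ".join(name for name, _ in dropped)
            )
        logger.warning("dropping %d zero-variance columns: %s",
                       len(dropped), [name for name, _ in dropped])
    keep = ~constant
    values = (matrix[:, keep] - means[keep]) / scales[keep]
    return StandardizedMatrix(
        values=values,
        col_means=means[keep],
        col_scales=scales[keep],
        column_names=[column_names[j] for j in np.nonzero(keep)[0]],
        dropped_columns=dropped,
    )
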