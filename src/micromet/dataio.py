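"""Tabular I/O, metabolite preprocessing, microbiome transform, Shannon diversity.

Metabolite preprocessing follows the standard untargeted-metabolomics chain
for semi-quantitative platforms: drop metabolites measured in fewer than
``min_measurements`` samples, log10-transform, impute remaining missing
cells with the per-metabolite minimum (missingness is predominantly
left-censoring at the detection limit), then standardize each column to
mean 0 / SD 1.  All tables are plain TSV (UTF-8, "NA" or empty = missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A table violates the expected layout (duplicates, non-numeric cells)."""


class AlignmentError(ValueError):
    """Sample IDs do not match across tables."""


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites matrix; ``state`` is 'raw' or 'preprocessed'.

    Preprocessed matrices have no missing cells and every column has
    mean 0 and SD 1 (constant columns are dropped during preprocessing).
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self):
        if self.state not in ("raw", "preprocessed"):
            raise ValueError("state must be 'raw' or 'preprocessed'")
        if self.state == "preprocessed":
            v = self.values.to_numpy()
            if np.isnan(v).any():
                raise ValueError("preprocessed matrix may not contain missing cells")
            if v.shape[1] and (
                np.abs(v.mean(axis=0)).max() > 1e-9
                or np.abs(v.std(axis=0, ddof=1) - 1).max() > 1e-9
            ):
                raise ValueError("preprocessed columns must have mean 0 and SD 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PreprocessReport:
    """Which metabolites were dropped at each preprocessing step and why."""

    dropped_few_measurements: list[str] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)
    n_raw: int = 0
    n_kept: int = 0


def read_table(path, kind: str) -> pd.DataFrame | MetaboliteMatrix:
    """Read a TSV with a ``sample_id`` first column into a typed table.

    ``kind`` is one of 'features', 'metabolites', 'metadata'.  Row order is
    preserved; "NA" and empty cells are missing.  Duplicate sample IDs or
    non-numeric cells (where numeric is expected) raise :class:`FormatError`.
    """
    if kind not in ("features", "metabolites", "metadata"):
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""], keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise FormatError(f"{path}: first column must be 'sample_id'")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate sample IDs {dups}")
    if kind == "metadata":
        out = df.copy()
        for col in out.columns:
            if col == "group":
                continue
            out[col] = _numeric_column(out[col], path, col)
        return out
    num = df.copy()
    for col in num.columns:
        num[col] = _numeric_column(num[col], path, col)
    if kind == "metabolites":
        return MetaboliteMatrix(num, state="raw")
    return num


def _numeric_column(col: pd.Series, path, name) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna()
    if bad.any():
        rows = list(col.index[bad][:5])
        raise FormatError(f"{path}: non-numeric value in column {name!r}, rows {rows}")
    return out


def check_alignment(*tables) -> None:
    """Raise :class:`AlignmentError` unless all tables share one sample set/order."""
    ids = [t.sample_ids if isinstance(t, MetaboliteMatrix) else list(t.index) for t in tables]
    ref = ids[0]
    for other in ids[1:]:
        if other != ref:
            missing = sorted(set(ref) ^ set(other))
            raise AlignmentError(f"sample sets differ; offending IDs: {missing[:10]}")


def preprocess_metabolites(
    raw: MetaboliteMatrix, min_measurements: int = 10
) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Filter / log10 / min-impute / standardize a raw metabolite matrix.

    Metabolites with fewer than ``min_measurements`` non-missing values are
    removed first; remaining values are log10-transformed, missing cells are
    imputed with the column minimum (of the log values), and each column is
    standardized with the sample (n-1) SD.  Constant columns are dropped
    with a warning.  Raw values must be positive where present.
    """
    if raw.state != "raw":
        raise ValueError("expected a raw metabolite matrix")
    vals = raw.values
    report = PreprocessReport(n_raw=vals.shape[1])
    counts = vals.notna().sum(axis=0)
    few = counts < min_measurements
    report.dropped_few_measurements = list(vals.columns[few])
    kept = vals.loc[:, ~few]

    nonpos = (kept <= 0).any()
    if nonpos.any():
        cells = [
            (r, c)
            for c in kept.columns[nonpos]
            for r in kept.index[kept[c] <= 0]
        ]
        raise ValueError(f"non-positive values cannot be log-transformed: {cells[:10]}")
    logv = np.log10(kept)
    logv = logv.fillna(logv.min(axis=0))

    sd = logv.std(axis=0, ddof=1)
    const = (sd == 0) | sd.isna()
    if const.any():
        report.dropped_constant = list(logv.columns[const])
        warnings.warn(
            f"dropping {int(const.sum())} constant metabolite(s) after imputation",
            stacklevel=2,
        )
        logv = logv.loc[:, ~const]
        sd = sd[~const]
    std = (logv - logv.mean(axis=0)) / sd
    report.n_kept = std.shape[1]
    return MetaboliteMatrix(std, state="preprocessed"), report


def filter_diet(diet: pd.DataFrame, max_missing: float = 0.8) -> pd.DataFrame:
    """Drop FFQ columns missing in more than ``max_missing`` of samples and
    impute the remaining missing cells with the column mode."""
    keep = diet.loc[:, diet.isna().mean() <= max_missing].copy()
    for col in keep.columns:
        if keep[col].isna().any():
            mode = keep[col].mode(dropna=True)
            keep[col] = keep[col].fillna(mode.iloc[0] if len(mode) else 0.0)
    return keep


def transform_microbiome(abund: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    """log10(relative abundance + pseudocount) per entry."""
    a = abund.to_numpy()
    if (a < 0).any():
        raise ValueError("negative abundances")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return pd.DataFrame(np.log10(a + pseudocount), index=abund.index, columns=abund.columns)


def inverse_transform_microbiome(logged: pd.DataFrame, pseudocount: float = 1e-6) -> pd.DataFrame:
    return pd.DataFrame(
        np.power(10.0, logged.to_numpy()) - pseudocount,
        index=logged.index,
        columns=logged.columns,
    )


def shannon_index(abund_row: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over one abundance row."""
    p = np.asarray(abund_row, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundance")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("abundances must sum to 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(abund: pd.DataFrame) -> pd.Series:
    """Shannon index for every row of a relative-abundance table."""
    return pd.Series(
        [shannon_index(row) for row in abund.to_numpy()], index=abund.index, name="shannon"
    )
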