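"""Readers, writers and shared preprocessing for expression matrices.

Two in-memory containers are used throughout the package:

``CountExperiment``
    A genes x samples integer count matrix from a paired-condition cell-line
    experiment, together with a sample sheet mapping each sample to its cell
    line, condition (normoxia / hypoxia) and replicate.

``CohortDataset``
    A genes x samples continuous log2 expression matrix for a patient cohort,
    together with a clinical table (time-to-event in years, event indicator,
    covariates and an optional second binary signature label).

Matrices are pandas DataFrames indexed by gene ID with sample IDs as columns;
clinical tables and sample sheets are DataFrames indexed by sample ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: offset added to linear-scale expression before log2 transformation
LOG2_OFFSET = 0.25

CONDITIONS = ("normoxia", "hypoxia")


@dataclass
class CountExperiment:
    """Integer count matrix with per-sample annotations for one cell line."""

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        validate_count_experiment(self.counts, self.sample_sheet)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def condition(self) -> pd.Series:
        """Condition label per sample, ordered as the count columns."""
        return self.sample_sheet.loc[self.counts.columns, "condition"]

    def write(self, counts_path, sample_sheet_path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t")
        sheet = self.sample_sheet.copy()
        sheet.index.name = "sample_id"
        sheet.to_csv(sample_sheet_path)


@dataclass
class CohortDataset:
    """Log2 expression matrix plus clinical table for one patient cohort."""

    expr: pd.DataFrame
    clinical: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        validate_cohort(self.expr, self.clinical)

    @property
    def gene_ids(self) -> pd.Index:
        return self.expr.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr.columns

    def write(self, expr_path, clinical_path) -> None:
        out = self.expr.copy()
        out.index.name = "gene_id"
        out.to_csv(expr_path, sep="\t")
        clin = self.clinical.copy()
        clin.index.name = "sample_id"
        clin.to_csv(clinical_path)


def validate_count_experiment(counts: pd.DataFrame, sample_sheet: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene IDs after collapsing: {dups}")
    missing = counts.columns.difference(sample_sheet.index)
    if len(missing) > 0:
        raise ValidationError(f"sample sheet missing sample IDs: {list(missing)}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            bad = counts.index[np.where(~np.isclose(arr, np.round(arr)))[0][:5]]
            raise ValidationError(f"non-integer counts in rows: {list(bad)}")
    if (arr < 0).any():
        bad = counts.index[np.where((arr < 0).any(axis=1))[0][:5]]
        raise ValidationError(f"negative counts in rows: {list(bad)}")
    cond = sample_sheet.loc[counts.columns, "condition"]
    unknown = set(cond.unique()) - set(CONDITIONS)
    if unknown:
        raise ValidationError(
            f"unknown condition labels {sorted(unknown)}; expected one of {CONDITIONS}"
        )
    if cond.nunique() > 2:
        raise ValidationError("more than two condition levels")


def validate_cohort(expr: pd.DataFrame, clinical: pd.DataFrame) -> None:
    if expr.isna().to_numpy().any():
        raise ValidationError("missing expression values in cohort matrix")
    missing = expr.columns.difference(clinical.index)
    if len(missing) > 0:
        raise ValidationError(f"clinical table missing sample IDs: {list(missing)}")
    if "time_years" in clinical.columns:
        t = clinical.loc[expr.columns, "time_years"]
        if (t < 0).any() or not np.isfinite(t.to_numpy(dtype=float)).all():
            raise ValidationError("survival times must be finite and >= 0")
    if "event" in clinical.columns:
        ev = set(pd.unique(clinical.loc[expr.columns, "event"]))
        if not ev <= {0, 1}:
            raise ValidationError(f"event indicator must be 0/1, found {sorted(ev)}")


def collapse_duplicate_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a gene ID to their per-sample median.

    Mirrors the convention of taking median expression when multiple probe
    sets (or annotation rows) map to the same gene.
    """
    if not matrix.index.has_duplicates:
        return matrix
    return matrix.groupby(level=0, sort=False).median()


def read_count_matrix(path, sample_sheet_path) -> CountExperiment:
    """Read a genes x samples count TSV and its sample sheet CSV.

    Duplicate gene rows are collapsed by median. Raises
    :class:`ValidationError` on dimension mismatches, negative or
    non-integer counts, or unknown condition labels.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts = collapse_duplicate_genes(counts)
    # medians of integer pairs can be half-integers; keep integer dtype when exact
    arr = counts.to_numpy()
    if np.allclose(arr, np.round(arr)):
        counts = counts.round().astype(np.int64)
    sheet = pd.read_csv(sample_sheet_path, index_col=0)
    return CountExperiment(counts=counts, sample_sheet=sheet)


def read_cohort(expr_path, clinical_path, name: str = "cohort") -> CohortDataset:
    """Read a cohort log2 expression TSV and clinical CSV."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr = collapse_duplicate_genes(expr)
    clinical = pd.read_csv(clinical_path, index_col=0)
    return CohortDataset(expr=expr, clinical=clinical, name=name)


def log2_transform(linear: pd.DataFrame, offset: float = LOG2_OFFSET) -> pd.DataFrame:
    """log2(x + offset) for linear-scale expression (e.g. TPM)."""
    if (linear.to_numpy() < 0).any():
        raise ValidationError("linear-scale expression must be non-negative")
    return np.log2(linear + offset)


def log2_median_center(expr: pd.DataFrame) -> pd.DataFrame:
    """Center each gene row at its median (input already on log2 scale)."""
    if expr.size == 0:
        raise ValidationError("cannot median-center an empty matrix")
    return expr.sub(expr.median(axis=1), axis=0)


def intersect_genes(*matrices: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict all matrices to their shared gene IDs, preserving the order
    of the first matrix. Cross-cohort analyses use only shared genes."""
    if not matrices:
        return []
    shared = matrices[0].index
    for m in matrices[1:]:
        shared = shared.intersection(m.index)
    if len(shared) == 0:
        raise ValidationError("gene-ID intersection across datasets is empty")
    return [m.loc[shared] for m in matrices]
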