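"""Loading, cleaning and merging of protein-expression and clinical tables.

The expression input follows the TCPA level-4 layout: one row per tumor
sample, one identifier column, one cancer-type column, and the remaining
columns real-valued normalized protein abundances (log-like scale) with
``NA`` marking missing measurements.  The clinical input follows the TCGA
phenotype layout (age, sex, race, AJCC stage, overall-survival status and
time).  Cleaning rules: drop any protein missing in more than a fraction of
samples (default one half, strict), mean-impute the rest, and inner-join
expression to clinical on a truncated barcode prefix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinMatrix",
    "ClinicalTable",
    "MergedDataset",
    "load_protein_matrix",
    "load_clinical_table",
    "subset_by_classes",
    "filter_missing_proteins",
    "impute_missing_mean",
    "merge_clinical",
    "parse_stage",
]

#: Cell tokens treated as missing on input, in addition to empty cells.
NA_TOKENS = ["NA", "NaN", "nan", "null", "None", ""]


class InputError(ValueError):
    """Raised when an input table violates a documented precondition."""


class ConfigurationError(ValueError):
    """Raised when a requested column or option does not exist."""


@dataclass
class ProteinMatrix:
    """Samples x proteins abundance table with per-sample class labels.

    ``values`` is a float DataFrame indexed by sample ID with protein IDs as
    columns; NaN encodes a missing measurement.  ``class_labels`` is aligned
    to the same index.  ``classes`` fixes the (ordered) two-class set once a
    binary subset has been taken; the order defines which class is "class 1"
    in downstream two-group statistics.
    """

    values: pd.DataFrame
    class_labels: pd.Series
    classes: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample IDs: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate protein IDs: {dups}")
        if not self.class_labels.index.equals(self.values.index):
            self.class_labels = self.class_labels.reindex(self.values.index)
            if self.class_labels.isna().any():
                raise InputError("class_labels do not cover every sample")
        if self.classes is not None:
            extra = set(self.class_labels.unique()) - set(self.classes)
            if extra:
                raise InputError(f"labels outside the declared class set: {sorted(extra)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def select_proteins(self, proteins: Sequence[str]) -> "ProteinMatrix":
        missing = [p for p in proteins if p not in self.values.columns]
        if missing:
            raise InputError(f"unknown proteins: {missing}")
        return ProteinMatrix(self.values[list(proteins)].copy(), self.class_labels.copy(), self.classes)

    def to_tsv(self, path: str | Path, type_column: str = "Cancer_Type") -> None:
        out = self.values.copy()
        out.insert(0, type_column, self.class_labels)
        out.to_csv(path, sep="\t", index_label="Sample_ID")


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates and overall-survival endpoints.

    Canonical columns: ``age_years``, ``sex``, ``race``, ``stage_ordinal``
    (1-4), ``os_status`` (0 alive / 1 dead), ``os_time_days``; the frame is
    indexed by sample ID.  Missing values stay NaN and are handled
    complete-case per downstream analysis.
    """

    data: pd.DataFrame

    CANONICAL = ["age_years", "sex", "race", "stage_ordinal", "os_status", "os_time_days"]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate clinical sample IDs: {dups}")
        for col in self.CANONICAL:
            if col not in self.data.columns:
                self.data[col] = np.nan
        # survival time must accompany a recorded status
        bad = self.data["os_status"].notna() & self.data["os_time_days"].isna()
        if bad.any():
            raise InputError(
                f"os_status without os_time_days for {self.data.index[bad].tolist()}"
            )
        stage = self.data["stage_ordinal"].dropna()
        if not stage.isin([1, 2, 3, 4]).all():
            raise InputError("stage_ordinal outside 1-4")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class MergedDataset:
    """A ProteinMatrix and a ClinicalTable row-aligned on the same samples."""

    expression: ProteinMatrix
    clinical: ClinicalTable
    unmatched_expression: list[str] = field(default_factory=list)
    unmatched_clinical: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.expression.values.index) != list(self.clinical.data.index):
            raise InputError("expression and clinical tables are not row-aligned")

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples


def _read_delimited(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    if delimiter is None:
        # sniff between comma and tab from the header line
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=delimiter, na_values=NA_TOKENS, keep_default_na=True)


def load_protein_matrix(
    path: str | Path,
    id_column: str = "Sample_ID",
    type_column: str = "Cancer_Type",
    delimiter: str | None = None,
) -> ProteinMatrix:
    """Read a TCPA-style expression table into a :class:`ProteinMatrix`.

    Every column other than ``id_column`` and ``type_column`` is parsed as a
    protein; unparseable cells and NA tokens become missing values.
    """
    df = _read_delimited(path, delimiter)
    for col in (id_column, type_column):
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not found in {path}")
    if df[id_column].duplicated().any():
        dups = df.loc[df[id_column].duplicated(), id_column].unique().tolist()
        raise InputError(f"duplicate sample IDs in {path}: {dups}")
    df = df.set_index(id_column)
    labels = df[type_column].astype(str)
    values = df.drop(columns=[type_column]).apply(pd.to_numeric, errors="coerce")
    return ProteinMatrix(values=values, class_labels=labels)


_STAGE_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


def parse_stage(label: object) -> float:
    """Map an AJCC stage string to its main-stage ordinal 1-4.

    Substage letters collapse to the main stage ("Stage IIIB" -> 3);
    unreported or unrecognized labels map to NaN (the latter with a
    warning, not a failure).
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return np.nan
    text = str(label).strip().lower()
    if text in ("", "not reported", "unknown", "na", "nan", "[not available]"):
        return np.nan
    m = re.match(r"^(?:ajcc\s+)?(?:pathologic\s+)?stage\s*([ivx]+)\s*[a-c]?[0-9]?$", text)
    if m is None:
        m = re.match(r"^([ivx]+)\s*[a-c]?$", text)
    if m is not None and m.group(1) in _STAGE_ROMAN:
        return float(_STAGE_ROMAN[m.group(1)])
    logger.warning("unrecognized stage label %r treated as missing", label)
    return np.nan


def load_clinical_table(
    path: str | Path,
    id_column: str = "sample",
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> ClinicalTable:
    """Read a TCGA-phenotype-style clinical table.

    ``column_map`` maps canonical names (``age_years``, ``sex``, ``race``,
    ``stage``, ``os_status``, ``os_time_days``) to columns in the file; any
    canonical field absent from the map (and the file) is left missing.
    Stage labels pass through :func:`parse_stage`.
    """
    defaults = {
        "age_years": "age",
        "sex": "gender",
        "race": "race",
        "stage": "stage",
        "os_status": "OS",
        "os_time_days": "OS.time",
    }
    cmap = {**defaults, **(column_map or {})}
    df = _read_delimited(path, delimiter)
    if id_column not in df.columns:
        raise ConfigurationError(f"column {id_column!r} not found in {path}")
    if df[id_column].duplicated().any():
        dups = df.loc[df[id_column].duplicated(), id_column].unique().tolist()
        raise InputError(f"duplicate sample IDs in {path}: {dups}")
    out = pd.DataFrame(index=df[id_column].astype(str))
    for canon in ("age_years", "os_status", "os_time_days"):
        col = cmap.get(canon)
        out[canon] = (
            pd.to_numeric(df[col], errors="coerce").to_numpy() if col in df.columns else np.nan
        )
    for canon in ("sex", "race"):
        col = cmap.get(canon)
        out[canon] = df[col].astype(str).str.lower().to_numpy() if col in df.columns else np.nan
    stage_col = cmap.get("stage")
    if stage_col in df.columns:
        out["stage_ordinal"] = [parse_stage(v) for v in df[stage_col]]
    else:
        out["stage_ordinal"] = np.nan
    return ClinicalTable(out)


def subset_by_classes(pm: ProteinMatrix, keep: Sequence[str]) -> ProteinMatrix:
    """Retain only samples whose class label is in ``keep``.

    Protein columns are untouched.  When exactly two labels are kept their
    order is recorded as the declared class order for downstream two-group
    statistics.
    """
    keep = list(dict.fromkeys(keep))
    present = set(pm.class_labels.unique())
    absent = [k for k in keep if k not in present]
    if absent:
        raise InputError(f"class labels not present in the matrix: {absent}")
    mask = pm.class_labels.isin(keep)
    classes = (keep[0], keep[1]) if len(keep) == 2 else pm.classes
    return ProteinMatrix(pm.values.loc[mask].copy(), pm.class_labels.loc[mask].copy(), classes)


def filter_missing_proteins(
    pm: ProteinMatrix, max_missing_frac: float = 0.5
) -> tuple[ProteinMatrix, list[str]]:
    """Drop proteins missing in strictly more than ``max_missing_frac`` of samples.

    Returns the filtered matrix and the list of dropped protein names.  The
    boundary case (missing fraction exactly equal to the threshold) is kept.
    """
    frac = pm.values.isna().mean(axis=0)
    dropped = list(frac.index[frac > max_missing_frac])
    if dropped:
        logger.info("dropping %d proteins over the %.0f%% missingness threshold: %s",
                    len(dropped), 100 * max_missing_frac, dropped)
    kept = pm.values.drop(columns=dropped)
    return ProteinMatrix(kept, pm.class_labels.copy(), pm.classes), dropped


def impute_missing_mean(
    pm: ProteinMatrix, per_class: bool = False
) -> tuple[ProteinMatrix, list[str]]:
    """Replace each missing entry by its protein's mean over observed samples.

    Means pool both classes by default; ``per_class=True`` imputes within
    each class label instead.  Returns the completed matrix and the list of
    proteins that required imputation.
    """
    all_missing = pm.values.columns[pm.values.isna().all(axis=0)].tolist()
    if all_missing:
        raise RuntimeError(
            f"all-missing proteins reached imputation (filter first): {all_missing}"
        )
    imputed = pm.values.columns[pm.values.isna().any(axis=0)].tolist()
    if per_class:
        values = pm.values.groupby(pm.class_labels, group_keys=False).apply(
            lambda g: g.fillna(g.mean())
        )
        values = values.loc[pm.values.index]
    else:
        values = pm.values.fillna(pm.values.mean())
    return ProteinMatrix(values, pm.class_labels.copy(), pm.classes), imputed


def merge_clinical(
    pm: ProteinMatrix, ct: ClinicalTable, id_match_len: int = 15
) -> MergedDataset:
    """Inner-join expression and clinical rows on truncated sample barcodes.

    TCGA barcodes carry trailing aliquot fields, so identifiers are compared
    after truncation to ``id_match_len`` characters (15 keeps the sample
    suffix, 12 keeps only the patient).  Unmatched samples on either side
    are reported on the result, never silently discarded.
    """
    pm_keys = pd.Index([s[:id_match_len] for s in pm.values.index])
    ct_keys = pd.Index([s[:id_match_len] for s in ct.data.index])
    for side, keys, original in (("expression", pm_keys, pm.values.index),
                                 ("clinical", ct_keys, ct.data.index)):
        if keys.has_duplicates:
            coll = keys[keys.duplicated()].unique().tolist()
            raise InputError(
                f"truncation to {id_match_len} chars collides {side} IDs: {coll}"
            )
    common = pm_keys.intersection(ct_keys)
    if len(common) == 0:
        logger.warning("no samples match between expression and clinical tables")
    unmatched_pm = [s for s, k in zip(pm.values.index, pm_keys) if k not in set(common)]
    unmatched_ct = [s for s, k in zip(ct.data.index, ct_keys) if k not in set(common)]
    if unmatched_pm:
        logger.info("%d expression samples had no clinical match", len(unmatched_pm))
    if unmatched_ct:
        logger.info("%d clinical samples had no expression match", len(unmatched_ct))

    pm_order = [s for s, k in zip(pm.values.index, pm_keys) if k in set(common)]
    key_of = dict(zip(pm_keys, pm.values.index))
    expr = ProteinMatrix(
        pm.values.loc[pm_order].copy(), pm.class_labels.loc[pm_order].copy(), pm.classes
    )
    ct_by_key = ct.data.set_axis(ct_keys, axis=0)
    clin_rows = ct_by_key.loc[[s[:id_match_len] for s in pm_order]]
    clin_rows.index = pd.Index(pm_order)
    return MergedDataset(expr, ClinicalTable(clin_rows), unmatched_pm, unmatched_ct)
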