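"""Reading MAF variant tables and deriving per-sample mutation burdens.

A MAF (Mutation Annotation Format) file is a tab-separated table with one
row per somatic variant call.  The GDC dialect is assumed: ``#``-prefixed
comment lines (e.g. ``#version``), a header row, and at minimum the
columns listed in :data:`REQUIRED_MAF_COLUMNS`.  Only per-sample counts
are used downstream; positions stay 1-based as in the file and are never
converted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MafFormatError",
    "REQUIRED_MAF_COLUMNS",
    "MutationCountCohort",
    "read_maf",
    "write_maf",
    "count_mutations_per_sample",
    "attach_metadata",
    "group_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

REQUIRED_MAF_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
)

#: Key identifying one variant for deduplication of concatenated MAFs.
_DEDUP_KEY = ["Tumor_Sample_Barcode", "Chromosome", "Start_Position", "Tumor_Seq_Allele2"]


class MafFormatError(ValueError):
    """Raised when a MAF file lacks a required column."""


@dataclass
class MutationCountCohort:
    """Per-sample somatic mutation counts for one cancer type.

    ``metadata``, when present, is a DataFrame indexed by ``sample_ids``
    with optional columns such as ``age_at_diagnosis`` (years),
    ``subtype`` and ``stage``.
    """

    cancer_type: str
    counts: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if not self.sample_ids:
            self.sample_ids = [f"S{i:05d}" for i in range(len(self.counts))]
        if len(self.sample_ids) != len(self.counts):
            raise ValueError("counts and sample_ids must have the same length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if np.any(self.counts < 0):
            raise ValueError("mutation counts must be non-negative")
        if self.metadata is not None:
            self.metadata = self.metadata.reindex(self.sample_ids)

    @property
    def n(self) -> int:
        return len(self.counts)

    def subset(self, indices: Iterable[int], cancer_type: str | None = None) -> "MutationCountCohort":
        """Cohort restricted to the given sample positions (order kept)."""
        idx = list(indices)
        meta = self.metadata.iloc[idx] if self.metadata is not None else None
        return MutationCountCohort(
            cancer_type=cancer_type or self.cancer_type,
            counts=self.counts[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            metadata=meta,
        )


def read_maf(path) -> pd.DataFrame:
    """Read a GDC-dialect MAF into a DataFrame, one row per variant call.

    ``#``-prefixed lines are skipped.  Raises :class:`MafFormatError`
    naming the first missing required column; a file with no data rows
    returns an empty frame with a warning.  Extra columns are preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"MAF file {path} contains no data", stacklevel=2)
        return pd.DataFrame(columns=list(REQUIRED_MAF_COLUMNS))
    for col in REQUIRED_MAF_COLUMNS:
        if col not in df.columns:
            raise MafFormatError(f"MAF file {path} is missing required column {col!r}")
    if df.empty:
        warnings.warn(f"MAF file {path} contains a header but no records", stacklevel=2)
    df["Start_Position"] = df["Start_Position"].astype(np.int64)
    if (df["Start_Position"] < 1).any():
        raise MafFormatError("Start_Position must be >= 1 (MAF is 1-based)")
    return df


def write_maf(records: pd.DataFrame, path) -> None:
    """Write variant records back out as tab-separated MAF."""
    records.to_csv(path, sep="\t", index=False)


def count_mutations_per_sample(
    records: pd.DataFrame,
    exclude_classifications: Iterable[str] = (),
    deduplicate: bool = True,
    cancer_type: str = "",
) -> MutationCountCohort:
    """Per-sample somatic mutation counts from MAF records.

    All variant rows are counted by default (the exome-scale G already
    accounts for synonymous changes); pass e.g. ``{"Silent"}`` to restrict
    to protein-altering calls.  With ``deduplicate`` (default), rows
    identical in (sample, chromosome, position, alternate allele) are
    collapsed to one, which makes counts robust to concatenated MAFs.
    Samples whose calls are all excluded keep a count of 0.
    """
    if records.empty:
        return MutationCountCohort(cancer_type=cancer_type, counts=np.array([], dtype=int))
    all_samples = sorted(records["Tumor_Sample_Barcode"].unique())
    kept = records
    excl = set(exclude_classifications)
    if excl:
        kept = kept[~kept["Variant_Classification"].isin(excl)]
    if deduplicate:
        kept = kept.drop_duplicates(subset=_DEDUP_KEY)
    counts = kept.groupby("Tumor_Sample_Barcode").size().reindex(all_samples, fill_value=0)
    return MutationCountCohort(
        cancer_type=cancer_type,
        counts=counts.to_numpy(),
        sample_ids=list(counts.index),
    )


def attach_metadata(
    cohort: MutationCountCohort,
    table: pd.DataFrame,
    id_column: str,
    barcode_prefix_len: int | None = 12,
) -> MutationCountCohort:
    """Join per-sample metadata onto a cohort.

    TCGA clinical tables are keyed by patient (the first 12 characters of
    the sample barcode); ``barcode_prefix_len`` controls how much of the
    cohort's sample ID is used as the join key (``None`` = whole ID).
    """
    if id_column not in table.columns:
        raise KeyError(f"metadata table has no column {id_column!r}; available: {list(table.columns)}")
    keyed = table.set_index(id_column)
    keys = [
        s[:barcode_prefix_len] if barcode_prefix_len else s for s in cohort.sample_ids
    ]
    meta = keyed.reindex(keys)
    meta.index = pd.Index(cohort.sample_ids)
    return replace(cohort, metadata=meta)


def group_cohort(
    cohort: MutationCountCohort, by: str, unknown_label: str = "unknown"
) -> Mapping[str, MutationCountCohort]:
    """Partition a cohort by a metadata column (e.g. subtype or stage).

    Samples with a missing value fall into the ``unknown_label`` group;
    the groups plus that group always partition the input.
    """
    if cohort.metadata is None or by not in cohort.metadata.columns:
        available = [] if cohort.metadata is None else list(cohort.metadata.columns)
        raise KeyError(f"no metadata column {by!r}; available: {available}")
    labels = cohort.metadata[by]
    groups: dict[str, MutationCountCohort] = {}
    order = np.arange(cohort.n)
    missing = labels.isna().to_numpy()
    for value in pd.unique(labels.dropna()):
        idx = order[(labels == value).to_numpy()]
        groups[str(value)] = cohort.subset(idx, cancer_type=f"{cohort.cancer_type}/{value}")
    if missing.any():
        groups[unknown_label] = cohort.subset(
            order[missing], cancer_type=f"{cohort.cancer_type}/{unknown_label}"
        )
    return groups


def write_cohort_csv(cohort: MutationCountCohort, path) -> None:
    """Serialize a cohort as CSV: sample_id, count, then metadata columns."""
    df = pd.DataFrame({"sample_id": cohort.sample_ids, "count": cohort.counts})
    if cohort.metadata is not None:
        df = df.join(cohort.metadata.reset_index(drop=True))
    df.to_csv(path, index=False)


def read_cohort_csv(path, cancer_type: str = "") -> MutationCountCohort:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    for col in ("sample_id", "count"):
        if col not in df.columns:
            raise ValueError(f"cohort CSV {path} is missing column {col!r}")
    meta_cols = [c for c in df.columns if c not in ("sample_id", "count")]
    meta = None
    if meta_cols:
        meta = df[meta_cols].copy()
        meta.index = pd.Index(df["sample_id"].astype(str))
    return MutationCountCohort(
        cancer_type=cancer_type,
        counts=df["count"].to_numpy(),
        sample_ids=[str(s) for s in df["sample_id"]],
        metadata=meta,
    )
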