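"""Data model, file I/O and pre-filtering for longitudinal count tables.

The central object is a feature-by-sample count table ``C`` (m features in
rows, n samples in columns) together with per-sample metadata: collection
time, phenotypic group (exactly two levels) and subject ID.  Times are
arbitrary non-negative reals — nothing assumes integer or equally spaced
time points, and subjects may contribute different numbers of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable", "SampleMetadata", "FeatureSeries",
    "read_counts", "write_counts", "read_metadata", "validate_metadata",
    "filter_low_abundance", "extract_feature",
]


@dataclass
class CountTable:
    """m x n matrix of (possibly normalized, hence fractional) read counts.

    Raw counts are non-negative integers; after between-sample normalization
    entries may be fractional but never negative.
    """

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        m, n = self.counts.shape
        if m < 1 or n < 2:
            raise ValueError(f"need at least 1 feature and 2 samples, got {m}x{n}")
        if len(self.feature_ids) != m or len(self.sample_ids) != n:
            raise ValueError("ID lengths do not match matrix dimensions")
        if len(set(self.feature_ids)) != m:
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite entries")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative entries")

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids,
                            columns=self.sample_ids)

    def row(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature ID: {feature_id!r}") from None
        return self.counts[i]


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's annotations: subject, phenotypic group and collection time.

    The time unit is the user's choice (hours, days, weeks, months or years);
    only relative spacing matters.
    """

    sample_id: str
    subject_id: str
    group: str
    time: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: time must be a non-negative real, "
                f"got {self.time!r}")


@dataclass
class FeatureSeries:
    """One feature's longitudinal observations joined with sample metadata."""

    feature_id: str
    times: np.ndarray
    groups: np.ndarray       # object array of group labels
    subjects: np.ndarray     # object array of subject IDs
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)
        n = len(self.times)
        if not (len(self.counts) == len(self.groups) == len(self.subjects) == n):
            raise ValueError("field lengths differ")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def group_levels(self) -> list[str]:
        return sorted(set(self.groups.tolist()))

    def subset(self, mask: np.ndarray) -> "FeatureSeries":
        return FeatureSeries(self.feature_id, self.times[mask],
                             self.groups[mask], self.subjects[mask],
                             self.counts[mask])

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.groups], dtype=bool)


def _sniff_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_counts(path: str, delimiter: str | None = None,
                transpose: bool = False) -> CountTable:
    """Read a count table: first column feature IDs, header row sample IDs.

    Parameters
    ----------
    path : str
        TSV or CSV file (delimiter inferred from the extension unless given).
    transpose : bool
        Set when the file stores samples in rows and features in columns.
    """
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False, comment="#")
    if transpose:
        df = df.T
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric count {raw!r} at feature {df.index[i]!r}, "
                    f"sample {col!r}") from None
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dupes}")
    return CountTable(values, list(df.index), list(df.columns))


def write_counts(table: CountTable, path: str,
                 delimiter: str | None = None) -> None:
    """Write a count table in the same dialect ``read_counts`` accepts."""
    sep = _sniff_delimiter(path, delimiter)
    table.to_frame().to_csv(path, sep=sep, index_label="feature_id")


REQUIRED_META_COLUMNS = ("sample_id", "subject_id", "group", "time")


def read_metadata(path: str, delimiter: str | None = None,
                  table: CountTable | None = None) -> list[SampleMetadata]:
    """Read and validate per-sample metadata.

    Requires columns sample_id, subject_id, group and time; checks the
    two-group design and (when `table` is given) coverage of its samples.
    """
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    missing = [c for c in REQUIRED_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    meta = []
    for _, r in df.iterrows():
        try:
            t = float(r["time"])
        except (TypeError, ValueError):
            raise ValueError(
                f"sample {r['sample_id']!r}: non-numeric time {r['time']!r}"
            ) from None
        meta.append(SampleMetadata(str(r["sample_id"]), str(r["subject_id"]),
                                   str(r["group"]), t))
    validate_metadata(meta, table)
    return meta


def validate_metadata(meta: Sequence[SampleMetadata],
                      table: CountTable | None = None) -> tuple[str, str]:
    """Check two-group design invariants; return the (sorted) group levels."""
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    levels = sorted({m.group for m in meta})
    if len(levels) != 2:
        raise ValueError(
            f"exactly two phenotypic groups required, found {len(levels)}: "
            f"{levels}")
    subject_groups: dict[str, str] = {}
    for m in meta:
        prev = subject_groups.setdefault(m.subject_id, m.group)
        if prev != m.group:
            raise ValueError(
                f"subject {m.subject_id!r} appears in both groups "
                f"({prev!r} and {m.group!r})")
    for level in levels:
        n_subj = len({m.subject_id for m in meta if m.group == level})
        if n_subj < 2:
            raise ValueError(
                f"group {level!r} has {n_subj} subject(s); need at least 2")
    if table is not None:
        known = set(ids)
        absent = [s for s in table.sample_ids if s not in known]
        if absent:
            raise ValueError(f"samples without metadata: {absent}")
    return (levels[0], levels[1])


def filter_low_abundance(table: CountTable, min_total: float = 5.0) -> CountTable:
    """Drop features whose total count across all samples is below `min_total`.

    The default of 5 reads removes the rare features whose trajectories carry
    essentially no information. Idempotent; monotone in the threshold.
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    keep = table.counts.sum(axis=1) >= min_total
    if not keep.any():
        raise ValueError(
            f"min_total={min_total} removed every feature; lower the threshold")
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    return CountTable(table.counts[keep], kept_ids, list(table.sample_ids))


def extract_feature(table: CountTable, meta: Sequence[SampleMetadata],
                    feature_id: str) -> FeatureSeries:
    """Join one feature's count row with the metadata, aligned by sample_id."""
    row = table.row(feature_id)
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    recs = [by_id[s] for s in table.sample_ids]
    return FeatureSeries(
        feature_id,
        times=[r.time for r in recs],
        groups=[r.group for r in recs],
        subjects=[r.subject_id for r in recs],
        counts=row,
    )


def write_metadata(meta: Sequence[SampleMetadata], path: str,
                   delimiter: str | None = None) -> None:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.DataFrame({
        "sample_id": [m.sample_id for m in meta],
        "subject_id": [m.subject_id for m in meta],
        "group": [m.group for m in meta],
        "time": [m.time for m in meta],
    })
    df.to_csv(path, sep=sep, index=False)
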