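"""Feature tables, sample metadata and read-mapping tables.

The central container is :class:`FeatureTable`, a samples × features matrix of
absolute counts or relative abundances, together with :class:`SampleMetadata`
describing each sample's subject, age group and time point.  Everything else in
the package consumes these two objects.

Files are plain tab-separated text with a header row; lines starting with
``#`` are ignored (except a leading ``#OTU ID`` header in BIOM-style exports).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "to_relative",
    "aggregate_median_by_subject",
    "read_readmap",
    "taxon_contribution",
    "UNASSIGNED_LABEL",
]

#: Reserved taxon label for reads without a taxonomic annotation.
UNASSIGNED_LABEL = "UNASSIGNED"

_REL_TOL = 1e-9


@dataclass
class FeatureTable:
    """Samples × features abundance matrix.

    Parameters
    ----------
    data
        DataFrame with sample identifiers as the index and feature
        identifiers as columns.  Entries must be non-negative.
    mode
        ``"counts"`` for absolute abundances, ``"relative"`` for rows that
        each sum to one.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("feature table body must be numeric")
        if np.isnan(values).any():
            raise ValueError("feature table contains missing values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _REL_TOL
            if bad.any():
                raise ValueError(
                    "relative-mode rows must sum to 1; offending samples: "
                    f"{self.data.index[bad].tolist()[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_relative(self) -> "FeatureTable":
        return to_relative(self)


@dataclass
class SampleMetadata:
    """Per-sample metadata: subject, age group, time point and optional extras.

    ``data`` is indexed by sample identifier and must contain columns
    ``subject_id``, ``group`` and ``timepoint`` (integers starting at 1).
    Optional columns: ``age`` and one column per named event holding values
    ``before`` / ``after`` (missing for subjects that never undergo it).
    """

    data: pd.DataFrame

    REQUIRED = ("subject_id", "group", "timepoint")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in metadata")
        self.data = self.data.copy()
        self.data["timepoint"] = self.data["timepoint"].astype(int)
        dup = self.data.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            pairs = self.data.loc[dup, ["subject_id", "timepoint"]].values.tolist()
            raise ValueError(f"repeated (subject, timepoint) pairs: {pairs[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, table: FeatureTable) -> None:
        """Raise if any table sample lacks a metadata row."""
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)])


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None, dtype=str,
                     keep_default_na=False)
    # drop comment lines but keep a BIOM-style '#OTU ID' header row intact
    df = df[~df.index.astype(str).str.startswith("#")]
    return df


def read_feature_table(path, orientation: str = "samples") -> FeatureTable:
    """Read a delimited feature table into counts mode.

    Parameters
    ----------
    path
        Tab-separated file with identifier header row and column.
    orientation
        ``"samples"`` if rows are samples, ``"features"`` if rows are
        features (the table is transposed into the canonical samples × features
        layout).
    """
    if orientation not in ("samples", "features"):
        raise ValueError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    raw = _read_tsv(path)
    body = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            body[:, j] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()][0]
            raise ValueError(
                f"malformed numeric cell at row {bad!r}, column {col!r} in {path}"
            ) from None
    df = pd.DataFrame(body, index=raw.index.astype(str), columns=raw.columns.astype(str))
    if orientation == "features":
        df = df.T
    df.index.name = "sample_id"
    return FeatureTable(df, mode="counts")


def write_feature_table(table: FeatureTable, path, orientation: str = "samples",
                        biom_style: bool = False) -> None:
    """Write a feature table as TSV; ``biom_style`` emits feature rows with an
    ``#OTU ID`` header for interoperability."""
    df = table.data
    if biom_style:
        out = df.T.copy()
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")
        return
    if orientation == "features":
        df = df.T
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def to_relative(table: FeatureTable) -> FeatureTable:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    if table.mode == "relative":
        return table
    values = table.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise ValueError(
            f"all-zero sample rows cannot be normalized: {table.data.index[zero].tolist()}"
        )
    rel = values / sums[:, None]
    # enforce exact unit sums against accumulated rounding
    rel /= rel.sum(axis=1)[:, None]
    return FeatureTable(pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
                        mode="relative")


def aggregate_median_by_subject(
    table: FeatureTable,
    meta: SampleMetadata,
    event: Optional[str] = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Collapse samples to per-subject median relative abundance profiles.

    With ``event`` given, each subject contributes one aggregated row per side
    of the event (``before`` / ``after``), and every subject must have at
    least one sample on each side.  Median rows are re-normalized to sum to 1
    because per-feature medians of compositions generally do not.

    Returns the aggregated relative-mode table and a label frame with columns
    ``subject_id``, ``group`` and (if ``event``) ``event_status``.
    """
    if table.mode != "relative":
        raise ValueError("aggregate_median_by_subject requires a relative-mode table")
    meta.require_samples(table)
    md = meta.data.loc[table.data.index]
    if event is not None:
        if event not in md.columns:
            raise ValueError(f"event column {event!r} missing from metadata")
        keys = list(zip(md["subject_id"], md[event]))
        sides = sorted({s for _, s in keys if pd.notna(s) and s != ""})
        if not set(sides) <= {"after", "before"}:
            raise ValueError(f"event column {event!r} must hold 'before'/'after', got {sides}")
    rows, labels = [], []
    for subject, sub_md in md.groupby("subject_id", sort=True):
        group = sub_md["group"].iloc[0]
        if event is None:
            chunks = [(None, sub_md.index)]
        else:
            status = sub_md[event]
            chunks = [(side, sub_md.index[status == side]) for side in ("before", "after")]
            for side, idx in chunks:
                if len(idx) == 0:
                    raise ValueError(
                        f"subject {subject!r} has no samples {side} event {event!r}"
                    )
        for side, idx in chunks:
            med = table.data.loc[idx].median(axis=0)
            total = med.sum()
            if total <= 0:
                raise ValueError(f"median profile of subject {subject!r} is all zero")
            rows.append(med / total)
            row_id = subject if side is None else f"{subject}:{side}"
            lab = {"subject_id": subject, "group": group}
            if side is not None:
                lab["event_status"] = side
            labels.append(pd.Series(lab, name=row_id))
    agg = pd.DataFrame(rows)
    agg.index = [s.name for s in labels]
    agg.index.name = "sample_id"
    out = FeatureTable(agg, mode="relative")
    return out, pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# read → (taxon, function) mapping tables

_READMAP_COLS = ["read_id", "sample_id", "orf_id", "function_id", "taxon_label"]


def read_readmap(path) -> pd.DataFrame:
    """Read a 5-column TSV relating each read to its ORF, function and taxon."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _READMAP_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"read map missing columns: {missing}")
    dup = df.duplicated(subset=["sample_id", "read_id"])
    if dup.any():
        raise ValueError(
            f"read identifiers repeated within a sample: "
            f"{df.loc[dup, ['sample_id', 'read_id']].values.tolist()[:5]}"
        )
    return df[_READMAP_COLS]


def taxon_contribution(readmap: pd.DataFrame) -> pd.DataFrame:
    """Percentage of reads each taxon contributes to each ORF in each sample.

    Reads lacking a taxon annotation are grouped under ``UNASSIGNED``.  Within
    every (sample, ORF) the percentages sum to 100.
    """
    if len(readmap) == 0:
        raise ValueError("read map is empty")
    rm = readmap.copy()
    taxon = rm["taxon_label"].astype(str)
    rm["taxon_label"] = taxon.where(taxon.str.len() > 0, UNASSIGNED_LABEL)
    rm.loc[rm["taxon_label"].str.lower().isin(["na", "nan", "none"]), "taxon_label"] = (
        UNASSIGNED_LABEL
    )
    counts = (
        rm.groupby(["sample_id", "orf_id", "taxon_label"], sort=True)
        .size()
        .rename("n_reads")
        .reset_index()
    )
    totals = counts.groupby(["sample_id", "orf_id"])["n_reads"].transform("sum")
    counts["percent"] = 100.0 * counts["n_reads"] / totals
    return counts[["sample_id", "orf_id", "taxon_label", "percent"]]
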