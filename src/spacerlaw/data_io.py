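"""Per-array spacer-count tables: reading, writing, and summaries.

The empirical unit of the analysis is one CRISPR array with an integer
spacer count, annotated with the metagenome (sample) it came from and a
habitat label.  The canonical on-disk form is a 4-column TSV:

    sample_id  habitat  array_id  spacer_count

Arrays with zero spacers are excluded at ingest: the dynamic model's classes
start at one spacer, and a zero-spacer CRISPR locus carries no length
information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["HABITATS", "SpacerCountDataset", "SummaryStats",
           "read_spacer_counts", "write_spacer_counts",
           "summarize", "size_histogram"]

log = logging.getLogger(__name__)

#: the 13 habitat types used to classify metagenomic samples
HABITATS = (
    "Air",
    "Aquaculture",
    "Aquatic Sediment",
    "Engineered",
    "Fresh Water",
    "Host (human)",
    "Host (other)",
    "Host (plant)",
    "Marine",
    "Non-Marine Saline and Alkaline",
    "Terrestrial (soil)",
    "Terrestrial (other)",
    "Thermal Springs",
)

_COLUMNS = ["sample_id", "habitat", "array_id", "spacer_count"]


class FormatError(ValueError):
    """Malformed spacer-count table."""


@dataclass
class SpacerCountDataset:
    """Per-array spacer counts with sample and habitat metadata.

    Wraps a DataFrame with columns sample_id, habitat, array_id,
    spacer_count; every count is >= 1 and (sample_id, array_id) pairs are
    unique.
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        self.records = df = df[_COLUMNS].reset_index(drop=True)
        if len(df):
            counts = df["spacer_count"]
            if not np.issubdtype(counts.dtype, np.integer):
                raise FormatError("spacer_count must be integer")
            if (counts < 1).any():
                raise FormatError("spacer_count must be >= 1")
            if df.duplicated(["sample_id", "array_id"]).any():
                raise FormatError("duplicate (sample_id, array_id) pair")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def counts(self) -> np.ndarray:
        return self.records["spacer_count"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self.records.copy()

    @classmethod
    def from_records(cls, rows, provenance: str = "") -> "SpacerCountDataset":
        """Build from an iterable of (sample_id, habitat, array_id, count)."""
        df = pd.DataFrame(rows, columns=_COLUMNS)
        df["spacer_count"] = df["spacer_count"].astype(np.int64)
        return cls(df, provenance=provenance)


@dataclass
class SummaryStats:
    """Pooled summary of a dataset (population mean/SD, denominator n)."""

    n_samples: int
    n_arrays: int
    n_spacers: int
    mean: float
    sd: float
    max: int


def read_spacer_counts(path, format: str = "tsv") -> SpacerCountDataset:
    """Read and validate a spacer-count TSV.

    Rows with a non-integer or < 1 spacer count are rejected with a per-row
    log report; habitat labels outside the 13 recognized types become
    ``"unclassified"`` with a warning.  Missing columns or an empty body
    raise :class:`FormatError`.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[_COLUMNS]
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    counts = pd.to_numeric(df["spacer_count"], errors="coerce")
    bad = counts.isna() | (counts != np.floor(counts)) | (counts < 1)
    for idx in df.index[bad]:
        log.warning("%s: row %d rejected (spacer_count=%r)", path, idx + 2,
                    df.at[idx, "spacer_count"])
    df = df[~bad].copy()
    if df.empty:
        raise FormatError(f"{path}: all rows rejected")
    df["spacer_count"] = counts[~bad].astype(np.int64)

    unknown = ~df["habitat"].isin(HABITATS) & (df["habitat"] != "unclassified")
    if unknown.any():
        labels = sorted(df.loc[unknown, "habitat"].unique())
        log.warning("%s: %d rows with habitat outside the 13 recognized types "
                    "(%s) mapped to 'unclassified'", path, int(unknown.sum()),
                    ", ".join(map(str, labels[:5])))
        df.loc[unknown, "habitat"] = "unclassified"
    return SpacerCountDataset(df, provenance=str(path))


def write_spacer_counts(dataset: SpacerCountDataset, path) -> None:
    """Write the canonical 4-column TSV (UTF-8, tab-delimited, LF endings)."""
    df = dataset.to_frame()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def summarize(dataset: SpacerCountDataset) -> SummaryStats:
    """Pooled counts and moments; population SD (denominator n)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    c = dataset.counts
    return SummaryStats(
        n_samples=int(dataset.records["sample_id"].nunique()),
        n_arrays=int(len(c)),
        n_spacers=int(c.sum()),
        mean=float(c.mean()),
        sd=float(c.std(ddof=0)),
        max=int(c.max()),
    )


def size_histogram(dataset: SpacerCountDataset,
                   by: Optional[str] = None):
    """Exact integer histogram spacer_count -> number of arrays.

    ``by`` may be ``"sample"`` or ``"habitat"`` for per-group histograms
    (returns a dict group -> histogram); totals always sum to n_arrays.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if by is None:
        vc = dataset.records["spacer_count"].value_counts().sort_index()
        return {int(k): int(v) for k, v in vc.items()}
    col = {"sample": "sample_id", "habitat": "habitat"}.get(by)
    if col is None:
        raise ValueError("by must be None, 'sample' or 'habitat'")
    out = {}
    for group, sub in dataset.records.groupby(col, sort=True):
        vc = sub["spacer_count"].value_counts().sort_index()
        out[group] = {int(k): int(v) for k, v in vc.items()}
    return out
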