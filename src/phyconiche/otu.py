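"""OTU count tables with sample→growth-stage metadata.

The central container is :class:`OtuTable`: an integer OTU × sample count
matrix plus a mapping from each sample to its growth stage (e.g. initial /
plateau / last).  Tables are strictly validated on construction — counts must
be non-negative integers, identifiers unique, and every sample must carry a
stage label.  Files are UTF-8, tab-delimited, OTUs in rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["OtuTable", "OtuTableError", "read_otu_table", "write_otu_table"]


class OtuTableError(ValueError):
    """Raised when an OTU table violates its invariants or cannot be parsed."""


@dataclass
class OtuTable:
    """Integer OTU × sample count matrix with per-sample stage labels.

    Parameters
    ----------
    counts
        DataFrame with OTU ids as the index and sample ids as columns.
        Values must be non-negative integers (integral floats are accepted
        and cast; fractional values are rejected, never silently truncated).
    stages
        Series mapping every sample id to a stage label.
    """

    counts: pd.DataFrame
    stages: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate OTU ids: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise OtuTableError(f"duplicate sample ids: {dupes}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise OtuTableError("counts must be numeric")
        if np.isnan(values.astype(float)).any():
            raise OtuTableError("counts contain missing cells")
        if (values < 0).any():
            bad = counts.columns[(values < 0).any(axis=0)].tolist()
            raise OtuTableError(f"negative counts in samples {bad}")
        if not np.allclose(values, np.round(values), rtol=0, atol=0):
            raise OtuTableError("counts contain non-integer values; refusing to coerce")
        self.counts = counts.astype(np.int64)

        stages = pd.Series(self.stages)
        missing = [s for s in counts.columns if s not in stages.index]
        if missing:
            raise OtuTableError(f"samples missing from metadata: {missing}")
        unknown = [s for s in stages.index if s not in counts.columns]
        if unknown:
            raise OtuTableError(f"metadata refers to unknown samples: {unknown}")
        self.stages = stages.reindex(counts.columns).astype(str)

    # -- basic views -------------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    def stage_groups(self) -> dict[str, list[str]]:
        """Samples grouped by stage label, in stage order of first appearance."""
        groups: dict[str, list[str]] = {}
        for sample, stage in self.stages.items():
            groups.setdefault(stage, []).append(sample)
        return groups

    def relative_abundance(self) -> pd.DataFrame:
        """Within-sample relative abundances (each column sums to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise OtuTableError(f"samples with zero reads: {empty}")
        return self.counts / totals

    def subset_otus(self, otu_ids) -> "OtuTable":
        keep = [o for o in self.counts.index if o in set(otu_ids)]
        return OtuTable(self.counts.loc[keep].copy(), self.stages.copy())

    def subset_samples(self, sample_ids) -> "OtuTable":
        keep = [s for s in self.counts.columns if s in set(sample_ids)]
        return OtuTable(self.counts[keep].copy(), self.stages.loc[keep].copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.stages.equals(other.stages)


def read_otu_table(path, metadata_path, transpose: bool = False) -> OtuTable:
    """Read a tab-separated OTU table (OTUs in rows) plus sample metadata.

    The metadata file needs at least two columns: sample id and stage label
    (header row required).  A table whose *rows* look like the metadata's
    samples is flagged as transposed and rejected unless ``transpose=True``
    — silent transposition is the classic microbiome bug.
    """
    try:
        counts = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise OtuTableError(f"malformed OTU table {path}: {exc}") from exc
    if counts.columns.size == 0:
        raise OtuTableError(f"malformed header in {path}: no sample columns")
    meta = pd.read_csv(metadata_path, sep="\t", encoding="utf-8")
    if meta.shape[1] < 2:
        raise OtuTableError(f"metadata {metadata_path} needs sample and stage columns")
    stages = pd.Series(meta.iloc[:, 1].values, index=meta.iloc[:, 0].astype(str))

    if transpose:
        counts = counts.T
    else:
        samples = set(stages.index)
        cols = set(map(str, counts.columns))
        rows = set(map(str, counts.index))
        if not samples & cols and samples & rows:
            raise OtuTableError(
                "OTU table appears transposed (metadata samples found in rows, "
                "not columns); pass transpose=True to accept it"
            )
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return OtuTable(counts, stages)


def write_otu_table(table: OtuTable, path, metadata_path=None) -> None:
    """Write the counts (and optionally the metadata) as tab-separated UTF-8."""
    table.counts.to_csv(path, sep="\t", index_label="otu_id", encoding="utf-8")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {"sample": table.sample_ids, "stage": table.stages.values}
        )
        meta.to_csv(metadata_path, sep="\t", index=False, encoding="utf-8")
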