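"""Core in-memory containers shared across the pipeline.

The central object is :class:`OtuTable`, a thin validated wrapper around a
``pandas.DataFrame`` of nonnegative integer read counts with samples as rows
and OTUs as columns.  Sample metadata travels as a plain ``DataFrame`` indexed
by sample id; phylogenies are ``skbio.TreeNode`` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OtuTable", "validate_metadata", "METADATA_COLUMNS"]

#: Columns expected in a full sample-metadata table.  Only ``sample_id`` (the
#: index), ``depth`` and ``zone`` are required by downstream operations; the
#: rest are environmental / biotic predictors used by variation partitioning.
METADATA_COLUMNS = [
    "station_id",
    "depth",
    "latitude",
    "longitude",
    "zone",
    "temperature",
    "salinity",
    "dissolved_oxygen",
    "bacterial_abundance",
    "viral_abundance",
    "hnf_abundance",
    "pnf_abundance",
]


@dataclass
class OtuTable:
    """Sample-by-OTU count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative integer counts, index = sample ids, columns = OTU ids.
    taxonomy : dict, optional
        Mapping of OTU id to a ranked lineage string.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if arr.size:
            if np.any(arr < 0):
                raise ValueError("counts must be nonnegative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)

    # -- basic properties -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total reads: {empty}")
        return self.counts.div(totals, axis=0)

    def presence(self) -> pd.DataFrame:
        """Binary presence/absence matrix (samples x OTUs)."""
        return (self.counts > 0).astype(np.int8)

    def subset_samples(self, sample_ids) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return OtuTable(self.counts.loc[list(sample_ids)].copy(), taxonomy=self.taxonomy)

    def subset_otus(self, otu_ids) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        return OtuTable(self.counts[list(otu_ids)].copy(), taxonomy=self.taxonomy)

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return OtuTable(self.counts[keep].copy(), taxonomy=self.taxonomy)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"OtuTable({self.n_samples} samples x {self.n_otus} OTUs)"


def validate_metadata(metadata: pd.DataFrame, table: OtuTable | None = None,
                      photic_boundary: float = 200.0) -> pd.DataFrame:
    """Validate a sample-metadata frame.

    Checks positive depths, that the ``zone`` labels agree with the configured
    photic/aphotic depth boundary, and (optionally) that the sample ids match
    an :class:`OtuTable`.
    """
    md = metadata.copy()
    if "depth" not in md.columns:
        raise ValueError("metadata must have a 'depth' column")
    if (md["depth"] <= 0).any():
        raise ValueError("depths must be strictly positive")
    if "zone" in md.columns:
        expected = np.where(md["depth"] <= photic_boundary, "photic", "aphotic")
        bad = md.index[md["zone"].to_numpy() != expected].tolist()
        if bad:
            raise ValueError(
                f"zone labels inconsistent with {photic_boundary} m boundary: {bad}"
            )
    if table is not None:
        if set(md.index) != set(table.sample_ids):
            raise ValueError("metadata sample ids do not match the OTU table")
    return md
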