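"""Core containers for sequence-type count tables and sample metadata.

The central object is :class:`SequenceTypeTable`: counts of metabarcoding
sequence types (rows) across samples and their PCR replicates (columns),
together with per-sequence taxonomy/best-identity metadata and per-sample
age and role annotations.  Samples are lake-sediment horizons plus the two
kinds of laboratory controls (extraction controls and no-template controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEDIMENT = "sediment"
EXTRACTION_CONTROL = "extraction_control"
NTC = "ntc"

ROLES = (SEDIMENT, EXTRACTION_CONTROL, NTC)

#: separator between sample id and replicate index in flat column names
_COL_SEP = "__"


class TableError(ValueError):
    """Structural problem in a sequence-type table."""


class EmptyDatasetError(TableError):
    """Raised when filtering leaves no usable sediment samples."""


@dataclass
class SequenceTypeTable:
    """Counts of sequence types per sample x PCR replicate.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame; index = sequence-type ids, columns =
        two-level MultiIndex ``(sample, replicate)``.
    metadata
        Per-sequence DataFrame indexed like ``counts`` with columns
        ``taxon``, ``family``, ``best_identity``.
    samples
        Per-sample DataFrame indexed by sample id with columns ``age``
        (ka BP; NaN allowed for controls) and ``role``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- integrity -------------------------------------------------------
    def validate(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex) or self.counts.columns.nlevels != 2:
            raise TableError("counts columns must be a (sample, replicate) MultiIndex")
        if (np.asarray(self.counts.to_numpy()) < 0).any():
            raise TableError("negative counts")
        if not self.metadata.index.equals(self.counts.index):
            raise TableError("metadata index must match counts index")
        missing = {"taxon", "family", "best_identity"} - set(self.metadata.columns)
        if missing:
            raise TableError(f"metadata missing columns: {sorted(missing)}")
        ident = self.metadata["best_identity"].to_numpy(dtype=float)
        if ident.size and ((ident < 0) | (ident > 1)).any():
            raise TableError("best_identity outside [0, 1]")
        declared = set(self.samples.index)
        used = set(self.counts.columns.get_level_values(0))
        if not used <= declared:
            raise TableError(f"count columns for undeclared samples: {sorted(used - declared)}")
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise TableError(f"unknown sample roles: {sorted(bad_roles)}")

    # -- convenience views ----------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.counts)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def sample_ids(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["role"] == role])

    def pooled(self) -> pd.DataFrame:
        """Counts summed over PCR replicates: sequence x sample."""
        return self.counts.T.groupby(level=0, sort=False).sum().T

    def sediment_pooled(self) -> pd.DataFrame:
        """Pooled counts restricted to sediment samples."""
        return self.pooled()[self.sample_ids(SEDIMENT)]

    def replicate_totals(self) -> pd.Series:
        """Total reads per (sample, replicate) column."""
        return self.counts.sum(axis=0)

    def subset_records(self, keep: pd.Index | np.ndarray | list) -> "SequenceTypeTable":
        return SequenceTypeTable(
            counts=self.counts.loc[keep].copy(),
            metadata=self.metadata.loc[keep].copy(),
            samples=self.samples.copy(),
        )

    def subset_samples(self, keep: list[str]) -> "SequenceTypeTable":
        cols = [c for c in self.counts.columns if c[0] in set(keep)]
        return SequenceTypeTable(
            counts=self.counts[cols].copy(),
            metadata=self.metadata.copy(),
            samples=self.samples.loc[keep].copy(),
        )

    def copy(self) -> "SequenceTypeTable":
        return SequenceTypeTable(self.counts.copy(), self.metadata.copy(), self.samples.copy())

    # -- text round trip -------------------------------------------------
    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        """Write counts TSV (one column per sample__replicate) + samples CSV."""
        flat = self.counts.copy()
        flat.columns = [f"{s}{_COL_SEP}{r}" for s, r in self.counts.columns]
        out = pd.concat([self.metadata, flat], axis=1)
        out.index.name = "id"
        out.to_csv(counts_path, sep="\t")
        samples = self.samples.copy()
        samples.index.name = "sample"
        samples.to_csv(samples_path)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "SequenceTypeTable":
        raw = pd.read_csv(counts_path, sep="\t", index_col="id")
        samples = pd.read_csv(samples_path, index_col="sample")
        meta_cols = ["taxon", "family", "best_identity"]
        metadata = raw[meta_cols]
        flat = raw.drop(columns=meta_cols)
        pairs = []
        for col in flat.columns:
            sample, _, rep = col.rpartition(_COL_SEP)
            pairs.append((sample, int(rep)))
        counts = flat.astype(np.int64)
        counts.columns = pd.MultiIndex.from_tuples(pairs, names=["sample", "replicate"])
        return cls(counts=counts, metadata=metadata, samples=samples)


def make_table(
    counts: dict[tuple[str, int], dict[str, int]] | pd.DataFrame,
    metadata: pd.DataFrame,
    samples: pd.DataFrame,
) -> SequenceTypeTable:
    """Build a table from a mapping ``(sample, replicate) -> {seq id: reads}``."""
    if isinstance(counts, dict):
        counts = pd.DataFrame(counts).fillna(0).astype(np.int64)
        counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["sample", "replicate"])
        counts = counts.reindex(metadata.index).fillna(0).astype(np.int64)
    return SequenceTypeTable(counts=counts, metadata=metadata, samples=samples)
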