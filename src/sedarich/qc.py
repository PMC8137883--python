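"""Post-assignment quality control for sedaDNA sequence-type tables.

The filtering chain turns a raw taxonomically assigned table into the
analysis datasets used downstream:

* ``bestid1``   — sequence types with best identity exactly 1 and
  occurrence in at least two sediment horizons;
* ``bestid095`` — best identity >= 0.95, same occurrence rule;
* ``single``    — like ``bestid1`` but keeping only the most deeply
  sequenced PCR replicate per horizon;
* ``pooled``    — replicates of each horizon summed.

The chain order is fixed: identity filter, low-count zeroing, contaminant
removal, occurrence (frequency) filter, empty-sample drop.  Every step is
recorded in a :class:`FilterLog`, and the chain is idempotent: running it
on its own output changes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .tables import (
    EXTRACTION_CONTROL,
    NTC,
    SEDIMENT,
    EmptyDatasetError,
    SequenceTypeTable,
)

__all__ = [
    "FilterLog",
    "filter_by_identity",
    "zero_low_counts",
    "remove_contaminants",
    "filter_by_frequency",
    "drop_empty_samples",
    "pool_replicates",
    "select_deepest_replicate",
    "screen_controls",
    "run_qc",
]


@dataclass
class FilterLog:
    """Ordered provenance of the QC chain (records/reads before and after)."""

    steps: list[tuple[str, int, int, int, int]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def record(self, name: str, before: SequenceTypeTable, after: SequenceTypeTable) -> None:
        self.steps.append(
            (name, before.n_records, after.n_records, before.total_reads, after.total_reads)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps,
            columns=["step", "records_before", "records_after", "reads_before", "reads_after"],
        )


def _log(log: FilterLog | None, name: str, before: SequenceTypeTable, after: SequenceTypeTable):
    if log is not None:
        log.record(name, before, after)


def filter_by_identity(
    table: SequenceTypeTable,
    threshold: float = 0.95,
    exact: bool = False,
    log: FilterLog | None = None,
) -> SequenceTypeTable:
    """Keep sequence types whose best identity passes the threshold.

    ``exact=True`` keeps only perfect reference matches (best identity 1),
    otherwise records with ``best_identity >= threshold`` are retained.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ident = table.metadata["best_identity"]
    keep = ident == 1.0 if exact else ident >= threshold
    out = table.subset_records(table.metadata.index[keep])
    _log(log, "identity=1" if exact else f"identity>={threshold}", table, out)
    return out


def zero_low_counts(
    table: SequenceTypeTable, min_count: int = 10, log: FilterLog | None = None
) -> SequenceTypeTable:
    """Replace per-cell counts below ``min_count`` with zero.

    Removes the sporadic low-copy signal typical of tag jumps and
    low-level contamination; a cell equal to ``min_count`` survives.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    out = table.copy()
    out.counts = out.counts.where(out.counts >= min_count, 0)
    _log(log, f"counts<{min_count}->0", table, out)
    return out


def remove_contaminants(
    table: SequenceTypeTable,
    blacklist: list[str] | None = None,
    whitelist: list[str] | None = None,
    log: FilterLog | None = None,
) -> SequenceTypeTable:
    """Drop presumed contaminants and, optionally, non-regional taxa.

    ``blacklist`` entries match either taxon or family names (fruit crops,
    cultivars, taxa absent from the study region).  When ``whitelist`` is
    given, only records whose taxon appears on it are treated as genuine.
    Unresolvable list entries trigger a warning, never a failure.
    """
    blacklist = list(blacklist or [])
    names = set(table.metadata["taxon"]) | set(table.metadata["family"])
    for entry in blacklist + list(whitelist or []):
        if entry not in names:
            warnings.warn(f"list entry not found in table: {entry!r}", stacklevel=2)
    bad = table.metadata["taxon"].isin(blacklist) | table.metadata["family"].isin(blacklist)
    keep = ~bad
    if whitelist is not None:
        keep &= table.metadata["taxon"].isin(set(whitelist))
    out = table.subset_records(table.metadata.index[keep])
    _log(log, "contaminants", table, out)
    return out


def filter_by_frequency(
    table: SequenceTypeTable,
    min_occurrence: int = 2,
    log: FilterLog | None = None,
) -> SequenceTypeTable:
    """Keep sequence types detected in at least ``min_occurrence`` horizons.

    Occurrence is counted over sediment samples with replicates pooled, so
    a taxon seen twice in one horizon's replicates still counts once.
    """
    pooled = table.sediment_pooled()
    occurrence = (pooled > 0).sum(axis=1)
    keep = occurrence >= min_occurrence
    out = table.subset_records(table.metadata.index[keep])
    _log(log, f"occurrence>={min_occurrence}", table, out)
    return out


def drop_empty_samples(
    table: SequenceTypeTable, log: FilterLog | None = None
) -> SequenceTypeTable:
    """Remove sediment horizons left without reads; drop control columns.

    Controls are screened (see :func:`screen_controls`) but never feed the
    statistical datasets, so their columns are removed here.
    """
    pooled = table.pooled()
    sediment = table.sample_ids(SEDIMENT)
    keep = [s for s in sediment if s in pooled.columns and pooled[s].sum() > 0]
    if not keep:
        raise EmptyDatasetError("no sediment samples with reads remain")
    out = table.subset_samples(keep)
    _log(log, "drop_empty_samples", table, out)
    return out


def pool_replicates(table: SequenceTypeTable, log: FilterLog | None = None) -> SequenceTypeTable:
    """Sum counts across PCR replicates of each horizon."""
    pooled = table.pooled()
    counts = pooled.copy()
    counts.columns = pd.MultiIndex.from_tuples(
        [(s, 1) for s in pooled.columns], names=["sample", "replicate"]
    )
    out = SequenceTypeTable(counts=counts, metadata=table.metadata.copy(), samples=table.samples.copy())
    _log(log, "pool_replicates", table, out)
    return out


def select_deepest_replicate(
    table: SequenceTypeTable, log: FilterLog | None = None
) -> SequenceTypeTable:
    """Per horizon keep only the replicate with the largest total read count.

    Ties break to the lowest replicate index, so the choice is
    deterministic and seed-free.
    """
    totals = table.replicate_totals()
    keep_cols = []
    for sample in table.counts.columns.get_level_values(0).unique():
        sub = totals.loc[sample]
        best_rep = sub.index[sub.to_numpy().argmax()]  # argmax -> first max = lowest index
        keep_cols.append((sample, best_rep))
    out = SequenceTypeTable(
        counts=table.counts[keep_cols].copy(),
        metadata=table.metadata.copy(),
        samples=table.samples.copy(),
    )
    _log(log, "deepest_replicate", table, out)
    return out


def screen_controls(table: SequenceTypeTable, strict: bool = False,
                    log: FilterLog | None = None) -> SequenceTypeTable:
    """Report taxa detected in controls; optionally remove them.

    The default is report-only: sequences found in a control are noted in
    the log but kept in the sediment samples.  ``strict=True`` removes any
    sequence type detected in an extraction control or NTC.
    """
    controls = table.sample_ids(EXTRACTION_CONTROL) + table.sample_ids(NTC)
    pooled = table.pooled()
    present = [c for c in controls if c in pooled.columns]
    if not present:
        return table
    hits = pooled[present].sum(axis=1) > 0
    hit_taxa = sorted(table.metadata.loc[hits, "taxon"].unique())
    if log is not None and hit_taxa:
        log.notes.append(f"control-positive taxa: {', '.join(hit_taxa)}")
    if strict and hits.any():
        out = table.subset_records(table.metadata.index[~hits])
        _log(log, "strict_control_removal", table, out)
        return out
    return table


def run_qc(
    table: SequenceTypeTable,
    mode: str = "bestid1",
    min_count: int = 10,
    min_occurrence: int = 2,
    blacklist: list[str] | None = None,
    whitelist: list[str] | None = None,
    strict_controls: bool = False,
) -> tuple[SequenceTypeTable, FilterLog]:
    """Run the full QC chain and return the requested analysis dataset.

    ``mode`` is one of ``bestid1``, ``bestid095``, ``single`` (deepest
    replicate of the bestid1 chain) or ``pooled`` (bestid1 with replicates
    summed).
    """
    if mode not in {"bestid1", "bestid095", "single", "pooled"}:
        raise ValueError(f"unknown mode: {mode!r}")
    log = FilterLog()
    exact = mode in {"bestid1", "single", "pooled"}
    t = filter_by_identity(table, threshold=0.95, exact=exact, log=log)
    t = zero_low_counts(t, min_count=min_count, log=log)
    t = remove_contaminants(t, blacklist=blacklist, whitelist=whitelist, log=log)
    t = screen_controls(t, strict=strict_controls, log=log)
    t = filter_by_frequency(t, min_occurrence=min_occurrence, log=log)
    t = drop_empty_samples(t, log=log)
    if mode == "single":
        t = select_deepest_replicate(t, log=log)
    elif mode == "pooled":
        t = pool_replicates(t, log=log)
    return t, log
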