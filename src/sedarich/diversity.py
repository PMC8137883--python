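"""Rarefaction-based richness estimation and zonal turnover.

Richness per horizon is made comparable across unequal sequencing effort by
rarefying every sample to a common read depth (by default the smallest
per-horizon total in the dataset) and averaging the number of detected taxa
over repeated draws.  Rarefaction is sampling without replacement, i.e. a
multivariate hypergeometric draw from the sample's read pool.

Turnover between stratigraphic zones follows the gain/loss convention of
community time-series analysis: with P the taxa present in either of two
consecutive assemblages, total turnover = (gained + lost) / |P|, and the
appearance/disappearance fractions are gained/|P| and lost/|P|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import SequenceTypeTable

__all__ = [
    "rarefy_counts",
    "rarefied_richness",
    "within_family_richness",
    "zonal_turnover",
    "depth_richness_correlation",
]


def rarefy_counts(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample exactly ``depth`` reads without replacement.

    Parameters
    ----------
    counts
        1-D non-negative integer vector of reads per taxon.
    depth
        Number of reads to draw; must not exceed ``counts.sum()``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    if depth == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, depth)


def _richness_draws(counts: np.ndarray, depth: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    return np.array(
        [(rarefy_counts(counts, depth, rng) > 0).sum() for _ in range(reps)], dtype=float
    )


def rarefied_richness(
    table: SequenceTypeTable,
    reps: int = 100,
    depth: int | None = None,
    ci: float = 95.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-horizon rarefied richness with a percentile confidence interval.

    Counts are pooled over PCR replicates per horizon first.  ``depth``
    defaults to the minimum per-horizon total across the dataset (the
    classic equal-effort base count).  Returns a DataFrame indexed by
    sample with columns ``age, richness, ci_low, ci_high, depth, n_reps``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(rng)
    pooled = table.sediment_pooled()
    if pooled.shape[1] == 0:
        raise ValueError("no sediment samples in table")
    totals = pooled.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    rows = {}
    for sample in pooled.columns:
        draws = _richness_draws(pooled[sample].to_numpy(), depth, reps, rng)
        rows[sample] = (
            float(table.samples.loc[sample, "age"]),
            draws.mean(),
            np.percentile(draws, lo_q),
            np.percentile(draws, hi_q),
            depth,
            reps,
        )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["age", "richness", "ci_low", "ci_high", "depth", "n_reps"]
    )
    return out.sort_values("age", ascending=False)


def within_family_richness(
    table: SequenceTypeTable,
    family: str,
    cutoff: int = 100,
    reps: int = 100,
    ci: float = 95.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Rarefied richness within one taxonomic family.

    The family sub-table is rarefied to ``cutoff`` reads per horizon so
    low-abundance families are comparable with dominant ones.  Horizons
    whose family total falls below the cutoff are reported as missing
    (NaN), not as zero richness.
    """
    if family not in set(table.metadata["family"]):
        raise KeyError(f"family not in table: {family!r}")
    rng = np.random.default_rng(rng)
    keep = table.metadata.index[table.metadata["family"] == family]
    sub = table.subset_records(keep)
    pooled = sub.sediment_pooled()
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    rows = {}
    for sample in pooled.columns:
        vec = pooled[sample].to_numpy()
        age = float(table.samples.loc[sample, "age"])
        if vec.sum() < cutoff:
            rows[sample] = (age, np.nan, np.nan, np.nan, cutoff, reps)
            continue
        draws = _richness_draws(vec, cutoff, reps, rng)
        rows[sample] = (
            age, draws.mean(), np.percentile(draws, lo_q), np.percentile(draws, hi_q), cutoff, reps
        )
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["age", "richness", "ci_low", "ci_high", "depth", "n_reps"]
    )
    return out.sort_values("age", ascending=False)


def zonal_turnover(
    zonal_counts: pd.DataFrame,
    reps: int = 100,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Turnover between consecutive zones on rarefied zonal assemblages.

    Parameters
    ----------
    zonal_counts
        DataFrame zones x taxa of summed counts, rows in stratigraphic
        order (oldest first).

    Each zone is rarefied to the minimal zonal total ``reps`` times; the
    gain/loss statistics are averaged over draws.  Columns: ``gains,
    losses, pooled, total, appearance, disappearance``.
    """
    if len(zonal_counts) < 2:
        raise ValueError("need at least two zones")
    rng = np.random.default_rng(rng)
    depth = int(zonal_counts.sum(axis=1).min())
    mat = zonal_counts.to_numpy(dtype=np.int64)
    zone_ids = list(zonal_counts.index)
    records = []
    for a, b in zip(range(len(mat) - 1), range(1, len(mat))):
        stats = np.zeros(6)
        for _ in range(reps):
            pa = rarefy_counts(mat[a], depth, rng) > 0
            pb = rarefy_counts(mat[b], depth, rng) > 0
            pooled = int((pa | pb).sum())
            gains = int((pb & ~pa).sum())
            losses = int((pa & ~pb).sum())
            if pooled == 0:
                continue
            stats += (
                gains, losses, pooled,
                (gains + losses) / pooled, gains / pooled, losses / pooled,
            )
        stats /= reps
        records.append((f"{zone_ids[a]}->{zone_ids[b]}", *stats))
    return pd.DataFrame(
        records,
        columns=["transition", "gains", "losses", "pooled", "total", "appearance", "disappearance"],
    ).set_index("transition")


@dataclass
class DepthCorrelation:
    rho: float
    p: float
    df: int
    degenerate: bool = False


def depth_richness_correlation(table: SequenceTypeTable, richness: pd.DataFrame) -> DepthCorrelation:
    """Spearman correlation of per-horizon read depth with rarefied richness.

    A sanity check that sequencing effort does not drive the richness
    signal.  Constant inputs make the coefficient undefined; those are
    reported as rho 0 with a degenerate flag so batch pipelines keep
    running.
    """
    from scipy import stats

    pooled = table.sediment_pooled()
    common = [s for s in richness.index if s in pooled.columns]
    depths = pooled[common].sum(axis=0).to_numpy(dtype=float)
    rich = richness.loc[common, "richness"].to_numpy(dtype=float)
    df = len(common) - 2
    if np.ptp(depths) == 0 or np.ptp(rich) == 0:
        return DepthCorrelation(rho=0.0, p=1.0, df=df, degenerate=True)
    rho, p = stats.spearmanr(depths, rich)
    return DepthCorrelation(rho=float(rho), p=float(p), df=df)
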