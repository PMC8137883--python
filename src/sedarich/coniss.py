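"""Stratigraphically constrained incremental sum-of-squares clustering.

Agglomerative clustering of ordered samples (e.g. depths or ages in a
sediment core) in which only stratigraphically adjacent clusters may merge.
At each step the pair of adjacent clusters whose fusion least increases the
total within-cluster sum of squares is merged; reported heights follow the
cumulative convention, i.e. the total within-cluster dispersion after each
merge, which is non-decreasing along the merge sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Zonation", "coniss"]


@dataclass
class _Cluster:
    members: list[int]  # contiguous row indices, ascending
    n: int
    s: np.ndarray   # per-column sum
    ss: float       # sum of squared entries (all columns)

    @property
    def dispersion(self) -> float:
        # within-cluster sum of squares: sum_j (ss_j - s_j^2/n)
        return float(self.ss - (self.s ** 2).sum() / self.n)


def _merged_dispersion(a: _Cluster, b: _Cluster) -> float:
    n = a.n + b.n
    s = a.s + b.s
    ss = a.ss + b.ss
    return float(ss - (s ** 2).sum() / n)


@dataclass
class Zonation:
    """Merge tree of a constrained clustering.

    ``merges`` lists, oldest-merge first, tuples ``(left_start, right_start,
    height)`` where the starts are the first row indices of the two merged
    contiguous clusters and ``height`` is the cumulative within-cluster sum
    of squares after the merge.
    """

    n: int
    merges: list[tuple[int, int, float]]

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def cut(self, k: int) -> np.ndarray:
        """Zone label (0-based, oldest zone first) per sample for k zones."""
        if not (1 <= k <= self.n):
            raise ValueError(f"k must be in [1, {self.n}]")
        boundaries = set(range(self.n))  # start index of each cluster
        for left, right, _ in self.merges[: self.n - k]:
            boundaries.discard(right)
        labels = np.zeros(self.n, dtype=int)
        zone = -1
        for i in range(self.n):
            if i in boundaries:
                zone += 1
            labels[i] = zone
        return labels


def coniss(relative_abundances: np.ndarray) -> Zonation:
    """Cluster stratigraphically ordered assemblages.

    Parameters
    ----------
    relative_abundances
        2-D array, rows = samples in stratigraphic order, columns = taxa
        (typically relative read abundances).

    Returns the full merge tree; use :meth:`Zonation.cut` to obtain a fixed
    number of contiguous zones.
    """
    X = np.asarray(relative_abundances, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least two samples")
    clusters = [
        _Cluster([i], 1, X[i].copy(), float((X[i] ** 2).sum())) for i in range(X.shape[0])
    ]
    merges: list[tuple[int, int, float]] = []
    while len(clusters) > 1:
        # increase in total dispersion for every adjacent pair
        best_i, best_inc = 0, np.inf
        for i in range(len(clusters) - 1):
            a, b = clusters[i], clusters[i + 1]
            inc = _merged_dispersion(a, b) - a.dispersion - b.dispersion
            if inc < best_inc - 1e-12:
                best_i, best_inc = i, inc
        a, b = clusters[best_i], clusters[best_i + 1]
        merged = _Cluster(a.members + b.members, a.n + b.n, a.s + b.s, a.ss + b.ss)
        clusters[best_i : best_i + 2] = [merged]
        total = sum(c.dispersion for c in clusters)
        merges.append((a.members[0], b.members[0], total))
    return Zonation(n=X.shape[0], merges=merges)
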