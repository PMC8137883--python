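"""Ordination-based comparison of compositional datasets.

Used as a replicate-stability diagnostic: the first two principal
components of two processings of the same samples (e.g. pooled replicates
vs the single deepest replicate) are compared by Procrustes rotation, and
the fit is tested by permutation (the "protest" procedure).

Before PCA, rare sequence types are screened out (maximum relative read
abundance below a threshold) and a double-square-root transform tames the
dominance of abundant types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes

from .tables import SequenceTypeTable

__all__ = ["ordination_scores", "procrustes_protest", "ProtestResult"]


def ordination_scores(
    table: SequenceTypeTable | pd.DataFrame,
    min_max_relabund: float = 0.0025,
    n_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA sample and taxon scores of a screened, transformed count table.

    Parameters
    ----------
    table
        A sequence-type table (pooled over replicates internally) or a
        samples x taxa count DataFrame.
    min_max_relabund
        Taxa whose maximum relative read abundance across samples is below
        this fraction are dropped before the transform.

    Counts are converted to per-sample relative abundances, transformed
    ``x -> x**(1/4)`` (double square root), column-centred (not scaled) and
    decomposed by SVD.  Returns ``(sample_scores, taxon_scores,
    explained_variance)`` for the first ``n_components`` components.
    """
    if isinstance(table, SequenceTypeTable):
        mat = table.sediment_pooled().T  # samples x taxa
    else:
        mat = table
    if mat.shape[0] < 3:
        raise ValueError("need at least three samples for ordination")
    rel = mat.div(mat.sum(axis=1), axis=0).fillna(0.0)
    keep = rel.max(axis=0) >= min_max_relabund
    rel = rel.loc[:, keep]
    if rel.shape[1] < n_components:
        raise ValueError("fewer taxa than requested components after screening")
    Y = rel.to_numpy() ** 0.25
    Yc = Y - Y.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Yc, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T
    expl = (S ** 2) / max(Y.shape[0] - 1, 1)
    return (
        pd.DataFrame(scores, index=rel.index, columns=[f"PC{i+1}" for i in range(n_components)]),
        pd.DataFrame(loadings, index=rel.columns, columns=[f"PC{i+1}" for i in range(n_components)]),
        expl[:n_components],
    )


@dataclass
class ProtestResult:
    m2: float
    p: float
    n_perm: int


def procrustes_protest(
    scores_a: np.ndarray | pd.DataFrame,
    scores_b: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> ProtestResult:
    """Procrustes fit statistic m2 plus a permutation (protest) p-value.

    Both configurations are centred and scaled, configuration B is rotated
    and dilated onto A minimising the residual sum of squares; m2 is that
    minimised residual (0 = identical shapes, up to 1).  The p-value is the
    plus-one-corrected fraction of row permutations of B achieving an m2 at
    least as small as observed.
    """
    A = np.asarray(scores_a, dtype=float)
    B = np.asarray(scores_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("configurations must have identical shape")
    if A.shape[0] < 3:
        raise ValueError("need at least three rows")
    rng = np.random.default_rng(rng)
    _, _, m2 = _scipy_procrustes(A, B)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(B.shape[0])
        _, _, m2p = _scipy_procrustes(A, B[perm])
        if m2p <= m2:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return ProtestResult(m2=float(m2), p=float(p), n_perm=n_perm)
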