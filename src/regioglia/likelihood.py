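"""Graph heat-kernel condition-likelihood estimation.

Per-replicate stress and control cell indicators are smoothed over a kNN
graph of the cells' PCA embedding with the heat kernel exp(-beta * L_rw),
where L_rw = I - D^{-1} W is the random-walk normalized Laplacian; the
per-cell stress likelihood is the smoothed stress density divided by the
sum of both densities, averaged over replicates. Random-walk normalization
makes constant signals exact fixed points of the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

CATEGORY_NON = "non-changed"
CATEGORY_SLIGHT = "slightly-changed"
CATEGORY_HIGH = "highly-changed"


@dataclass
class CellGraph:
    """Symmetric weighted kNN graph over cells (no self-loops)."""

    adjacency: sp.csr_matrix
    cell_ids: pd.Index
    k: int

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency)
        if (abs(A - A.T) > 1e-12).nnz:
            raise ValueError("adjacency must be symmetric")
        if abs(A.diagonal()).max() if A.shape[0] else 0:
            raise ValueError("adjacency must have zero diagonal")
        if A.nnz and A.data.min() < 0:
            raise ValueError("weights must be non-negative")
        self.adjacency = A

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]


def build_knn_graph(embedding: np.ndarray, cell_ids, k: int = 7) -> CellGraph:
    """Adaptive-bandwidth Gaussian kNN graph.

    Directed kNN edges by Euclidean distance get weights
    w(u, v) = exp(-d(u, v)^2 / (sigma_u * sigma_v)) with sigma_u the distance
    from u to its k-th neighbor; the adjacency is symmetrized by averaging
    and self-loops removed. Duplicate points (zero kth distance) fall back
    to weight 1 for zero-distance pairs.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    sigma = dist[:, -1].copy()
    sigma[sigma == 0] = 1.0  # duplicate points: capped weight 1 below

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    denom = sigma[rows] * sigma[cols]
    w = np.exp(-(dist.ravel() ** 2) / denom)
    w = np.minimum(w, 1.0)
    directed = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    adj = 0.5 * (directed + directed.T)
    adj.setdiag(0.0)
    adj.eliminate_zeros()
    return CellGraph(adjacency=adj, cell_ids=pd.Index(cell_ids), k=k)


def _random_walk_laplacian(graph: CellGraph) -> sp.csr_matrix:
    A = graph.adjacency
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-300), 0.0)
    P = sp.diags(inv_deg) @ A
    # isolated vertices: L row of zeros, i.e. the filter leaves them unchanged
    L = sp.eye(graph.n_cells, format="csr") - P
    L = sp.csr_matrix(L)
    iso = deg == 0
    if iso.any():
        L = L.tolil()
        for i in np.flatnonzero(iso):
            L[i, i] = 0.0
        L = L.tocsr()
    return L


def graph_density(
    graph: CellGraph, indicator: np.ndarray, beta: float = 67.0
) -> np.ndarray:
    """Smooth a nonnegative indicator with exp(-beta * L_rw).

    The indicator is normalized to sum 1 before filtering. beta = 0 returns
    the normalized input exactly; constants are fixed points on connected
    graphs, and mass cannot leak between connected components.
    """
    h = np.asarray(indicator, dtype=float)
    if (h < 0).any():
        raise ValueError("indicator must be non-negative")
    total = h.sum()
    if total == 0:
        raise ValueError("indicator must not be all zero")
    h = h / total
    if beta == 0:
        return h
    L = _random_walk_laplacian(graph)
    return np.asarray(expm_multiply(-beta * L, h)).ravel()


def relative_likelihood(
    graph: CellGraph,
    cell_meta: pd.DataFrame,
    beta: float = 67.0,
) -> pd.DataFrame:
    """Per-cell stress likelihood, averaged over replicates (donors).

    For each donor r with cells in both conditions, the stress and control
    cell indicators are smoothed and the per-cell likelihood is
    d_stress / (d_stress + d_control); donors missing a condition are dropped
    with a warning. The mean over donors is clipped to [0, 1].
    """
    cell_meta = cell_meta.loc[graph.cell_ids]
    cond = cell_meta["condition"].to_numpy()
    per_donor = {}
    for donor in sorted(cell_meta["donor"].unique()):
        in_donor = (cell_meta["donor"] == donor).to_numpy()
        stress = in_donor & (cond == "stress")
        control = in_donor & (cond == "control")
        if not stress.any() or not control.any():
            logger.warning("donor %s missing a condition; dropped", donor)
            continue
        d_stress = graph_density(graph, stress.astype(float), beta)
        d_control = graph_density(graph, control.astype(float), beta)
        denom = d_stress + d_control
        lik = np.where(denom > 0, d_stress / np.where(denom > 0, denom, 1.0), 0.5)
        per_donor[donor] = np.clip(lik, 0.0, 1.0)
    if not per_donor:
        raise ValueError("no replicate has cells in both conditions")
    result = pd.DataFrame(per_donor, index=graph.cell_ids)
    result.columns = [f"likelihood_{d}" for d in per_donor]
    result["likelihood"] = np.clip(
        np.column_stack(list(per_donor.values())).mean(axis=1), 0.0, 1.0
    )
    return result


def classify_likelihood(
    likelihood: pd.Series | np.ndarray, low: float = 0.4, high: float = 0.6
) -> pd.Series:
    """Three-way classification: < low non-changed, [low, high] slightly-changed,
    > high highly-changed."""
    if not 0.0 < low < high < 1.0:
        raise ValueError("cutoffs must satisfy 0 < low < high < 1")
    values = np.asarray(likelihood, dtype=float)
    cats = np.where(
        values < low,
        CATEGORY_NON,
        np.where(values > high, CATEGORY_HIGH, CATEGORY_SLIGHT),
    )
    index = likelihood.index if isinstance(likelihood, pd.Series) else None
    return pd.Series(cats, index=index, name="category")


def summarize_by_celltype(
    likelihood: pd.Series,
    categories: pd.Series,
    cell_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-type mean likelihood, within-type highly-changed proportion, and
    each type's share of the global highly-changed set (shares sum to 1).

    Returns an empty frame when no cell is highly changed (shares undefined).
    """
    cell_meta = cell_meta.loc[likelihood.index]
    if "cell_type" not in cell_meta.columns:
        raise ValueError("cell_meta must carry cell_type labels")
    high = categories == CATEGORY_HIGH
    n_high_total = int(high.sum())
    rows = []
    for ct, idx in cell_meta.groupby("cell_type", sort=True).groups.items():
        lik = likelihood.loc[idx]
        h = high.loc[idx]
        rows.append(
            {
                "cell_type": ct,
                "n_cells": len(idx),
                "mean_likelihood": float(lik.mean()),
                "prop_highly_changed": float(h.mean()),
                "share_of_highly_changed": (
                    float(h.sum() / n_high_total) if n_high_total else np.nan
                ),
            }
        )
    out = pd.DataFrame(rows)
    if n_high_total == 0:
        return out.iloc[0:0]
    return out
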