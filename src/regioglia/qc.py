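"""Cell-level QC, doublet detection, normalization, HVG selection and
pseudobulk group correlation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from regioglia.datatypes import ExpressionStudy, NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Cell retention rules. Boundary values are retained: removal criteria
    are strictly 'over'/'under' the thresholds."""

    min_features: int = 200
    max_features: int = 6000
    max_mito_ratio: float = 0.15
    max_hb_ratio: float = 0.05

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        for r in (self.max_mito_ratio, self.max_hb_ratio):
            if not 0.0 <= r <= 1.0:
                raise ValueError("ratio thresholds must be in [0, 1]")


def compute_cell_qc(study: ExpressionStudy) -> pd.DataFrame:
    """Per-cell QC metrics: n_features, total_counts, mito_ratio, hb_ratio.

    Ratios are 0 by convention for all-zero cells.
    """
    for col in ("is_mito", "is_hemoglobin"):
        if col not in study.gene_meta.columns:
            raise ValueError(f"gene_meta is missing required column {col!r}")
    counts = study.counts.tocsr()
    totals = np.asarray(counts.sum(axis=1)).ravel()
    n_features = counts.getnnz(axis=1)
    mito_mask = study.gene_meta["is_mito"].to_numpy()
    hb_mask = study.gene_meta["is_hemoglobin"].to_numpy()
    mito_counts = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel()
    hb_counts = np.asarray(counts[:, hb_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_ratio = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        hb_ratio = np.where(totals > 0, hb_counts / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(
        {
            "n_features": n_features,
            "total_counts": totals.astype(np.int64),
            "mito_ratio": mito_ratio,
            "hb_ratio": hb_ratio,
        },
        index=study.cell_ids,
    )


def filter_cells(qc: pd.DataFrame, thresholds: QCThresholds) -> pd.Index:
    """Cell ids passing all QC rules; boundary equality retained."""
    keep = (
        (qc["n_features"] >= thresholds.min_features)
        & (qc["n_features"] <= thresholds.max_features)
        & (qc["mito_ratio"] <= thresholds.max_mito_ratio)
        & (qc["hb_ratio"] <= thresholds.max_hb_ratio)
    )
    retained = qc.index[keep]
    if len(retained) == 0:
        logger.warning("filter_cells removed every cell")
    return retained


def normalize_log1p(study: ExpressionStudy, scale: float = 10_000.0) -> NormalizedMatrix:
    """log(1 + scale * count / cell_total); zero-total cells map to zeros."""
    counts = study.counts.astype(float).toarray()
    totals = counts.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    values = np.log1p(scale * counts / safe)
    return NormalizedMatrix(values, study.cell_ids, study.gene_ids, scale)


def select_hvg(norm: NormalizedMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-n genes by binned standardized dispersion.

    Dispersion = variance / mean of the normalized values; genes are placed
    in ``n_bins`` equal-frequency mean bins and dispersion is z-scored
    within each bin. Constant genes score -inf. Ties break by gene id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    values = norm.values
    means = values.mean(axis=0)
    variances = values.var(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros_like(means)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(means > 0, variances / np.maximum(means, 1e-12), 0.0)

    n_genes = values.shape[1]
    if n >= n_genes:
        return list(norm.gene_ids)

    bins = pd.qcut(pd.Series(means), q=min(n_bins, max(n_genes // 2, 1)),
                   duplicates="drop", labels=False)
    z = np.full(n_genes, -np.inf)
    for b in np.unique(bins[~pd.isna(bins)]):
        mask = (bins == b).to_numpy()
        d = dispersion[mask]
        sd = d.std()
        center = d.mean()
        if sd > 0:
            z[mask] = (d - center) / sd
        else:
            z[mask] = 0.0
    z[variances == 0] = -np.inf  # constant genes can never outrank varying ones

    order = sorted(range(n_genes), key=lambda i: (-z[i], norm.gene_ids[i]))
    return [norm.gene_ids[i] for i in order[:n]]


def detect_doublets(
    norm: NormalizedMatrix,
    pN: float = 0.25,
    pK: float = 0.09,
    n_pcs: int = 20,
    expected_rate: float = 0.075,
    seed: int = 0,
) -> pd.Series:
    """Artificial-doublet nearest-neighbor detection.

    Creates round(pN * n) artificial doublets by averaging random real-cell
    pairs' normalized profiles on the linear (expm1) scale — matching how a
    real doublet's counts combine — embeds all cells in ``n_pcs`` principal
    components, scores each real cell by the fraction of artificial cells
    among its round(pK * (n_real + n_art)) nearest neighbors (pANN), and
    flags the top round(expected_rate * n_real) cells.
    """
    if not 0.0 <= expected_rate < 1.0:
        raise ValueError("expected_rate must be in [0, 1)")
    n_real = norm.n_cells
    n_art = int(round(pN * n_real))
    k = int(round(pK * (n_real + n_art)))
    if k < 1:
        raise ValueError(
            f"dataset too small: k = round(pK * (n_real + n_art)) = {k} < 1"
        )
    flags = pd.Series(False, index=norm.cell_ids, name="doublet")
    if expected_rate == 0.0 or n_art == 0:
        flags.attrs["pANN"] = pd.Series(0.0, index=norm.cell_ids, name="pANN")
        return flags

    rng = np.random.default_rng(seed)
    pairs_a = rng.integers(0, n_real, size=n_art)
    pairs_b = rng.integers(0, n_real, size=n_art)
    clash = pairs_a == pairs_b
    while clash.any():
        pairs_b[clash] = rng.integers(0, n_real, size=int(clash.sum()))
        clash = pairs_a == pairs_b
    artificial = np.log1p(
        0.5 * (np.expm1(norm.values[pairs_a]) + np.expm1(norm.values[pairs_b]))
    )

    combined = np.vstack([norm.values, artificial])
    n_comp = min(n_pcs, combined.shape[0] - 1, combined.shape[1])
    embedding = PCA(n_components=n_comp, random_state=0).fit_transform(combined)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding[:n_real])
    neighbor_idx = idx[:, 1:]  # drop self
    pann = (neighbor_idx >= n_real).mean(axis=1)

    n_flag = int(round(expected_rate * n_real))
    # highest pANN wins; ties broken by cell order for determinism
    order = np.lexsort((np.arange(n_real), -pann))
    flags.iloc[order[:n_flag]] = True
    flags.attrs["pANN"] = pd.Series(pann, index=norm.cell_ids, name="pANN")
    return flags


def pseudobulk_correlation(
    norm: NormalizedMatrix, cell_meta: pd.DataFrame, hvg: list[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation between per-group mean expression over HVGs.

    Groups are the LM/CM/LP/CP codes derived from region and condition.
    """
    from regioglia.datatypes import group_code

    cell_meta = cell_meta.loc[norm.cell_ids]
    groups = pd.Series(
        [
            group_code(r, c)
            for r, c in zip(cell_meta["region"], cell_meta["condition"])
        ],
        index=cell_meta.index,
    )
    values = norm.subset_genes(hvg).values if hvg is not None else norm.values
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("pseudobulk correlation needs at least 2 groups")
    profiles = []
    for g in labels:
        mask = (groups == g).to_numpy()
        if not mask.any():
            raise ValueError(f"group {g} has no cells")
        profiles.append(values[mask].mean(axis=0))
    corr = np.corrcoef(np.vstack(profiles))
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=labels, columns=labels)
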