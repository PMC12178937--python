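"""Differential expression between cell groups, regional high-expression
categories, light-induced change flags, and related summaries."""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from regioglia.datatypes import NormalizedMatrix

logger = logging.getLogger(__name__)

LABEL_M_HX = "m-HX"
LABEL_P_HX = "p-HX"
LABEL_NONE = "none"

#: pseudocount on expm1-averaged normalized means entering fold changes
FC_PSEUDOCOUNT = 0.01


def differential_expression(
    norm: NormalizedMatrix,
    cells_a,
    cells_b,
    min_pct: float = 0.2,
    logfc_threshold: float = 0.2,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between cell groups A and B.

    A gene is tested iff it is detected (normalized value > 0) in at least
    ``min_pct`` of A or of B, and |log2FC| >= ``logfc_threshold`` where the
    fold change compares expm1-averaged normalized values with a pseudocount.
    P-values are BH-adjusted over the tested genes only (``adjust='bonferroni'``
    available). Log2 fold change is A over B.
    """
    idx_a = norm.cell_ids.get_indexer(cells_a)
    idx_b = norm.cell_ids.get_indexer(cells_b)
    if (idx_a < 0).any() or (idx_b < 0).any():
        raise KeyError("unknown cell ids")
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both groups must be non-empty")
    a = norm.values[idx_a]
    b = norm.values[idx_b]

    pct_a = (a > 0).mean(axis=0)
    pct_b = (b > 0).mean(axis=0)
    mean_a = np.expm1(a).mean(axis=0)
    mean_b = np.expm1(b).mean(axis=0)
    log2fc = np.log2((mean_a + FC_PSEUDOCOUNT) / (mean_b + FC_PSEUDOCOUNT))

    tested = ((pct_a >= min_pct) | (pct_b >= min_pct)) & (
        np.abs(log2fc) >= logfc_threshold
    )
    tested_idx = np.flatnonzero(tested)
    if len(tested_idx) == 0:
        return pd.DataFrame(
            columns=["log2fc", "pct_a", "pct_b", "p_value", "p_adj", "direction"]
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield exact ties
        pvals = mannwhitneyu(
            a[:, tested_idx], b[:, tested_idx], alternative="two-sided", axis=0
        ).pvalue
    pvals = np.minimum(np.nan_to_num(pvals, nan=1.0), 1.0)
    p_adj = multipletests(pvals, method=adjust)[1]
    fc = log2fc[tested_idx]
    table = pd.DataFrame(
        {
            "log2fc": fc,
            "pct_a": pct_a[tested_idx],
            "pct_b": pct_b[tested_idx],
            "p_value": pvals,
            "p_adj": p_adj,
            "direction": np.where(fc > 0, "A-high", "B-high"),
        },
        index=pd.Index([norm.gene_ids[i] for i in tested_idx], name="gene"),
    )
    table.attrs["fc_scale"] = "log2, expm1-averaged with pseudocount"
    return table


def categorize_regional(
    deg: pd.DataFrame, fc_cutoff: float = 1.5, alpha: float = 0.05
) -> pd.Series:
    """m-HX / p-HX labels from a macula (A) vs periphery (B) DE table.

    A gene is m-HX iff its linear fold change macula/periphery is > fc_cutoff
    with adjusted p < alpha; p-HX symmetrically. The cutoff is on the linear
    scale. Labels are disjoint by construction.
    """
    linear_fc = np.power(2.0, deg["log2fc"])
    sig = deg["p_adj"] < alpha
    labels = np.where(
        sig & (linear_fc > fc_cutoff),
        LABEL_M_HX,
        np.where(sig & (linear_fc < 1.0 / fc_cutoff), LABEL_P_HX, LABEL_NONE),
    )
    return pd.Series(labels, index=deg.index, name="regional_category")


def flag_light_induced(
    deg: pd.DataFrame, alpha: float = 0.05, min_change: float = 0.09
) -> pd.Series:
    """Up/down flags from a stress (A) vs control (B) DE table.

    up iff adjusted p < alpha and linear FC - 1 > min_change;
    down iff adjusted p < alpha and 1 - FC > min_change.
    """
    linear_fc = np.power(2.0, deg["log2fc"])
    sig = deg["p_adj"] < alpha
    flags = np.where(
        sig & (linear_fc - 1.0 > min_change),
        "up",
        np.where(sig & (1.0 - linear_fc > min_change), "down", LABEL_NONE),
    )
    return pd.Series(flags, index=deg.index, name="light_induced")


def top_k_by_fold_change(
    deg: pd.DataFrame, k: int = 40, side: str = "A-high", alpha: float = 0.05
) -> list[str]:
    """k significant genes with the largest fold change on one side.

    Ties break by adjusted p, then gene id, so output order is reproducible.
    Fewer than k qualifying genes returns them all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if side not in ("A-high", "B-high"):
        raise ValueError("side must be 'A-high' or 'B-high'")
    sig = deg[deg["p_adj"] < alpha]
    sig = sig[sig["direction"] == side]
    magnitude = sig["log2fc"].abs()
    order = sorted(
        sig.index,
        key=lambda g: (-magnitude.loc[g], sig.loc[g, "p_adj"], g),
    )
    return order[:k]


def marker_normalized_expression(
    norm: NormalizedMatrix,
    targets: list[str],
    reference: str,
    groups: pd.Series,
) -> pd.DataFrame:
    """mean(target) / mean(reference) per group; groups with a zero reference
    mean get NaN with a warning."""
    if reference not in norm.gene_ids:
        raise KeyError(f"reference gene {reference!r} not found")
    gidx = norm.gene_ids.get_indexer(targets)
    if (gidx < 0).any():
        missing = [t for t, i in zip(targets, gidx) if i < 0]
        raise KeyError(f"unknown target genes: {missing}")
    ridx = norm.gene_ids.get_loc(reference)
    groups = groups.loc[norm.cell_ids]
    rows = {}
    for g in sorted(groups.unique()):
        mask = (groups == g).to_numpy()
        ref_mean = norm.values[mask, ridx].mean()
        if ref_mean == 0:
            logger.warning("reference gene has zero mean in group %s", g)
            rows[g] = [np.nan] * len(targets)
        else:
            rows[g] = list(norm.values[mask][:, gidx].mean(axis=0) / ref_mean)
    return pd.DataFrame(rows, index=pd.Index(targets, name="gene")).T


def deg_set_overlap(sets: dict[str, set]) -> dict[str, int]:
    """Sizes of all exclusive intersection regions of the named sets.

    Region keys are '&'-joined sorted subset names; a region counts elements
    in every named set of the subset and in no other set.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(sets)
    out: dict[str, int] = {}
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo))
            out["&".join(combo)] = len(inside - outside)
    return out


def annotate_by_markers(
    norm: NormalizedMatrix,
    marker_map: dict[str, list[str]],
    min_margin: float = 0.0,
) -> pd.Series:
    """Label each cell by the marker set with the highest mean z-scored
    expression; cells whose top margin over the runner-up is below
    ``min_margin`` stay 'unassigned'."""
    if not marker_map or any(len(v) == 0 for v in marker_map.values()):
        raise ValueError("marker sets must be non-empty")
    means = norm.values.mean(axis=0)
    sds = norm.values.std(axis=0)
    sds[sds == 0] = 1.0
    z = (norm.values - means) / sds
    types = sorted(marker_map)
    scores = np.zeros((norm.n_cells, len(types)))
    for j, t in enumerate(types):
        gidx = norm.gene_ids.get_indexer(marker_map[t])
        if (gidx < 0).any():
            raise KeyError(f"marker set for {t!r} contains unknown genes")
        scores[:, j] = z[:, gidx].mean(axis=1)
    order = np.argsort(-scores, axis=1)
    best = order[:, 0]
    margin = (
        scores[np.arange(norm.n_cells), best]
        - scores[np.arange(norm.n_cells), order[:, 1]]
        if len(types) > 1
        else np.full(norm.n_cells, np.inf)
    )
    labels = np.array([types[b] for b in best], dtype=object)
    labels[margin < min_margin] = "unassigned"
    # exact ties are unassigned regardless of margin threshold
    labels[margin == 0] = "unassigned"
    return pd.Series(labels, index=norm.cell_ids, name="cell_type")
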