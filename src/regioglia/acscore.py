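"""Per-cell-type signature selection and alteration scoring.

The alteration score of cell type j is

    score(j) = sum_i log2(FCexp(i) * FCprop(i) + 1)

over its signature genes i, where FCexp is the stress/control fold change of
mean normalized expression within the type and FCprop the fold change of the
fraction of cells expressing the gene. Pseudocounts keep both ratios finite;
an unchanged gene contributes exactly log2(2) = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from regioglia.datatypes import ExpressionStudy, NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureParams:
    max_genes: int = 50
    min_log2fc: float = 0.5
    min_detection: float = 0.25
    alpha: float = 0.05
    min_cells: int = 3
    pseudocount: float = 0.01


@dataclass
class SignatureSet:
    """Per-type ordered signature gene lists with selection statistics."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def genes(self, cell_type: str) -> list[str]:
        if cell_type not in self.tables:
            return []
        return list(self.tables[cell_type].index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.tables)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for ct, t in self.tables.items():
            f = t.copy()
            f.insert(0, "cell_type", ct)
            frames.append(f.reset_index(names="gene"))
        if not frames:
            return pd.DataFrame(
                columns=["cell_type", "gene", "log2fc", "detection", "p_adj"]
            )
        return pd.concat(frames, ignore_index=True)


def select_signature_genes(
    norm: NormalizedMatrix,
    cell_meta: pd.DataFrame,
    params: SignatureParams = SignatureParams(),
) -> SignatureSet:
    """One-vs-rest Wilcoxon markers per cell type, on control cells only.

    A gene enters a type's signature when its BH-adjusted one-vs-rest p-value
    is < alpha, its one-vs-rest log2 fold change is >= min_log2fc, and it is
    detected in >= min_detection of the type's cells. At most ``max_genes``
    are kept, the largest fold changes first, ties by gene id.
    """
    cell_meta = cell_meta.loc[norm.cell_ids]
    if "cell_type" not in cell_meta.columns or cell_meta["cell_type"].isna().any():
        raise ValueError("every cell must carry a cell_type label")
    control = cell_meta["condition"] == "control"
    values = norm.values[control.to_numpy()]
    types = cell_meta.loc[control, "cell_type"]

    out: dict[str, pd.DataFrame] = {}
    eps = params.pseudocount
    for ct in sorted(types.unique()):
        mask = (types == ct).to_numpy()
        if mask.sum() < params.min_cells or (~mask).sum() < params.min_cells:
            logger.warning("cell type %s has too few control cells; skipped", ct)
            continue
        in_vals = values[mask]
        out_vals = values[~mask]
        mean_in = np.expm1(in_vals).mean(axis=0)
        mean_out = np.expm1(out_vals).mean(axis=0)
        log2fc = np.log2((mean_in + eps) / (mean_out + eps))
        detection = (in_vals > 0).mean(axis=0)
        candidate = (log2fc >= params.min_log2fc) & (
            detection >= params.min_detection
        )
        if not candidate.any():
            out[ct] = pd.DataFrame(columns=["log2fc", "detection", "p_adj"])
            continue
        cand_idx = np.flatnonzero(candidate)
        pvals = mannwhitneyu(
            in_vals[:, cand_idx],
            out_vals[:, cand_idx],
            alternative="two-sided",
            axis=0,
        ).pvalue
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        keep = p_adj < params.alpha
        table = pd.DataFrame(
            {
                "log2fc": log2fc[cand_idx][keep],
                "detection": detection[cand_idx][keep],
                "p_adj": p_adj[keep],
            },
            index=pd.Index([norm.gene_ids[i] for i in cand_idx[keep]], name="gene"),
        )
        table = table.iloc[
            np.lexsort((table.index, -table["log2fc"].to_numpy()))
        ]
        out[ct] = table.head(params.max_genes)
    return SignatureSet(out)


def compute_fold_changes(
    norm: NormalizedMatrix,
    counts: sp.spmatrix,
    cell_meta: pd.DataFrame,
    signatures: SignatureSet,
    eps: float = 0.01,
    delta: float = 0.001,
) -> pd.DataFrame:
    """FCexp and FCprop per (cell type, signature gene), stress over control.

    FCexp = (mean norm expr in stress + eps) / (mean in control + eps);
    FCprop = (detected fraction in stress + delta) / (fraction in control
    + delta). Detection uses raw counts > 0. Types missing a condition are
    excluded with a warning.
    """
    cell_meta = cell_meta.loc[norm.cell_ids]
    counts = sp.csr_matrix(counts)
    rows = []
    for ct in signatures.cell_types:
        genes = signatures.genes(ct)
        if not genes:
            continue
        in_type = (cell_meta["cell_type"] == ct).to_numpy()
        stress = in_type & (cell_meta["condition"] == "stress").to_numpy()
        control = in_type & (cell_meta["condition"] == "control").to_numpy()
        if not stress.any() or not control.any():
            logger.warning("cell type %s missing a condition; excluded", ct)
            continue
        gidx = norm.gene_ids.get_indexer(genes)
        expr = norm.values[:, gidx]
        detected = (counts[:, gidx] > 0).toarray()
        fc_exp = (expr[stress].mean(axis=0) + eps) / (expr[control].mean(axis=0) + eps)
        fc_prop = (detected[stress].mean(axis=0) + delta) / (
            detected[control].mean(axis=0) + delta
        )
        for g, fe, fp in zip(genes, fc_exp, fc_prop):
            rows.append((ct, g, float(fe), float(fp)))
    table = pd.DataFrame(rows, columns=["cell_type", "gene", "fc_exp", "fc_prop"])
    if len(table) and not (
        np.isfinite(table[["fc_exp", "fc_prop"]]).all().all()
        and (table[["fc_exp", "fc_prop"]] > 0).all().all()
    ):
        raise ValueError("fold changes must be positive and finite")
    return table


def alteration_score(fold_changes: pd.DataFrame, symmetric: bool = False) -> pd.DataFrame:
    """Sum per-gene contributions log2(fc_exp * fc_prop + 1) per cell type.

    With ``symmetric=True`` each fold change is replaced by max(fc, 1/fc), so
    down-regulation scores as strongly as equal up-regulation; the default is
    the literal formula, where unchanged genes contribute exactly 1.
    """
    columns = ["cell_type", "n_genes", "score", "score_per_gene"]
    if len(fold_changes) == 0:
        out = pd.DataFrame(columns=columns)
        out.attrs["contributions"] = fold_changes.copy()
        out.attrs["symmetric"] = symmetric
        return out
    fc = fold_changes.copy()
    if len(fc):
        if (fc[["fc_exp", "fc_prop"]] <= 0).any().any() or not np.isfinite(
            fc[["fc_exp", "fc_prop"]]
        ).all().all():
            raise ValueError("fold-change table contains nonpositive or non-finite entries")
    if symmetric and len(fc):
        fc["fc_exp"] = np.maximum(fc["fc_exp"], 1.0 / fc["fc_exp"])
        fc["fc_prop"] = np.maximum(fc["fc_prop"], 1.0 / fc["fc_prop"])
    fc["contribution"] = np.log2(fc["fc_exp"] * fc["fc_prop"] + 1.0) if len(fc) else []
    rows = []
    for ct, sub in fc.groupby("cell_type", sort=True):
        score = float(sub["contribution"].sum())
        rows.append(
            {
                "cell_type": ct,
                "n_genes": len(sub),
                "score": score,
                "score_per_gene": score / len(sub) if len(sub) else 0.0,
            }
        )
    result = pd.DataFrame(rows, columns=columns)
    result.attrs["contributions"] = fc
    result.attrs["symmetric"] = symmetric
    return result


def acscore_null_band(
    study: ExpressionStudy,
    norm: NormalizedMatrix,
    signatures: SignatureSet,
    n_perm: int = 200,
    seed: int = 0,
    quantiles: tuple[float, float, float] = (0.025, 0.5, 0.975),
) -> pd.DataFrame:
    """Permutation null quantiles of the score per cell type.

    Condition labels are permuted within (cell type, donor) strata so donor
    composition is preserved; with fewer than 2 donors, within type only.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    cell_meta = study.cell_meta.loc[norm.cell_ids]
    counts = study.counts[study.cell_ids.get_indexer(norm.cell_ids)]
    rng = np.random.default_rng(seed)
    donors = cell_meta["donor"].unique()
    if len(donors) < 2:
        logger.warning("fewer than 2 donors; permuting within cell type only")
        strata_cols = ["cell_type"]
    else:
        strata_cols = ["cell_type", "donor"]

    null_scores: dict[str, list[float]] = {}
    for _ in range(n_perm):
        permuted = cell_meta.copy()
        cond = permuted["condition"].to_numpy().copy()
        for _, idx in permuted.groupby(strata_cols, sort=False).groups.items():
            pos = permuted.index.get_indexer(idx)
            cond[pos] = cond[pos][rng.permutation(len(pos))]
        permuted["condition"] = cond
        fc = compute_fold_changes(norm, counts, permuted, signatures)
        scores = alteration_score(fc)
        for _, row in scores.iterrows():
            null_scores.setdefault(row["cell_type"], []).append(row["score"])

    rows = []
    for ct, vals in null_scores.items():
        qs = np.quantile(vals, quantiles)
        rows.append({"cell_type": ct, "q_low": qs[0], "q_mid": qs[1], "q_high": qs[2]})
    return pd.DataFrame(rows, columns=["cell_type", "q_low", "q_mid", "q_high"])
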