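"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

REGIONS = ("macula", "periphery")
CONDITIONS = ("control", "stress")

#: short group codes used throughout outputs: condition initial x region initial
GROUP_CODES = {
    ("macula", "control"): "CM",
    ("macula", "stress"): "LM",
    ("periphery", "control"): "CP",
    ("periphery", "stress"): "LP",
}


def group_code(region: str, condition: str) -> str:
    return GROUP_CODES[(region, condition)]


@dataclass
class ExpressionStudy:
    """A sparse cells x genes count matrix with cell and gene annotations.

    Attributes
    ----------
    counts
        Non-negative integer matrix, cells in rows, genes in columns.
    cell_meta
        One row per cell; indexed by cell id; must carry ``donor``,
        ``region`` and ``condition`` columns; ``cell_type`` is optional.
    gene_meta
        One row per gene; indexed by gene id; must carry boolean
        ``is_mito`` and ``is_hemoglobin`` columns.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.cell_meta):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but cell_meta has "
                f"{len(self.cell_meta)} entries"
            )
        if self.counts.shape[1] != len(self.gene_meta):
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but gene_meta has "
                f"{len(self.gene_meta)} entries"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_meta.index

    def group_codes(self) -> pd.Series:
        """Per-cell LM/CM/LP/CP group code."""
        return pd.Series(
            [
                group_code(r, c)
                for r, c in zip(self.cell_meta["region"], self.cell_meta["condition"])
            ],
            index=self.cell_meta.index,
            name="group",
        )

    def subset_cells(self, cell_ids) -> "ExpressionStudy":
        idx = self.cell_meta.index.get_indexer(cell_ids)
        if (idx < 0).any():
            missing = [c for c, i in zip(cell_ids, idx) if i < 0]
            raise KeyError(f"unknown cell ids: {missing[:5]}")
        return ExpressionStudy(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta.copy(),
        )


@dataclass
class GroundTruth:
    """Planted structure of a simulated study, for validation only."""

    cell_types: pd.Series
    markers: dict[str, list[str]] = field(default_factory=dict)
    stress_fold_changes: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )
    regional_fold_changes: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )
    doublet_ids: list[str] = field(default_factory=list)
    doublet_parents: dict[str, tuple[str, str]] = field(default_factory=dict)

    def validate(self, study: ExpressionStudy) -> None:
        cell_set = set(study.cell_ids)
        if not set(self.doublet_ids) <= cell_set:
            raise ValueError("doublet ids must be a subset of cell ids")
        gene_set = set(study.gene_ids)
        for (ctype, region), genes in {
            **self.stress_fold_changes,
            **self.regional_fold_changes,
        }.items():
            unknown = set(genes) - gene_set
            if unknown:
                raise ValueError(
                    f"stress program ({ctype}, {region}) references unknown "
                    f"genes: {sorted(unknown)[:5]}"
                )


@dataclass
class NormalizedMatrix:
    """Log1p library-size-normalized expression (cells x genes), dense."""

    values: np.ndarray
    cell_ids: pd.Index
    gene_ids: pd.Index
    scale: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "NormalizedMatrix":
        idx = self.gene_ids.get_indexer(gene_ids)
        if (idx < 0).any():
            raise KeyError("unknown gene ids in subset")
        return NormalizedMatrix(
            self.values[:, idx], self.cell_ids, pd.Index(gene_ids), self.scale
        )

    def subset_cells(self, cell_ids) -> "NormalizedMatrix":
        idx = self.cell_ids.get_indexer(cell_ids)
        if (idx < 0).any():
            raise KeyError("unknown cell ids in subset")
        return NormalizedMatrix(
            self.values[idx], pd.Index(cell_ids), self.gene_ids, self.scale
        )
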