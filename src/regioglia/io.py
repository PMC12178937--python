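"""Readers and writers for the 10x-style Matrix Market layout.

On disk the matrix is genes-as-rows (10x dialect) with features.tsv and
barcodes.tsv; in memory everything is cells x genes.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from regioglia.datatypes import ExpressionStudy, GroundTruth


def write_study(study: ExpressionStudy, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(study.counts.T))
    features = pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "gene_name": study.gene_ids,
            "feature_type": "Gene Expression",
        }
    )
    features.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(study.cell_ids).to_csv(
        out / "barcodes.tsv", sep="\t", header=False, index=False
    )
    study.cell_meta.to_csv(out / "cell_meta.tsv", sep="\t")
    study.gene_meta.to_csv(out / "gene_meta.tsv", sep="\t")


def read_study(in_dir: str | Path) -> ExpressionStudy:
    src = Path(in_dir)
    mtx_path = src / "matrix.mtx"
    if not mtx_path.exists():
        mtx_path = src / "matrix.mtx.gz"
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path).T)  # to cells x genes
    features = pd.read_csv(src / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(src / "barcodes.tsv", sep="\t", header=None)[0]
    cell_meta = pd.read_csv(src / "cell_meta.tsv", sep="\t", index_col=0)
    gene_meta_path = src / "gene_meta.tsv"
    if gene_meta_path.exists():
        gene_meta = pd.read_csv(gene_meta_path, sep="\t", index_col=0)
    else:
        gene_ids = features[0]
        gene_meta = pd.DataFrame(
            {
                "is_mito": gene_ids.str.startswith("MT-"),
                "is_hemoglobin": gene_ids.str.startswith("HB"),
            },
        )
        gene_meta.index = pd.Index(gene_ids, name="gene_id")
    cell_meta = cell_meta.loc[barcodes]
    return ExpressionStudy(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "cell_types": truth.cell_types.to_dict(),
        "markers": truth.markers,
        "stress_fold_changes": {
            f"{ct}|{region}": genes
            for (ct, region), genes in truth.stress_fold_changes.items()
        },
        "regional_fold_changes": {
            f"{ct}|{region}": genes
            for (ct, region), genes in truth.regional_fold_changes.items()
        },
        "doublet_ids": list(truth.doublet_ids),
        "doublet_parents": {k: list(v) for k, v in truth.doublet_parents.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        cell_types=pd.Series(payload["cell_types"]),
        markers=payload["markers"],
        stress_fold_changes={
            tuple(k.split("|")): v
            for k, v in payload["stress_fold_changes"].items()
        },
        regional_fold_changes={
            tuple(k.split("|")): v
            for k, v in payload.get("regional_fold_changes", {}).items()
        },
        doublet_ids=payload["doublet_ids"],
        doublet_parents={
            k: tuple(v) for k, v in payload["doublet_parents"].items()
        },
    )
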