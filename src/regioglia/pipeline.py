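"""End-to-end orchestration: simulate -> qc -> acscore -> likelihood -> deg."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from regioglia import __version__
from regioglia.acscore import (
    SignatureParams,
    alteration_score,
    compute_fold_changes,
    select_signature_genes,
)
from regioglia.datatypes import ExpressionStudy
from regioglia.deg import (
    categorize_regional,
    differential_expression,
    flag_light_induced,
)
from regioglia.io import read_study, write_study, write_truth
from regioglia.likelihood import (
    build_knn_graph,
    classify_likelihood,
    relative_likelihood,
    summarize_by_celltype,
)
from regioglia.qc import (
    QCThresholds,
    compute_cell_qc,
    detect_doublets,
    filter_cells,
    normalize_log1p,
    pseudobulk_correlation,
    select_hvg,
)
from regioglia.synthetic import (
    CellTypeSpec,
    GeneratorConfig,
    StressProgram,
    default_cell_types,
    generate_study,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    out_dir: str = "run_out"
    input_dir: str | None = None  # when None, the generator is used
    seed: int = 0
    generator: GeneratorConfig | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    expected_doublet_rate: float = 0.075
    n_hvg: int = 2000
    n_pcs: int = 20
    beta: float = 67.0
    knn: int = 7
    likelihood_low: float = 0.4
    likelihood_high: float = 0.6
    signature: SignatureParams = field(default_factory=SignatureParams)
    deg_min_pct: float = 0.2
    deg_logfc_threshold: float = 0.2
    hx_fc_cutoff: float = 1.5
    light_min_change: float = 0.09
    alpha: float = 0.05

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            return obj

        return encode(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if data.get("generator") is not None:
            gen = dict(data["generator"])
            gen["cell_types"] = tuple(
                CellTypeSpec(**ct) for ct in gen.get("cell_types", ())
            )
            gen["stress_programs"] = tuple(
                StressProgram(**sp) for sp in gen.get("stress_programs", ())
            )
            gen["library_size_lognormal"] = tuple(gen["library_size_lognormal"])
            data["generator"] = GeneratorConfig(**gen)
        if isinstance(data.get("qc"), dict):
            data["qc"] = QCThresholds(**data["qc"])
        if isinstance(data.get("signature"), dict):
            data["signature"] = SignatureParams(**data["signature"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def demo_config(out_dir: str = "run_out", seed: int = 0) -> RunConfig:
    """Small end-to-end demo: 4 donors x 2 regions x 2 conditions, planted
    peripheral stress programs in MG and rods."""
    gen = GeneratorConfig(
        n_genes=1500,
        n_cells_per_group=500,
        n_donors=4,
        cell_types=default_cell_types(),
        stress_programs=(
            StressProgram("MG", "periphery", 20, 3.0),
            StressProgram("rod", "periphery", 20, 2.5),
            StressProgram("rod", "macula", 20, 1.5),
        ),
        doublet_rate=0.03,
        seed=seed,
    )
    return RunConfig(out_dir=out_dir, generator=gen, seed=seed)


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, write per-stage outputs under ``config.out_dir`` and
    return the machine-readable run report (also written as report.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- stage: input -----------------------------------------------------
    stage = "simulate" if config.input_dir is None else "load"
    try:
        if config.input_dir is None:
            gen = config.generator or demo_config().generator
            gen = dataclasses.replace(gen, seed=_stage_seed(config.seed, "simulate"))
            study, truth = generate_study(gen)
            write_study(study, out / "sim")
            write_truth(truth, out / "sim" / "truth.json")
        else:
            study = read_study(config.input_dir)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)
    report["stages"][stage] = {
        "n_cells": study.n_cells,
        "n_genes": study.n_genes,
    }

    # --- stage: qc --------------------------------------------------------
    try:
        qc_table = compute_cell_qc(study)
        retained = filter_cells(qc_table, config.qc)
        study_f = study.subset_cells(retained)
        norm_prov = normalize_log1p(study_f)
        doublet_flags = detect_doublets(
            norm_prov,
            expected_rate=config.expected_doublet_rate,
            n_pcs=config.n_pcs,
            seed=_stage_seed(config.seed, "doublets"),
        )
        keep = doublet_flags.index[~doublet_flags]
        study_clean = study_f.subset_cells(keep)
        norm = normalize_log1p(study_clean)
        hvg = select_hvg(norm, n=config.n_hvg)
        corr = pseudobulk_correlation(norm, study_clean.cell_meta, hvg)
        qc_table.assign(retained=qc_table.index.isin(retained)).to_csv(
            out / "qc_table.csv"
        )
        pd.Series(list(keep)).to_csv(out / "retained_cells.txt", index=False, header=False)
        corr.to_csv(out / "pseudobulk_corr.csv")
    except Exception as exc:  # noqa: BLE001
        fail("qc", exc)
    report["stages"]["qc"] = {
        "cells_in": study.n_cells,
        "cells_after_filter": len(retained),
        "doublets_removed": int(doublet_flags.sum()),
        "cells_out": study_clean.n_cells,
        "n_hvg": len(hvg),
    }

    # --- stage: annotate (from truth labels when simulated) ---------------
    cell_meta = study_clean.cell_meta
    if "cell_type" not in cell_meta.columns:
        raise RuntimeError(
            "pipeline stage 'annotate' failed: no cell_type labels; provide "
            "them in cell_meta.tsv or use the generator"
        )

    # --- stage: acscore ---------------------------------------------------
    try:
        signatures = select_signature_genes(norm, cell_meta, config.signature)
        fc_frames, score_frames = [], []
        for reg in sorted(cell_meta["region"].unique()):
            in_region = cell_meta.index[cell_meta["region"] == reg]
            fc = compute_fold_changes(
                norm.subset_cells(in_region),
                study_clean.counts[study_clean.cell_ids.get_indexer(in_region)],
                cell_meta.loc[in_region],
                signatures,
            )
            fc_frames.append(fc.assign(region=reg))
            sc = alteration_score(fc).assign(region=reg)
            sc.attrs = {}  # contributions frame breaks pd.concat attr merging
            score_frames.append(sc)
        fold_changes = pd.concat(fc_frames, ignore_index=True)
        scores = pd.concat(score_frames, ignore_index=True)
        signatures.to_frame().to_csv(out / "signatures.csv", index=False)
        fold_changes.to_csv(out / "fold_changes.csv", index=False)
        scores.to_csv(out / "acscores.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("acscore", exc)
    report["stages"]["acscore"] = {
        "n_types_scored": int(scores["cell_type"].nunique()),
        "cells_in": study_clean.n_cells,
    }

    # --- stage: likelihood ------------------------------------------------
    try:
        hvg_norm = norm.subset_genes(hvg)
        centered = hvg_norm.values - hvg_norm.values.mean(axis=0)
        n_comp = min(config.n_pcs, centered.shape[0] - 1, centered.shape[1])
        embedding = PCA(n_components=n_comp, random_state=0).fit_transform(centered)
        graph = build_knn_graph(embedding, norm.cell_ids, k=config.knn)
        lik = relative_likelihood(graph, cell_meta, beta=config.beta)
        categories = classify_likelihood(
            lik["likelihood"], config.likelihood_low, config.likelihood_high
        )
        summary = summarize_by_celltype(lik["likelihood"], categories, cell_meta)
        lik.assign(category=categories).to_csv(out / "likelihood.csv")
        summary.to_csv(out / "type_summary.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("likelihood", exc)
    report["stages"]["likelihood"] = {
        "cells_in": study_clean.n_cells,
        "mean_likelihood": float(lik["likelihood"].mean()),
    }

    # --- stage: deg -------------------------------------------------------
    try:
        deg_outputs = {}
        region = cell_meta["region"]
        condition = cell_meta["condition"]
        focal = "MG" if (cell_meta["cell_type"] == "MG").any() else None
        type_mask = (
            (cell_meta["cell_type"] == focal)
            if focal
            else pd.Series(True, index=cell_meta.index)
        )
        mac = cell_meta.index[type_mask & (region == "macula")]
        per = cell_meta.index[type_mask & (region == "periphery")]
        if len(mac) >= 3 and len(per) >= 3:
            deg_region = differential_expression(
                norm, mac, per, config.deg_min_pct, config.deg_logfc_threshold
            )
            cats = categorize_regional(deg_region, config.hx_fc_cutoff, config.alpha)
            deg_region.assign(regional_category=cats).to_csv(
                out / "deg_macula_vs_periphery.csv"
            )
            deg_outputs["regional"] = len(deg_region)
        for reg in ("macula", "periphery"):
            s = cell_meta.index[type_mask & (region == reg) & (condition == "stress")]
            c = cell_meta.index[type_mask & (region == reg) & (condition == "control")]
            if len(s) < 3 or len(c) < 3:
                continue
            deg_cond = differential_expression(
                norm, s, c, config.deg_min_pct, config.deg_logfc_threshold
            )
            flags = flag_light_induced(deg_cond, config.alpha, config.light_min_change)
            deg_cond.assign(light_induced=flags).to_csv(
                out / f"deg_stress_vs_control_{reg}.csv"
            )
            deg_outputs[f"condition_{reg}"] = len(deg_cond)
    except Exception as exc:  # noqa: BLE001
        fail("deg", exc)
    report["stages"]["deg"] = deg_outputs

    # conservation check: cells entering downstream equal QC survivors
    assert report["stages"]["qc"]["cells_out"] == report["stages"]["acscore"]["cells_in"]
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
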