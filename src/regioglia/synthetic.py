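"""Negative-binomial count simulator with planted regional stress programs.

Generates studies with the structure the downstream analysis assumes: donors,
two regions x two conditions, ~10 cell types with marker genes, region-specific
composition, mitochondrial/hemoglobin gene flags, planted stress-response
programs whose strength differs by (cell type, region), and optional doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from regioglia.datatypes import CONDITIONS, REGIONS, ExpressionStudy, GroundTruth


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type.

    ``proportions`` maps region name to the type's share of cells there;
    per-region shares must sum to 1 over all types.
    """

    name: str
    n_markers: int
    proportions: dict[str, float]


@dataclass(frozen=True)
class StressProgram:
    """A planted expression program in one (cell type, region).

    ``baseline_fold`` multiplies the NB mean of the program's genes in both
    conditions (a regional expression difference); ``fold_change``
    additionally multiplies them under stress (a stress response). Program
    genes are drawn first from the type's own unclaimed markers, then from
    unflagged background genes, so marker-based signatures can detect
    stress programs; later programs never reuse an earlier program's genes.
    """

    cell_type: str
    region: str
    n_genes: int
    fold_change: float
    baseline_fold: float = 1.0
    base_mean_boost: float = 1.0  # lifts program genes' baseline mean everywhere


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 1000
    n_cells_per_group: int = 500  # cells per (region, condition) group
    n_donors: int = 4
    cell_types: tuple[CellTypeSpec, ...] = ()
    nb_dispersion: float = 0.5
    library_size_lognormal: tuple[float, float] = (0.0, 0.25)
    mito_gene_fraction: float = 0.01
    hb_gene_fraction: float = 0.005
    marker_fold: float = 8.0
    donor_effect_sd: float = 0.1
    stress_programs: tuple[StressProgram, ...] = ()
    doublet_rate: float = 0.0
    base_mean: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_group < 1 or self.n_donors < 1:
            raise ConfigurationError("n_genes, n_cells_per_group, n_donors must be >= 1")
        if not self.cell_types:
            raise ConfigurationError("at least one cell type is required")
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ConfigurationError("cell type names must be unique")
        for region in REGIONS:
            total = sum(t.proportions.get(region, 0.0) for t in self.cell_types)
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ConfigurationError(
                    f"cell type proportions in region {region!r} sum to "
                    f"{total:.4f}, expected 1"
                )
            for t in self.cell_types:
                p = t.proportions.get(region, 0.0)
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"proportion of {t.name!r} in {region!r} outside [0, 1]"
                    )
        for prog in self.stress_programs:
            if prog.fold_change <= 0 or prog.baseline_fold <= 0:
                raise ConfigurationError("program fold changes must be > 0")
            if prog.cell_type not in names:
                raise ConfigurationError(f"unknown cell type {prog.cell_type!r}")
            if prog.region not in REGIONS:
                raise ConfigurationError(f"unknown region {prog.region!r}")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ConfigurationError("doublet_rate must be in [0, 1)")
        frac = self.mito_gene_fraction + self.hb_gene_fraction
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError("flagged gene fractions must fit in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        n_marked = sum(t.n_markers for t in self.cell_types)
        if n_marked > self.n_genes * (1 - frac):
            raise ConfigurationError("not enough unflagged genes for all markers")


def default_cell_types() -> tuple[CellTypeSpec, ...]:
    """A 10-type retina-like composition; macula cone-rich, periphery rod-rich."""
    table = [
        # name, markers, macula share, periphery share
        ("rod", 20, 0.25, 0.40),
        ("cone", 20, 0.20, 0.05),
        ("MG", 20, 0.15, 0.18),
        ("bipolar", 15, 0.12, 0.12),
        ("amacrine", 15, 0.08, 0.08),
        ("horizontal", 10, 0.05, 0.05),
        ("RGC", 15, 0.07, 0.04),
        ("astrocyte", 10, 0.03, 0.03),
        ("microglia", 10, 0.03, 0.03),
        ("endothelial", 10, 0.02, 0.02),
    ]
    return tuple(
        CellTypeSpec(name, n, {"macula": pm, "periphery": pp})
        for name, n, pm, pp in table
    )


def _gene_table(config: GeneratorConfig) -> pd.DataFrame:
    n_mito = int(round(config.n_genes * config.mito_gene_fraction))
    n_hb = int(round(config.n_genes * config.hb_gene_fraction))
    names, mito, hb = [], [], []
    for i in range(n_mito):
        names.append(f"MT-G{i:03d}")
    for i in range(n_hb):
        names.append(f"HB-G{i:03d}")
    for i in range(config.n_genes - n_mito - n_hb):
        names.append(f"G{i:05d}")
    mito = [True] * n_mito + [False] * (config.n_genes - n_mito)
    hb = [False] * n_mito + [True] * n_hb + [False] * (config.n_genes - n_mito - n_hb)
    return pd.DataFrame(
        {"is_mito": mito, "is_hemoglobin": hb}, index=pd.Index(names, name="gene_id")
    )


def generate_study(config: GeneratorConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Draw a study from the generative model.

    Counts are gene-wise negative binomial with per-(gene, type) means:
    a lognormal baseline, multiplied by ``marker_fold`` for a type's own
    markers, by the planted stress fold in (type, region, stress) cells,
    by a lognormal donor factor, and by a per-cell lognormal size factor.
    Deterministic given ``config.seed``; sub-steps consume one RNG stream
    in fixed order (genes, composition, cells, counts, doublets).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_meta = _gene_table(config)
    gene_ids = gene_meta.index
    n_genes = config.n_genes

    # baseline mean per gene (lognormal around base_mean)
    base_means = config.base_mean * rng.lognormal(0.0, 0.8, size=n_genes)

    # marker assignment: disjoint blocks of unflagged genes
    unflagged = np.flatnonzero(~(gene_meta["is_mito"] | gene_meta["is_hemoglobin"]))
    order = rng.permutation(unflagged)
    markers: dict[str, list[str]] = {}
    cursor = 0
    for ct in config.cell_types:
        block = order[cursor : cursor + ct.n_markers]
        markers[ct.name] = [gene_ids[g] for g in sorted(block)]
        cursor += ct.n_markers
    marker_idx = {
        name: gene_ids.get_indexer(genes) for name, genes in markers.items()
    }

    # program gene choice: the type's unclaimed markers first, then spare genes
    spare = list(order[cursor:])
    claimed: set[int] = set()
    stress_truth: dict[tuple[str, str], dict[str, float]] = {}
    regional_truth: dict[tuple[str, str], dict[str, float]] = {}
    programs: list[tuple[StressProgram, np.ndarray]] = []
    for prog in config.stress_programs:
        own = [
            g for g in marker_idx[prog.cell_type] if g not in claimed
        ][: prog.n_genes]
        short = prog.n_genes - len(own)
        if short > 0:
            if short > len(spare):
                raise ConfigurationError(
                    f"program for ({prog.cell_type}, {prog.region}) needs "
                    f"{short} extra genes but only {len(spare)} are available"
                )
            own += [spare.pop() for _ in range(short)]
        claimed.update(own)
        idx = np.asarray(sorted(own), dtype=int)
        key = (prog.cell_type, prog.region)
        if prog.fold_change != 1.0:
            stress_truth[key] = {gene_ids[g]: prog.fold_change for g in idx}
        if prog.baseline_fold != 1.0:
            regional_truth[key] = {gene_ids[g]: prog.baseline_fold for g in idx}
        if prog.base_mean_boost != 1.0:
            base_means[idx] *= prog.base_mean_boost
        programs.append((prog, idx))

    # per-(type) mean profiles
    type_means = {}
    for ct in config.cell_types:
        mu = base_means.copy()
        mu[marker_idx[ct.name]] *= config.marker_fold
        type_means[ct.name] = mu

    # donor effects: lognormal gene-wise factor per donor
    donors = [f"D{d + 1}" for d in range(config.n_donors)]
    donor_factors = {
        d: rng.lognormal(0.0, config.donor_effect_sd, size=n_genes) for d in donors
    }

    # cell roster: for each (region, condition) group, cells split evenly
    # across donors, types drawn from the region's composition
    type_names = [t.name for t in config.cell_types]
    rows = []
    for region in REGIONS:
        probs = np.array(
            [t.proportions.get(region, 0.0) for t in config.cell_types]
        )
        for condition in CONDITIONS:
            drawn = rng.choice(
                len(type_names), size=config.n_cells_per_group, p=probs
            )
            for i, t_i in enumerate(drawn):
                donor = donors[i % config.n_donors]
                rows.append((region, condition, donor, type_names[t_i]))
    cell_meta = pd.DataFrame(
        rows, columns=["region", "condition", "donor", "cell_type"]
    )
    cell_meta.index = pd.Index(
        [f"cell_{i:05d}" for i in range(len(cell_meta))], name="cell_id"
    )

    # count draws
    n_cells = len(cell_meta)
    log_mu, log_sd = config.library_size_lognormal
    size_factors = rng.lognormal(log_mu, log_sd, size=n_cells)
    r = 1.0 / config.nb_dispersion  # NB shape; var = mu + dispersion * mu^2

    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    for region in REGIONS:
        for condition in CONDITIONS:
            for ct in config.cell_types:
                mask = (
                    (cell_meta["region"] == region)
                    & (cell_meta["condition"] == condition)
                    & (cell_meta["cell_type"] == ct.name)
                ).to_numpy()
                if not mask.any():
                    continue
                mu = type_means[ct.name].copy()
                for prog, idx in programs:
                    if prog.cell_type != ct.name or prog.region != region:
                        continue
                    mu[idx] *= prog.baseline_fold
                    if condition == "stress":
                        mu[idx] *= prog.fold_change
                cells = np.flatnonzero(mask)
                for c in cells:
                    m = mu * donor_factors[cell_meta["donor"].iloc[c]]
                    m = m * size_factors[c]
                    p = r / (r + m)
                    counts[c] = rng.negative_binomial(r, p)

    study = ExpressionStudy(
        counts=sp.csr_matrix(counts),
        cell_meta=cell_meta,
        gene_meta=gene_meta,
    )
    truth = GroundTruth(
        cell_types=cell_meta["cell_type"].copy(),
        markers=markers,
        stress_fold_changes=stress_truth,
        regional_fold_changes=regional_truth,
    )

    if config.doublet_rate > 0:
        study, doublet_ids = inject_doublets(
            study, config.doublet_rate, seed=int(rng.integers(2**31))
        )
        truth.doublet_ids = doublet_ids
        truth.doublet_parents = study.cell_meta.attrs.get("doublet_parents", {})

    truth.validate(study)
    return study, truth


def inject_doublets(
    study: ExpressionStudy, rate: float, seed: int
) -> tuple[ExpressionStudy, list[str]]:
    """Replace round(rate * n) cells by sums of two random distinct parents.

    The replaced cell keeps its id and metadata; parent ids are recorded in
    ``cell_meta.attrs['doublet_parents']``. Returns the new study and the
    replaced cell ids. ``rate == 0`` returns the study unchanged.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("doublet rate must be in [0, 1)")
    if rate == 0.0:
        return study, []
    rng = np.random.default_rng(seed)
    n = study.n_cells
    n_doublets = int(round(rate * n))
    targets = rng.choice(n, size=n_doublets, replace=False)
    counts = study.counts.tolil(copy=True)
    parents: dict[str, tuple[str, str]] = {}
    target_set = set(targets.tolist())
    candidates = np.array([i for i in range(n) if i not in target_set])
    for t in targets:
        a, b = rng.choice(candidates, size=2, replace=False)
        counts[t] = (study.counts[a] + study.counts[b]).toarray().ravel()
        parents[study.cell_ids[t]] = (study.cell_ids[a], study.cell_ids[b])
    meta = study.cell_meta.copy()
    meta.attrs["doublet_parents"] = parents
    out = ExpressionStudy(
        counts=sp.csr_matrix(counts), cell_meta=meta, gene_meta=study.gene_meta.copy()
    )
    doublet_ids = [study.cell_ids[t] for t in sorted(targets)]
    return out, doublet_ids


def two_type_config(**overrides) -> GeneratorConfig:
    """Small two-type config with well-separated types, used for doublet tests."""
    types = (
        CellTypeSpec("A", 40, {"macula": 0.5, "periphery": 0.5}),
        CellTypeSpec("B", 40, {"macula": 0.5, "periphery": 0.5}),
    )
    cfg = GeneratorConfig(
        n_genes=400,
        n_cells_per_group=150,
        n_donors=2,
        cell_types=types,
        marker_fold=12.0,
        nb_dispersion=0.3,
    )
    return replace(cfg, **overrides)
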