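import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from regioglia.datatypes import ExpressionStudy
from regioglia.synthetic import (
    CellTypeSpec,
    GeneratorConfig,
    StressProgram,
    default_cell_types,
    generate_study,
    two_type_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_study(counts, regions=None, conditions=None, donors=None, types=None,
               mito=None, hb=None):
    """Small dense-array study helper for hand-enumerated fixtures."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    cell_meta = pd.DataFrame(
        {
            "donor": donors or ["D1"] * n_cells,
            "region": regions or ["macula"] * n_cells,
            "condition": conditions or ["control"] * n_cells,
        },
        index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"),
    )
    if types is not None:
        cell_meta["cell_type"] = types
    gene_meta = pd.DataFrame(
        {
            "is_mito": mito if mito is not None else [False] * n_genes,
            "is_hemoglobin": hb if hb is not None else [False] * n_genes,
        },
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
    )
    return ExpressionStudy(sp.csr_matrix(counts), cell_meta, gene_meta)


@pytest.fixture
def toy_study():
    counts = [
        [5, 0, 2],
        [0, 0, 0],
        [1, 1, 1],
        [10, 2, 0],
        [3, 3, 4],
    ]
    return make_study(counts, mito=[False, False, True])


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated study with a planted peripheral MG stress program."""
    cfg = GeneratorConfig(
        n_genes=600,
        n_cells_per_group=250,
        n_donors=4,
        cell_types=default_cell_types(),
        stress_programs=(StressProgram("MG", "periphery", 20, 3.0),),
        seed=42,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def two_type_sim():
    return generate_study(two_type_config(seed=7))


def mg_rod_config(seed, **overrides):
    """Generator config used by the simulation-based acceptance criteria."""
    base = dict(
        n_genes=800,
        n_cells_per_group=500,
        n_donors=4,
        cell_types=default_cell_types(),
        stress_programs=(
            StressProgram("MG", "periphery", 20, 3.0),
            StressProgram("rod", "periphery", 20, 2.5),
        ),
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def regional_hx_config(seed):
    """Two-type config planting a light-responsive peripheral program and a
    light-inert macular program in MG, for the regional categorization check."""
    types = (
        CellTypeSpec("MG", 20, {"macula": 0.5, "periphery": 0.5}),
        CellTypeSpec("rod", 20, {"macula": 0.5, "periphery": 0.5}),
    )
    return GeneratorConfig(
        n_genes=600,
        n_cells_per_group=250,
        n_donors=4,
        cell_types=types,
        stress_programs=(
            StressProgram(
                "MG", "periphery", 50,
                fold_change=2.5, baseline_fold=2.0, base_mean_boost=3.0,
            ),
            StressProgram(
                "MG", "macula", 50,
                fold_change=1.0, baseline_fold=2.0, base_mean_boost=3.0,
            ),
        ),
        seed=seed,
    )
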