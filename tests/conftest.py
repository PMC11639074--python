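import numpy as np
import pytest
import scipy.sparse as sp

from intercell.data import LRPair, SpatialExpression
from intercell.model import ModelConfig, build_masks
from intercell.simulate import generate, preset_config


@pytest.fixture
def toy_data() -> SpatialExpression:
    """4 cells x 3 genes with simple structure for unit tests."""
    X = np.array([
        [0.0, 4.0, 1.0],
        [4.0, 0.0, 2.0],
        [0.0, 9.0, 0.0],
        [9.0, 3.0, 5.0],
    ])
    T = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
    C = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0], [0.0, 1.0]])
    return SpatialExpression(
        X_obs=sp.csr_matrix(X), C=C, T=T,
        gene_names=["gA", "gB", "gC"],
        cell_ids=["c0", "c1", "c2", "c3"])


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-communication dataset shared across test modules."""
    return generate(preset_config(1, n_cells=120, n_lr_pairs=8, seed=7))


@pytest.fixture(scope="session")
def trained_small(small_sim):
    """One short full-pipeline run on the small dataset."""
    from intercell.iterate import run

    cfg = ModelConfig(seed=7, d=16, max_epochs=120)
    masks = build_masks(small_sim.prior, small_sim.lr_table,
                        small_sim.data.gene_names)
    result, multiview, history = run(
        small_sim.data, small_sim.lr_table, masks, cfg, max_iterations=3)
    return result, multiview, history, masks


def lr(pid, ligand, receptor):
    return LRPair(pid, tuple(ligand), tuple(receptor))


ABLATION_SEEDS = (1, 2, 3, 4, 5)
ABLATION_VARIANTS = ("full", "no-grn", "no-iterate", "per-view-decoder",
                     "shared-gnn")


@pytest.fixture(scope="session")
def ablation_results():
    """Benchmark sweep: five variants x five seeds at reduced scale.

    Uses setting-1 simulation parameters with 300 cells and 20 LR pairs —
    small enough for a desk run, large enough for stable ranking metrics.
    Returns the per-run summaries and, for the default configuration, the
    trained results themselves for downstream property checks.
    """
    import pandas as pd

    from intercell.evaluate import run_variant

    rows = []
    full_runs = []
    for seed in ABLATION_SEEDS:
        sim = generate(preset_config(1, n_cells=300, n_lr_pairs=20,
                                     seed=seed))
        for variant in ABLATION_VARIANTS:
            summary, result, history = run_variant(sim, variant=variant)
            rows.append(summary)
            if variant == "full":
                full_runs.append((seed, sim, result, history))
    return {"summaries": pd.DataFrame(rows), "full_runs": full_runs}
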