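"""Synthetic spatial transcriptomics with planted cell-cell communication.

The generator emulates the benchmark construction used throughout this
package's evaluation: cells are scattered uniformly in a square, assigned
cell types by nearest-anchor (Voronoi) territories whose mixing is
controlled by ``k_b`` anchors per type, given negative-binomial counts
(high for a type's own marker block, low elsewhere), and then a set of
ligand-receptor pairs is planted: each pair gets a circular communication
zone where ligand and receptor counts are boosted and a dedicated target
gene is incremented proportionally to the inverse-distance communication
weight the model family assumes. Finally the matrix is randomly masked
down to a target non-zero density. Ground truth records, for every zone
cell and target gene, which pair truly regulates it.

Negative-binomial parameters ``(n, p)`` follow the numpy convention:
``n`` successes with probability ``p``, mean ``n * (1 - p) / p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import (
    LRPair,
    NetworkKind,
    PriorNetwork,
    SpatialExpression,
    write_lr_table,
    write_prior_network,
    write_spatial_dataset,
)

#: the nine benchmark settings: (k_b, r, (n_h, p_h), (n_l, p_l), (n_c, p_c))
PRESETS: dict[int, tuple] = {
    1: (2, 10, (8, 0.5), (2, 0.8), (4, 0.8)),
    2: (2, 10, (8, 0.5), (2, 0.8), (8, 0.8)),
    3: (5, 10, (8, 0.5), (2, 0.8), (4, 0.8)),
    4: (5, 10, (8, 0.5), (2, 0.8), (8, 0.8)),
    5: (5, 10, (8, 0.5), (4, 0.8), (4, 0.8)),
    6: (5, 10, (8, 0.5), (4, 0.8), (8, 0.8)),
    7: (5, 20, (8, 0.5), (2, 0.8), (4, 0.8)),
    8: (10, 10, (8, 0.5), (2, 0.8), (8, 0.8)),
    9: (20, 10, (8, 0.5), (2, 0.8), (8, 0.8)),
}


@dataclass
class SimulationConfig:
    """Generator settings; defaults are benchmark setting 1 at full scale."""

    n_cells: int = 1000
    side: float = 100.0
    n_genes: int = 50
    n_lr_pairs: int = 50
    n_cell_types: int = 5
    k_b: int = 2
    r: float = 10.0
    nb_high: tuple[float, float] = (8, 0.5)
    nb_low: tuple[float, float] = (2, 0.8)
    nb_comm: tuple[float, float] = (4, 0.8)
    target_density: float = 0.2
    n_decoy_edges: int | None = None  # default: one decoy per true edge
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_density <= 1:
            raise ValueError("target_density must be in (0, 1]")
        if self.r >= self.side:
            raise ValueError("zone radius must be smaller than the square side")
        for _, p in (self.nb_high, self.nb_low, self.nb_comm):
            if not 0 < p < 1:
                raise ValueError("NB success probabilities must be in (0, 1)")
        if self.k_b < 1:
            raise ValueError("k_b must be >= 1")
        if self.n_genes < self.n_cell_types:
            raise ValueError("need at least one gene per cell type")
        if self.n_lr_pairs > self.n_genes:
            raise ValueError("disjoint target genes need n_lr_pairs <= n_genes")


def preset_config(setting: int, **overrides) -> SimulationConfig:
    """Config for one of the nine benchmark settings (1-9)."""
    if setting not in PRESETS:
        raise ValueError(f"unknown setting {setting}; choose 1..9")
    k_b, r, nb_high, nb_low, nb_comm = PRESETS[setting]
    cfg = SimulationConfig(k_b=k_b, r=float(r), nb_high=nb_high,
                           nb_low=nb_low, nb_comm=nb_comm)
    return replace(cfg, **overrides)


@dataclass
class SimulatedDataset:
    """Masked data + dense pre-mask truth + planted communication record."""

    data: SpatialExpression
    dense: SpatialExpression
    lr_table: list[LRPair]
    prior: PriorNetwork
    truth: dict[tuple[int, int], set[str]]  # (cell_index, gene_index) -> lr ids
    zones: list[tuple[str, tuple[float, float], float]]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# generation steps
# ---------------------------------------------------------------------------

def assign_cell_types(
    n_cells: int, side: float, n_cell_types: int, k_b: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform coordinates; type of the nearest of k_b anchors per type.

    More anchors per type means smaller, more interleaved territories,
    i.e. stronger cell-type mixing.
    """
    coords = rng.uniform(0, side, size=(n_cells, 2))
    anchors = rng.uniform(0, side, size=(n_cell_types * k_b, 2))
    anchor_types = np.repeat(np.arange(n_cell_types), k_b)
    d2 = ((coords[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
    labels = anchor_types[np.argmin(d2, axis=1)]
    return coords, labels


def sample_expression(
    labels: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """NB counts: a type's own marker block high, everything else low."""
    n, m, t = len(labels), config.n_genes, config.n_cell_types
    n_h, p_h = config.nb_high
    n_l, p_l = config.nb_low
    X = rng.negative_binomial(n_l, p_l, size=(n, m)).astype(np.float64)
    block = m // t
    markers = {ct: np.arange(ct * block, (ct + 1) * block) for ct in range(t)}
    for ct in range(t):
        rows = np.where(labels == ct)[0]
        if len(rows):
            X[np.ix_(rows, markers[ct])] = rng.negative_binomial(
                n_h, p_h, size=(len(rows), block))
    return X, markers


def plant_communication(
    dense: np.ndarray,
    coords: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[LRPair], dict, list]:
    """Plant one circular high-communication zone per LR pair.

    Zone cells get boosted ligand and receptor counts; each pair's
    dedicated target gene is incremented by NB draws scaled by the cell's
    inverse-distance communication weight with its zone neighbours, so the
    regulatory signal follows the spatial signalling geometry. Target
    genes are disjoint across pairs, and a gene is never its own pair's
    ligand or target simultaneously.
    """
    X = dense.copy()
    n, m = X.shape
    n_c, p_c = config.nb_comm
    genes = np.arange(m)
    targets = rng.permutation(m)[:config.n_lr_pairs]
    lr_table: list[LRPair] = []
    truth: dict[tuple[int, int], set[str]] = {}
    zones: list[tuple[str, tuple[float, float], float]] = []
    width = len(str(config.n_lr_pairs))
    for j in range(config.n_lr_pairs):
        t_gene = int(targets[j])
        candidates = genes[genes != t_gene]
        lig, rec = rng.choice(candidates, size=2, replace=False)
        lr_id = f"LR{j + 1:0{width}d}"
        lr_table.append(LRPair(lr_id, (f"g{lig}",), (f"g{rec}",)))

        zone_cells = np.array([], dtype=int)
        center = (0.0, 0.0)
        for _ in range(200):
            center = tuple(rng.uniform(0, config.side, size=2))
            dist = np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1])
            zone_cells = np.where(dist <= config.r)[0]
            if len(zone_cells) >= 2:
                break
        zones.append((lr_id, (float(center[0]), float(center[1])), config.r))

        X[zone_cells, lig] += rng.negative_binomial(n_c, p_c, len(zone_cells))
        X[zone_cells, rec] += rng.negative_binomial(n_c, p_c, len(zone_cells))
        # inverse-distance communication weight into each zone cell
        zc = coords[zone_cells]
        D = np.hypot(zc[:, None, 0] - zc[None, :, 0],
                     zc[:, None, 1] - zc[None, :, 1])
        np.fill_diagonal(D, np.inf)
        D[D < 1e-9] = 1e-9
        w_in = (X[zone_cells, lig][:, None] / D).sum(axis=0) \
            * X[zone_cells, rec]
        scale = np.ones_like(w_in)
        if w_in.mean() > 0:
            scale = np.clip(w_in / w_in.mean(), 0.0, 3.0)
        draws = rng.negative_binomial(n_c, p_c, len(zone_cells))
        X[zone_cells, t_gene] += np.round(draws * scale)
        for c in zone_cells:
            truth.setdefault((int(c), t_gene), set()).add(lr_id)
    return X, lr_table, truth, zones


def build_prior_network(
    lr_table: list[LRPair],
    truth: dict[tuple[int, int], set[str]],
    gene_names: list[str],
    n_decoy_edges: int,
    rng: np.random.Generator,
) -> PriorNetwork:
    """True receptor->target edges plus random decoy edges (noise)."""
    target_of = {}
    for (_, g), lrs in truth.items():
        for lr_id in lrs:
            target_of[lr_id] = g
    edges = set()
    for lr in lr_table:
        g = target_of.get(lr.id)
        if g is not None:
            for rec in lr.receptor_subunits:
                edges.add((rec, gene_names[g]))
    added = 0
    while added < n_decoy_edges:
        a, b = rng.choice(len(gene_names), size=2, replace=False)
        edge = (gene_names[a], gene_names[b])
        if edge not in edges:
            edges.add(edge)
            added += 1
    return PriorNetwork(edges=edges, kind=NetworkKind.GRN)


def mask_to_density(
    dense: np.ndarray, target_density: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero random non-zero entries until the non-zero fraction hits target."""
    X = dense.copy()
    n, m = X.shape
    nz_rows, nz_cols = np.nonzero(X)
    nnz = len(nz_rows)
    target_nnz = int(round(target_density * n * m))
    if nnz < target_nnz:
        raise ValueError(
            f"dense matrix density {nnz / (n * m):.3f} below target "
            f"{target_density}; cannot mask up")
    drop = rng.choice(nnz, size=nnz - target_nnz, replace=False)
    X[nz_rows[drop], nz_cols[drop]] = 0.0
    return X


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Compose the four steps into a fully reproducible dataset."""
    rng = np.random.default_rng(config.seed)
    coords, labels = assign_cell_types(
        config.n_cells, config.side, config.n_cell_types, config.k_b, rng)
    X, _ = sample_expression(labels, config, rng)
    X, lr_table, truth, zones = plant_communication(X, coords, config, rng)
    gene_names = [f"g{j}" for j in range(config.n_genes)]
    n_decoys = (config.n_decoy_edges if config.n_decoy_edges is not None
                else config.n_lr_pairs)
    prior = build_prior_network(lr_table, truth, gene_names, n_decoys, rng)
    X_masked = mask_to_density(X, config.target_density, rng)

    T = np.zeros((config.n_cells, config.n_cell_types))
    T[np.arange(config.n_cells), labels] = 1.0
    cell_ids = [f"c{i}" for i in range(config.n_cells)]
    type_names = [f"type_{j}" for j in range(config.n_cell_types)]

    def _wrap(mat):
        return SpatialExpression(
            X_obs=sp.csr_matrix(mat), C=coords, T=T,
            gene_names=gene_names, cell_ids=cell_ids,
            cell_type_names=type_names)

    return SimulatedDataset(
        data=_wrap(X_masked), dense=_wrap(X), lr_table=lr_table,
        prior=prior, truth=truth, zones=zones, config=config)


def write_dataset(sim: SimulatedDataset, out_dir) -> dict:
    """Write the full input file set plus truth.csv and zones.csv."""
    from pathlib import Path

    out_dir = Path(out_dir)
    paths = write_spatial_dataset(sim.data, out_dir)
    write_lr_table(sim.lr_table, out_dir / "lr_table.csv")
    write_prior_network(sim.prior, out_dir / "prior_network.csv")
    gene_names = sim.data.gene_names
    cell_ids = sim.data.cell_ids
    truth_rows = [
        (cell_ids[c], gene_names[g], lr_id)
        for (c, g), lrs in sorted(sim.truth.items()) for lr_id in sorted(lrs)
    ]
    pd.DataFrame(truth_rows, columns=["cell_id", "gene", "lr_id"]).to_csv(
        out_dir / "truth.csv", index=False)
    pd.DataFrame(
        [(lr_id, cx, cy, r) for lr_id, (cx, cy), r in sim.zones],
        columns=["lr_id", "center_x", "center_y", "radius"],
    ).to_csv(out_dir / "zones.csv", index=False)
    paths.update({
        "lr_table": out_dir / "lr_table.csv",
        "prior_network": out_dir / "prior_network.csv",
        "truth": out_dir / "truth.csv",
        "zones": out_dir / "zones.csv",
    })
    return paths
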