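"""Core data model and readers/writers for spatial expression datasets.

The central container is :class:`SpatialExpression`, holding the observed
sparse cell-by-gene count matrix ``X_obs``, 2-D spatial coordinates ``C``
and a cell-by-cell-type matrix ``T`` (one-hot labels for cell-resolution
platforms, proportions for spot-resolution ones — downstream math is
identical). Ligand-receptor pair tables and gene-gene prior networks
(GRN/PPI edge lists) round out the inputs.

File formats are deliberately plain: matrix-market or dense CSV/TSV for the
matrix, CSV sidecars for coordinates, cell types, LR pairs and prior edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

#: separator for multi-subunit ligand/receptor complexes inside one CSV field
COMPLEX_SEPARATOR = "+"


class AlignmentError(ValueError):
    """Rows/columns of the input files do not line up."""


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


@dataclass
class SpatialExpression:
    """Observed spatial transcriptomics data for ``n`` cells and ``m`` genes.

    Attributes
    ----------
    X_obs
        Non-negative sparse ``n x m`` expression matrix (CSR).
    C
        ``n x 2`` spatial coordinates, continuous Euclidean positions.
    T
        Non-negative ``n x t`` cell-type matrix; rows are one-hot or sum
        to 1 (proportions).
    gene_names, cell_ids
        Identifier lists; gene names must be unique.
    """

    X_obs: sp.csr_matrix
    C: np.ndarray
    T: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    cell_type_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X_obs = sp.csr_matrix(self.X_obs, dtype=np.float64)
        self.C = np.asarray(self.C, dtype=np.float64)
        self.T = np.asarray(self.T, dtype=np.float64)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.X_obs.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X_obs.shape[1]

    @property
    def n_cell_types(self) -> int:
        return self.T.shape[1]

    def validate(self) -> None:
        n, m = self.X_obs.shape
        if self.X_obs.nnz and self.X_obs.data.min() < 0:
            raise ValidationError("expression matrix contains negative entries")
        if self.C.shape != (n, 2):
            raise AlignmentError(
                f"coordinates have shape {self.C.shape}, expected ({n}, 2)")
        if self.T.ndim != 2 or self.T.shape[0] != n:
            raise AlignmentError(
                f"cell-type matrix has {self.T.shape[0]} rows, expected {n}")
        if self.T.min() < 0:
            raise ValidationError("cell-type matrix contains negative entries")
        row_sums = self.T.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-6):
            raise ValidationError(
                "cell-type rows must be one-hot or sum to 1 (proportions)")
        if len(self.gene_names) != m:
            raise AlignmentError(
                f"{len(self.gene_names)} gene names for {m} matrix columns")
        if len(self.cell_ids) != n:
            raise AlignmentError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(set(self.gene_names)) != m:
            raise ValidationError("gene names are not unique")

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in dataset") from None


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor pair; either side may be a multi-subunit complex."""

    id: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]

    def __post_init__(self):
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValidationError(f"LR pair {self.id!r} has an empty side")


class NetworkKind(str, Enum):
    GRN = "GRN"
    PPI = "PPI"


@dataclass
class PriorNetwork:
    """Directed gene-gene prior (GRN) or undirected interaction set (PPI)."""

    edges: set[tuple[str, str]]
    kind: NetworkKind = NetworkKind.GRN

    def successors(self, gene: str) -> set[str]:
        out = {b for a, b in self.edges if a == gene}
        if self.kind is NetworkKind.PPI:
            out |= {a for a, b in self.edges if b == gene}
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> tuple[sp.csr_matrix, list[str] | None, list[str] | None]:
    path = Path(path)
    if path.suffix == ".mtx":
        X = sp.csr_matrix(mmread(path))
        cells = genes = None
        cell_file = path.with_name(path.stem + "_cells.txt")
        gene_file = path.with_name(path.stem + "_genes.txt")
        if cell_file.exists():
            cells = cell_file.read_text().split()
        if gene_file.exists():
            genes = gene_file.read_text().split()
        return X, cells, genes
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return (sp.csr_matrix(df.to_numpy(dtype=np.float64)),
            [str(i) for i in df.index], [str(c) for c in df.columns])


def read_spatial_dataset(
    matrix_path,
    coordinates_path,
    cell_types_path,
) -> SpatialExpression:
    """Read matrix + coordinates + cell-type files into a validated dataset.

    When cell identifiers are available in the matrix file they are matched
    against the sidecar files by name; otherwise row order is trusted.
    """
    X, cells, genes = _read_matrix(Path(matrix_path))
    n, m = X.shape
    if X.nnz and X.data.min() < 0:
        raise ValidationError(
            f"negative entries in expression matrix {matrix_path}")

    coords = pd.read_csv(coordinates_path)
    if coords.shape[1] < 3:
        raise AlignmentError(
            f"{coordinates_path}: expected columns cell_id,x,y")
    coords = coords.set_index(coords.columns[0])
    types = pd.read_csv(cell_types_path)
    types = types.set_index(types.columns[0])
    types.index = types.index.map(str)
    coords.index = coords.index.map(str)

    if cells is not None:
        missing = [c for c in cells if c not in coords.index]
        if missing or len(coords) != n:
            raise AlignmentError(
                f"{coordinates_path}: {len(coords)} rows do not align with "
                f"{n} matrix cells (first missing: {missing[:3]})")
        coords = coords.loc[cells]
        missing = [c for c in cells if c not in types.index]
        if missing or len(types) != n:
            raise AlignmentError(
                f"{cell_types_path}: {len(types)} rows do not align with "
                f"{n} matrix cells (first missing: {missing[:3]})")
        types = types.loc[cells]
    else:
        if len(coords) != n:
            raise AlignmentError(
                f"{coordinates_path}: {len(coords)} rows for {n} cells")
        if len(types) != n:
            raise AlignmentError(
                f"{cell_types_path}: {len(types)} rows for {n} cells")
        cells = [str(i) for i in coords.index]
    if genes is None:
        genes = [f"g{j}" for j in range(m)]

    return SpatialExpression(
        X_obs=X,
        C=coords.iloc[:, :2].to_numpy(dtype=np.float64),
        T=types.to_numpy(dtype=np.float64),
        gene_names=list(genes),
        cell_ids=list(cells),
        cell_type_names=[str(c) for c in types.columns],
    )


def read_lr_table(path, gene_names: Sequence[str] | None = None) -> list[LRPair]:
    """Parse an LR-pair CSV with columns ``id,ligand,receptor``.

    Complex subunits are joined with ``+`` inside a field (CellChatDB-like
    convention). Pairs whose genes are absent from ``gene_names`` (when
    given) are dropped with a warning — real LR databases always exceed a
    measured panel.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"id", "ligand", "receptor"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: LR table needs columns {sorted(required)}")
    pairs: list[LRPair] = []
    seen: set[str] = set()
    known = set(gene_names) if gene_names is not None else None
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(row.id)
        if pid in seen:
            raise ValidationError(f"{path}: duplicate LR pair id {pid!r}")
        seen.add(pid)
        lig = _split_subunits(row.ligand, path, row_num, "ligand")
        rec = _split_subunits(row.receptor, path, row_num, "receptor")
        if known is not None:
            absent = [g for g in lig + rec if g not in known]
            if absent:
                logger.warning(
                    "dropping LR pair %s: genes %s not in panel", pid, absent)
                continue
        pairs.append(LRPair(pid, tuple(lig), tuple(rec)))
    return pairs


def _split_subunits(value, path, row_num, side) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValidationError(f"{path} row {row_num}: empty {side} field")
    parts = [p.strip() for p in str(value).split(COMPLEX_SEPARATOR)]
    if any(not p for p in parts):
        raise ValidationError(f"{path} row {row_num}: empty {side} subunit")
    return parts


def read_prior_network(
    path,
    kind: NetworkKind = NetworkKind.GRN,
    gene_names: Sequence[str] | None = None,
) -> PriorNetwork:
    """Read a 2-column edge list (source,target); unknown genes dropped."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns source,target")
    edges = set()
    known = set(gene_names) if gene_names is not None else None
    dropped = 0
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if known is not None and (a not in known or b not in known):
            dropped += 1
            continue
        edges.add((a, b))
    if dropped:
        logger.warning("dropped %d prior edges with genes not in panel", dropped)
    return PriorNetwork(edges=edges, kind=kind)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_spatial_dataset(data: SpatialExpression, out_dir) -> dict[str, Path]:
    """Write matrix-market + sidecar CSVs; inverse of read_spatial_dataset."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "expression.mtx",
        "coordinates": out_dir / "coordinates.csv",
        "cell_types": out_dir / "cell_types.csv",
    }
    mmwrite(paths["matrix"], sp.coo_matrix(data.X_obs))
    (out_dir / "expression_cells.txt").write_text(
        "\n".join(data.cell_ids) + "\n")
    (out_dir / "expression_genes.txt").write_text(
        "\n".join(data.gene_names) + "\n")
    pd.DataFrame(
        {"cell_id": data.cell_ids, "x": data.C[:, 0], "y": data.C[:, 1]}
    ).to_csv(paths["coordinates"], index=False)
    tnames = data.cell_type_names or [f"type_{j}" for j in range(data.n_cell_types)]
    tdf = pd.DataFrame(data.T, columns=tnames)
    tdf.insert(0, "cell_id", data.cell_ids)
    tdf.to_csv(paths["cell_types"], index=False)
    return paths


def write_lr_table(pairs: Sequence[LRPair], path) -> None:
    pd.DataFrame({
        "id": [p.id for p in pairs],
        "ligand": [COMPLEX_SEPARATOR.join(p.ligand_subunits) for p in pairs],
        "receptor": [COMPLEX_SEPARATOR.join(p.receptor_subunits) for p in pairs],
    }).to_csv(path, index=False)


def write_prior_network(prior: PriorNetwork, path) -> None:
    rows = sorted(prior.edges)
    pd.DataFrame(rows, columns=["source", "target"]).to_csv(path, index=False)
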