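"""Multi-view graph-neural imputation of spatial gene expression.

The imputed matrix decomposes additively into a cell-type baseline and one
micro-environment component per active ligand-receptor pair:

    X_hat = X_hat_b + sum_lr X_hat_s_lr'

Each LR view runs its own GNN encoder over the communication graph (node
features = the cell-type matrix T), a decoder MLP maps embeddings to genes
(shared across views by default), and an optional binary gene mask derived
from a GRN/PPI prior zeroes genes the pair cannot plausibly regulate.
Training minimizes MSE over the *non-zero* entries of the observed matrix
with Adam and patience-based early stopping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .ccc import CCCView, MultiViewCCC
from .data import LRPair, PriorNetwork, SpatialExpression

logger = logging.getLogger(__name__)

GNN_ARCHITECTURES = ("graph_transformer", "gcn", "gat", "graphsage")


@dataclass
class ModelConfig:
    """Hyperparameters of the imputation model.

    Defaults: hidden dimension 32, two GNN layers, graph-transformer
    encoder, Adam at learning rate 0.01, at most 1000 epochs with patience
    10. ``min_delta_regulatory`` is the minimum loss decrease counted as
    improvement when training for regulatory scoring (0 for imputation).
    """

    d: int = 32
    L: int = 2
    gnn_arch: str = "graph_transformer"
    learning_rate: float = 0.01
    max_epochs: int = 1000
    patience: int = 10
    min_delta_regulatory: float = 0.001
    share_gnn_across_views: bool = False
    per_view_decoder: bool = False
    use_prior_mask: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.d < 1 or self.L < 1:
            raise ValueError("d and L must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.gnn_arch not in GNN_ARCHITECTURES:
            raise ValueError(f"unknown gnn_arch {self.gnn_arch!r}")


@dataclass
class GeneMask:
    """Binary per-gene regulation mask for one LR pair."""

    lr: LRPair
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.float64)
        if not np.isin(self.mask, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")


@dataclass
class ImputationResult:
    """Trained decomposition: X_hat = X_hat_b + sum of per-LR components."""

    X_hat: np.ndarray
    X_hat_b: np.ndarray
    components: dict[str, np.ndarray]
    training_log: list[dict]
    views_used: list[str]

    def micro_environment(self) -> np.ndarray:
        return self.X_hat - self.X_hat_b


class TrainingError(RuntimeError):
    pass


def derive_gene_mask(
    prior: PriorNetwork | None,
    lr: LRPair,
    gene_names: Sequence[str],
    hops: int = 2,
) -> GeneMask:
    """Genes reachable from the receptor within ``hops`` prior-network steps.

    Receptor subunits themselves are always marked. If the prior is missing
    or contains no edge touching the receptor, the mask falls back to all
    ones (no constraint available) with a warning.
    """
    if hops < 1:
        raise ValueError("hops must be >= 1")
    names = list(gene_names)
    if prior is None or not prior.edges:
        if prior is not None:
            logger.warning("empty prior network; all-ones mask for %s", lr.id)
        return GeneMask(lr, np.ones(len(names)))
    touched = {g for e in prior.edges for g in e}
    if not any(r in touched for r in lr.receptor_subunits):
        logger.warning(
            "receptor of %s absent from prior network; all-ones mask", lr.id)
        return GeneMask(lr, np.ones(len(names)))
    frontier = set(lr.receptor_subunits)
    reach = set(frontier)
    for _ in range(hops):
        frontier = {s for g in frontier for s in prior.successors(g)} - reach
        if not frontier:
            break
        reach |= frontier
    mask = np.array([1.0 if g in reach else 0.0 for g in names])
    return GeneMask(lr, mask)


def build_masks(
    prior: PriorNetwork | None,
    lr_table: Sequence[LRPair],
    gene_names: Sequence[str],
    hops: int = 2,
    use_prior_mask: bool = True,
) -> dict[str, GeneMask]:
    if not use_prior_mask:
        prior = None
    return {lr.id: derive_gene_mask(prior, lr, gene_names, hops)
            for lr in lr_table}


# ---------------------------------------------------------------------------
# neural building blocks
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return ad.parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


class _MLP:
    """One-hidden-layer perceptron; relu hidden, optional softplus output."""

    def __init__(self, rng, in_dim, hidden, out_dim, out_softplus=True):
        self.W1 = _glorot(rng, in_dim, hidden)
        self.b1 = ad.parameter(np.zeros(hidden))
        self.W2 = _glorot(rng, hidden, out_dim)
        self.b2 = ad.parameter(np.zeros(out_dim))
        self.out_softplus = out_softplus

    def forward(self, X: Tensor) -> Tensor:
        h = ad.relu(ad.matmul(X, self.W1) + self.b1)
        out = ad.matmul(h, self.W2) + self.b2
        return ad.softplus(out) if self.out_softplus else out

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2]


@dataclass
class _ViewArrays:
    """Precomputed constant pieces of one CCC view for the encoders."""

    src: np.ndarray
    dst: np.ndarray
    w: np.ndarray
    logw: np.ndarray
    coef: np.ndarray  # receiver-normalized weights (gcn / graphsage)
    n: int

    @classmethod
    def from_view(cls, view: CCCView) -> "_ViewArrays":
        src, dst, w = view.arrays()
        n = view.n_cells
        denom = np.zeros(n)
        np.add.at(denom, dst, w)
        denom[denom == 0] = 1.0
        with np.errstate(divide="ignore"):
            logw = np.log(w)
        return cls(src=src, dst=dst, w=w, logw=logw, coef=w / denom[dst], n=n)


class _GNNEncoder:
    """L layers of weighted directed aggregation over one view's edges.

    All four architectures share the pattern ``out = aggregate(neighbors)
    + H @ W_self + b`` with relu; they differ in how incoming edges are
    weighted: fixed receiver-normalized weights (gcn, graphsage), or an
    attention softmax whose logits include the log edge weight (gat,
    graph_transformer).
    """

    def __init__(self, rng, arch, in_dim, d, L):
        self.arch = arch
        self.layers = []
        for layer in range(L):
            f_in = in_dim if layer == 0 else d
            p = {
                "W_self": _glorot(rng, f_in, d),
                "W_neigh": _glorot(rng, f_in, d),
                "b": ad.parameter(np.zeros(d)),
            }
            if arch == "graph_transformer":
                p["W_q"] = _glorot(rng, f_in, d)
                p["W_k"] = _glorot(rng, f_in, d)
            elif arch == "gat":
                p["a_src"] = _glorot(rng, d, 1)
                p["a_dst"] = _glorot(rng, d, 1)
            self.layers.append(p)
        self.d = d

    def forward(self, H: Tensor, va: _ViewArrays) -> Tensor:
        for p in self.layers:
            if self.arch == "gcn":
                # self-loop folded into the normalization, single weight matrix
                denom = np.ones(va.n)
                np.add.at(denom, va.dst, va.w)
                if len(va.src):
                    coef = ad.constant((va.w / denom[va.dst]).reshape(-1, 1))
                    agg = ad.segment_sum(
                        ad.gather_rows(H, va.src) * coef, va.dst, va.n)
                    mixed = agg + H * ad.constant((1.0 / denom).reshape(-1, 1))
                else:
                    mixed = H * ad.constant((1.0 / denom).reshape(-1, 1))
                H = ad.relu(ad.matmul(mixed, p["W_neigh"]) + p["b"])
                continue
            msg = ad.matmul(H, p["W_neigh"])  # (n, d)
            if len(va.src):
                if self.arch == "graphsage":
                    attn = ad.constant(va.coef)
                elif self.arch == "graph_transformer":
                    q = ad.gather_rows(ad.matmul(H, p["W_q"]), va.dst)
                    k = ad.gather_rows(ad.matmul(H, p["W_k"]), va.src)
                    score = ad.tsum(q * k, axis=1) / np.sqrt(self.d)
                    attn = ad.segment_softmax(
                        score + ad.constant(va.logw), va.dst, va.n)
                else:  # gat
                    hs = ad.gather_rows(msg, va.src)
                    hd = ad.gather_rows(msg, va.dst)
                    score = ad.tsum(
                        ad.leaky_relu(ad.matmul(hs, p["a_src"])
                                      + ad.matmul(hd, p["a_dst"])), axis=1)
                    attn = ad.segment_softmax(
                        score + ad.constant(va.logw), va.dst, va.n)
                weighted = ad.gather_rows(msg, va.src) * _col(attn)
                agg = ad.segment_sum(weighted, va.dst, va.n)
            else:
                agg = ad.constant(np.zeros((va.n, self.d)))
            H = ad.relu(agg + ad.matmul(H, p["W_self"]) + p["b"])
        return H

    def parameters(self):
        return [t for p in self.layers for t in p.values()]


def _col(v: Tensor) -> Tensor:
    """Reshape a length-E tensor to (E, 1) for row-wise scaling."""
    out = v.data.reshape(-1, 1)
    return v._make(out, (v,), lambda g: (g.reshape(v.data.shape),))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class ImputationModel:
    """Holds all trainable pieces; views can be added across iterations.

    New views receive freshly initialized encoders (and decoders when
    ``per_view_decoder``); existing parameters persist, so an outer
    refinement loop warm-starts from the previous iteration.
    """

    def __init__(self, n_genes: int, n_cell_types: int, config: ModelConfig):
        self.config = config
        self.n_genes = n_genes
        self.n_cell_types = n_cell_types
        self._rng = np.random.default_rng(config.seed)
        self.baseline_mlp = _MLP(self._rng, n_cell_types, config.d, n_genes)
        self.shared_decoder = _MLP(self._rng, config.d, config.d, n_genes)
        self.shared_encoder: _GNNEncoder | None = None
        if config.share_gnn_across_views:
            self.shared_encoder = _GNNEncoder(
                self._rng, config.gnn_arch, n_cell_types, config.d, config.L)
        self.encoders: dict[str, _GNNEncoder] = {}
        self.decoders: dict[str, _MLP] = {}

    def ensure_view(self, lr_id: str) -> None:
        if self.config.share_gnn_across_views:
            pass
        elif lr_id not in self.encoders:
            self.encoders[lr_id] = _GNNEncoder(
                self._rng, self.config.gnn_arch,
                self.n_cell_types, self.config.d, self.config.L)
        if self.config.per_view_decoder and lr_id not in self.decoders:
            self.decoders[lr_id] = _MLP(
                self._rng, self.config.d, self.config.d, self.n_genes)

    def encoder_for(self, lr_id: str) -> _GNNEncoder:
        if self.config.share_gnn_across_views:
            assert self.shared_encoder is not None
            return self.shared_encoder
        return self.encoders[lr_id]

    def decoder_for(self, lr_id: str) -> _MLP:
        if self.config.per_view_decoder:
            return self.decoders[lr_id]
        return self.shared_decoder

    def parameters(self, lr_ids: Sequence[str]):
        params = list(self.baseline_mlp.parameters())
        if self.config.per_view_decoder:
            for lr_id in lr_ids:
                params += self.decoders[lr_id].parameters()
        else:
            params += self.shared_decoder.parameters()
        if self.config.share_gnn_across_views:
            params += self.shared_encoder.parameters()
        else:
            for lr_id in lr_ids:
                params += self.encoders[lr_id].parameters()
        return params

    def forward(
        self,
        T: np.ndarray,
        view_arrays: dict[str, _ViewArrays],
        masks: dict[str, np.ndarray] | None,
    ) -> tuple[Tensor, Tensor, dict[str, Tensor]]:
        T_const = ad.constant(T)
        X_b = self.baseline_mlp.forward(T_const)
        components: dict[str, Tensor] = {}
        X_hat = X_b
        for lr_id in sorted(view_arrays):
            H = self.encoder_for(lr_id).forward(T_const, view_arrays[lr_id])
            comp = self.decoder_for(lr_id).forward(H)
            if masks is not None and lr_id in masks:
                comp = comp * ad.constant(masks[lr_id][None, :])
            components[lr_id] = comp
            X_hat = X_hat + comp
        return X_hat, X_b, components


# ---------------------------------------------------------------------------
# elementary operations (public, numpy level)
# ---------------------------------------------------------------------------

def apply_mask(X_hat_s_lr: np.ndarray, mask: GeneMask) -> np.ndarray:
    """Column-wise product with the binary gene mask."""
    return np.asarray(X_hat_s_lr) * mask.mask[None, :]


def combine(X_hat_b: np.ndarray, components: dict[str, np.ndarray]) -> np.ndarray:
    """X_hat = baseline + sum of masked per-LR components (order-free)."""
    out = np.array(X_hat_b, dtype=np.float64)
    for comp in components.values():
        if comp.shape != out.shape:
            raise ValueError(
                f"component shape {comp.shape} != baseline {out.shape}")
        out = out + comp
    return out


def masked_mse(
    X_hat: np.ndarray,
    X_obs: np.ndarray,
    weight: np.ndarray | None = None,
) -> float:
    """MSE over non-zero entries of X_obs (optionally a custom indicator)."""
    X_hat = np.asarray(X_hat, dtype=np.float64)
    X_obs = np.asarray(X_obs, dtype=np.float64)
    w = (X_obs != 0).astype(np.float64) if weight is None else weight
    count = w.sum()
    if count == 0:
        raise ValueError("masked MSE undefined: no counted entries")
    return float((w * (X_hat - X_obs) ** 2).sum() / count)


def encode_view(T: np.ndarray, view: CCCView, config: ModelConfig):
    """Standalone single-view encoding (n x d), seeded by config.seed."""
    rng = np.random.default_rng(config.seed)
    enc = _GNNEncoder(rng, config.gnn_arch, T.shape[1], config.d, config.L)
    H = enc.forward(ad.constant(np.asarray(T, dtype=np.float64)),
                    _ViewArrays.from_view(view))
    if not np.isfinite(H.data).all():
        raise TrainingError(f"non-finite embedding for view {view.lr.id}")
    return H.data


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    data: SpatialExpression,
    multiview: MultiViewCCC,
    masks: dict[str, GeneMask] | None,
    config: ModelConfig,
    model: ImputationModel | None = None,
    val_indices: tuple[np.ndarray, np.ndarray] | None = None,
    exclude_indices: tuple[np.ndarray, np.ndarray] | None = None,
    min_delta: float = 0.0,
) -> tuple[ImputationResult, ImputationModel]:
    """Fit all parameters against the masked MSE; return the decomposition.

    The loss counts non-zero entries of ``X_obs`` only. Entries listed in
    ``val_indices`` or ``exclude_indices`` (e.g. a held-out test set) are
    removed from the training loss; validation loss, when available, drives
    early stopping, otherwise the training loss does. Stops after
    ``config.patience`` epochs without an improvement larger than
    ``min_delta`` and restores the best parameters seen.
    """
    X_obs = np.asarray(data.X_obs.todense(), dtype=np.float64)
    train_w = (X_obs != 0).astype(np.float64)
    for idx in (val_indices, exclude_indices):
        if idx is not None:
            train_w[idx] = 0.0
    if train_w.sum() == 0:
        raise ValueError("no non-zero training entries")
    val_w = None
    if val_indices is not None:
        val_w = np.zeros_like(train_w)
        val_w[val_indices] = (X_obs[val_indices] != 0).astype(np.float64)
        if val_w.sum() == 0:
            val_w = None

    if model is None:
        model = ImputationModel(data.n_genes, data.n_cell_types, config)
    lr_ids = multiview.lr_ids
    for lr_id in lr_ids:
        model.ensure_view(lr_id)
    view_arrays = {
        lr_id: _ViewArrays.from_view(multiview.views[lr_id])
        for lr_id in lr_ids
    }
    mask_arrays = None
    if masks is not None:
        mask_arrays = {lr_id: masks[lr_id].mask for lr_id in lr_ids
                       if lr_id in masks}

    params = model.parameters(lr_ids)
    opt = ad.Adam(params, lr=config.learning_rate)
    n_count = train_w.sum()
    obs_const = ad.constant(X_obs)
    w_const = ad.constant(train_w)

    best = np.inf
    best_state = [p.data.copy() for p in params]
    bad = 0
    log: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        opt.zero_grad()
        X_hat_t, _, _ = model.forward(data.T, view_arrays, mask_arrays)
        diff = X_hat_t - obs_const
        loss_t = ad.tsum(w_const * diff * diff) / n_count
        train_loss = float(loss_t.data)
        if not np.isfinite(train_loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        loss_t.backward()
        opt.step()
        val_loss = None
        if val_w is not None:
            val_loss = masked_mse(X_hat_t.data, X_obs, val_w)
        log.append({"epoch": epoch, "train_loss": train_loss,
                    "val_loss": val_loss})
        monitored = val_loss if val_loss is not None else train_loss
        if monitored < best - min_delta:
            best = monitored
            best_state = [p.data.copy() for p in params]
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    for p, saved in zip(params, best_state):
        p.data = saved

    X_hat_t, X_b_t, comp_t = model.forward(data.T, view_arrays, mask_arrays)
    result = ImputationResult(
        X_hat=X_hat_t.data.copy(),
        X_hat_b=X_b_t.data.copy(),
        components={k: v.data.copy() for k, v in comp_t.items()},
        training_log=log,
        views_used=list(lr_ids),
    )
    return result, model
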