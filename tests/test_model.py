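import numpy as np
import pytest
import scipy.sparse as sp

from intercell.ccc import CCCView, MultiViewCCC, assemble_multiview
from intercell.data import NetworkKind, PriorNetwork, SpatialExpression
from intercell.model import (
    GeneMask,
    ImputationModel,
    ModelConfig,
    apply_mask,
    build_masks,
    combine,
    derive_gene_mask,
    encode_view,
    masked_mse,
    train,
)

from conftest import lr


class TestGeneMask:
    GENES = ["R", "A", "B", "C"]

    def test_one_hop_reaches_direct_targets_only(self):
        prior = PriorNetwork({("R", "A"), ("A", "B")})
        m = derive_gene_mask(prior, lr("p", ["L"], ["R"]), self.GENES, hops=1)
        assert m.mask.tolist() == [1, 1, 0, 0]

    def test_two_hops_extend_the_chain(self):
        prior = PriorNetwork({("R", "A"), ("A", "B")})
        m = derive_gene_mask(prior, lr("p", ["L"], ["R"]), self.GENES, hops=2)
        assert m.mask.tolist() == [1, 1, 1, 0]

    def test_empty_prior_falls_back_to_all_ones(self):
        m = derive_gene_mask(PriorNetwork(set()), lr("p", ["L"], ["R"]),
                             self.GENES)
        assert m.mask.tolist() == [1, 1, 1, 1]

    def test_receptor_absent_from_prior_gives_all_ones(self):
        prior = PriorNetwork({("A", "B")})
        m = derive_gene_mask(prior, lr("p", ["L"], ["R"]), self.GENES)
        assert m.mask.tolist() == [1, 1, 1, 1]

    def test_ppi_edges_are_bidirectional(self):
        prior = PriorNetwork({("A", "R")}, kind=NetworkKind.PPI)
        m = derive_gene_mask(prior, lr("p", ["L"], ["R"]), self.GENES, hops=1)
        assert m.mask.tolist() == [1, 1, 0, 0]

    def test_disabled_prior_gives_all_ones_for_every_pair(self):
        prior = PriorNetwork({("R", "A")})
        masks = build_masks(prior, [lr("p", ["L"], ["R"])], self.GENES,
                            use_prior_mask=False)
        assert masks["p"].mask.tolist() == [1, 1, 1, 1]


class TestElementaryOps:
    def test_apply_mask_examples(self):
        X = np.array([[5.0, 7.0]])
        pair = lr("p", ["L"], ["R"])
        assert apply_mask(X, GeneMask(pair, [1, 1])).tolist() == [[5, 7]]
        assert apply_mask(X, GeneMask(pair, [0, 0])).tolist() == [[0, 0]]
        assert apply_mask(X, GeneMask(pair, [1, 0])).tolist() == [[5, 0]]

    def test_combine_examples(self):
        base = np.array([[1.0]])
        assert combine(base, {}).tolist() == [[1.0]]
        out = combine(base, {"a": np.array([[2.0]]), "b": np.array([[3.0]])})
        assert out.tolist() == [[6.0]]

    def test_combine_shape_mismatch(self):
        with pytest.raises(ValueError):
            combine(np.ones((2, 2)), {"a": np.ones((2, 3))})

    def test_masked_mse_counts_only_nonzero_observed(self):
        X_hat = np.array([[1.0, 0.0], [2.0, 3.0]])
        X_obs = np.array([[2.0, 0.0], [2.0, 4.0]])
        assert masked_mse(X_hat, X_obs) == pytest.approx(2 / 3)
        assert masked_mse(X_obs, X_obs) == 0.0
        # perturbing positions where X_obs == 0 leaves the loss unchanged
        X_hat2 = X_hat.copy()
        X_hat2[0, 1] = 99.0
        assert masked_mse(X_hat2, X_obs) == masked_mse(X_hat, X_obs)

    def test_masked_mse_all_zero_is_undefined(self):
        with pytest.raises(ValueError):
            masked_mse(np.ones((2, 2)), np.zeros((2, 2)))


def _tiny_view(n=4, seed=0):
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.5, 2.0, size=(n, n))
    np.fill_diagonal(W, 0.0)
    return CCCView(lr=lr("p", ["L"], ["R"]), edges=sp.csr_matrix(W))


class TestEncoders:
    @pytest.mark.parametrize("arch", ["graph_transformer", "gcn", "gat",
                                      "graphsage"])
    def test_shape_determinism_and_finiteness(self, arch):
        T = np.eye(2)[[0, 1, 0, 1]].astype(float)
        cfg = ModelConfig(d=8, gnn_arch=arch, seed=3)
        H1 = encode_view(T, _tiny_view(), cfg)
        H2 = encode_view(T, _tiny_view(), cfg)
        assert H1.shape == (4, 8)
        assert np.array_equal(H1, H2)
        assert np.isfinite(H1).all()

    @pytest.mark.parametrize("arch", ["graph_transformer", "gcn", "gat",
                                      "graphsage"])
    def test_isolated_cell_depends_only_on_own_features(self, arch):
        """A cell with no incoming edges encodes as if it were alone."""
        W = np.zeros((3, 3))
        W[1, 2] = 1.0  # cell 0 receives nothing
        view = CCCView(lr=lr("p", ["L"], ["R"]), edges=sp.csr_matrix(W))
        T = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        cfg = ModelConfig(d=6, gnn_arch=arch, seed=1)
        H = encode_view(T, view, cfg)
        lone = CCCView(lr=lr("p", ["L"], ["R"]),
                       edges=sp.csr_matrix(np.zeros((1, 1))))
        H_alone = encode_view(T[:1], lone, cfg)
        assert H[0] == pytest.approx(H_alone[0])


def _constant_type_dataset(mu=4.0, n=30):
    X = np.full((n, 3), mu)
    return SpatialExpression(
        X_obs=sp.csr_matrix(X),
        C=np.random.default_rng(0).uniform(0, 10, (n, 2)),
        T=np.ones((n, 1)),
        gene_names=["a", "b", "c"],
        cell_ids=[f"c{i}" for i in range(n)])


class TestTraining:
    def test_baseline_learns_constant_type_mean_without_views(self):
        data = _constant_type_dataset(mu=4.0)
        cfg = ModelConfig(d=8, seed=0, max_epochs=400, patience=30)
        result, _ = train(data, MultiViewCCC(views={}), None, cfg)
        assert result.X_hat_b == pytest.approx(4.0, abs=0.2)
        assert result.X_hat == pytest.approx(result.X_hat_b)

    def test_identical_type_rows_get_identical_baselines(self):
        data = _constant_type_dataset()
        cfg = ModelConfig(d=8, seed=0, max_epochs=30)
        result, _ = train(data, MultiViewCCC(views={}), None, cfg)
        assert np.allclose(result.X_hat_b, result.X_hat_b[0])

    def test_early_stopping_and_determinism(self, small_sim):
        mv = assemble_multiview(small_sim.data, small_sim.lr_table)
        masks = build_masks(small_sim.prior, small_sim.lr_table,
                            small_sim.data.gene_names)
        cfg = ModelConfig(d=8, seed=5, max_epochs=80)
        r1, _ = train(small_sim.data, mv, masks, cfg)
        r2, _ = train(small_sim.data, mv, masks, cfg)
        log1 = [e["train_loss"] for e in r1.training_log]
        log2 = [e["train_loss"] for e in r2.training_log]
        assert log1 == log2
        assert log1[-1] <= log1[0]

    def test_decomposition_identity_and_mask_conservation(self, trained_small,
                                                          small_sim):
        result, _, _, masks = trained_small
        total = result.X_hat_b + sum(result.components.values())
        assert np.abs(result.X_hat - total).max() < 1e-5
        # genes masked out in every trained view get exactly zero
        # micro-environment contribution
        joint = np.zeros(small_sim.data.n_genes)
        for lr_id in result.views_used:
            joint = np.maximum(joint, masks[lr_id].mask)
        blocked = np.where(joint == 0)[0]
        micro = result.micro_environment()
        for g in blocked:
            assert np.all(micro[:, g] == 0.0)

    def test_shared_decoder_maps_equal_embeddings_equally(self):
        cfg = ModelConfig(d=4, seed=0)
        model = ImputationModel(n_genes=3, n_cell_types=2, config=cfg)
        model.ensure_view("a")
        model.ensure_view("b")
        assert model.decoder_for("a") is model.decoder_for("b")
        cfg2 = ModelConfig(d=4, seed=0, per_view_decoder=True)
        model2 = ImputationModel(n_genes=3, n_cell_types=2, config=cfg2)
        model2.ensure_view("a")
        model2.ensure_view("b")
        assert model2.decoder_for("a") is not model2.decoder_for("b")

    def test_beats_column_mean_predictor_on_heldout_entries(self, small_sim):
        """Trained imputation must beat the naive per-gene mean baseline."""
        from intercell.evaluate import imputation_metrics, make_splits
        from intercell.iterate import run

        split = make_splits(small_sim.data.X_obs, 1, seed=21)[0]
        masks = build_masks(small_sim.prior, small_sim.lr_table,
                            small_sim.data.gene_names)
        cfg = ModelConfig(seed=21, d=16, max_epochs=300)
        result, _, _ = run(small_sim.data, small_sim.lr_table, masks, cfg,
                           max_iterations=1, val_indices=split.val_idx,
                           exclude_indices=split.test_idx)
        X = np.asarray(small_sim.data.X_obs.todense())
        train_mask = np.zeros_like(X, dtype=bool)
        train_mask[split.train_idx] = True
        col_mean = np.where(
            train_mask.sum(0) > 0,
            (X * train_mask).sum(0) / np.maximum(train_mask.sum(0), 1), 0.0)
        baseline_pred = np.tile(col_mean, (X.shape[0], 1))
        _, rmse_model, _ = imputation_metrics(
            result.X_hat, small_sim.data.X_obs, split.test_idx)
        _, rmse_naive, _ = imputation_metrics(
            baseline_pred, small_sim.data.X_obs, split.test_idx)
        assert rmse_model < rmse_naive
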