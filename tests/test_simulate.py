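import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from intercell.simulate import (
    PRESETS,
    SimulationConfig,
    assign_cell_types,
    generate,
    mask_to_density,
    plant_communication,
    preset_config,
    sample_expression,
)


class TestCellTypeAssignment:
    def test_every_cell_gets_exactly_one_type(self):
        rng = np.random.default_rng(0)
        coords, labels = assign_cell_types(200, 100.0, 4, 2, rng)
        assert coords.shape == (200, 2)
        assert labels.shape == (200,)
        assert set(labels) <= set(range(4))

    def test_kb_one_with_two_types_splits_plane_in_two(self):
        rng = np.random.default_rng(1)
        coords, labels = assign_cell_types(500, 100.0, 2, 1, rng)
        # one anchor per type: the boundary is a single line, both sides occupied
        assert len(set(labels)) == 2

    def test_higher_kb_fragments_territories(self):
        """More anchors per type produce more spatially connected same-type
        patches (stronger mixing), averaged over seeds."""
        def n_components(k_b, seed):
            rng = np.random.default_rng(seed)
            coords, labels = assign_cell_types(400, 100.0, 3, k_b, rng)
            tree = cKDTree(coords)
            _, idx = tree.query(coords, k=7)
            total = 0
            for t in range(3):
                cells = np.where(labels == t)[0]
                if len(cells) == 0:
                    continue
                pos = {c: i for i, c in enumerate(cells)}
                rows, cols = [], []
                for c in cells:
                    for nb in idx[c, 1:]:
                        if labels[nb] == t:
                            rows.append(pos[c])
                            cols.append(pos[nb])
                adj = sp.csr_matrix(
                    (np.ones(len(rows)), (rows, cols)),
                    shape=(len(cells), len(cells)))
                total += connected_components(adj, directed=False)[0]
            return total

        low = np.mean([n_components(2, s) for s in range(5)])
        high = np.mean([n_components(20, s) for s in range(5)])
        assert high > low


class TestExpressionSampling:
    def test_counts_are_nonnegative_integers(self):
        cfg = SimulationConfig(n_cells=100, seed=0)
        rng = np.random.default_rng(0)
        _, labels = assign_cell_types(100, 100.0, cfg.n_cell_types, 2, rng)
        X, _ = sample_expression(labels, cfg, rng)
        assert (X >= 0).all()
        assert np.array_equal(X, np.round(X))

    def test_marker_and_background_means_match_nb_formula(self):
        """Empirical means agree with the NB mean n(1-p)/p within 3 SE."""
        cfg = SimulationConfig(n_cells=1000, seed=0)
        rng = np.random.default_rng(0)
        labels = rng.integers(0, cfg.n_cell_types, 1000)
        X, markers = sample_expression(labels, cfg, rng)
        n_h, p_h = cfg.nb_high
        n_l, p_l = cfg.nb_low
        mean_h = n_h * (1 - p_h) / p_h          # 8.0 at setting 1
        var_h = n_h * (1 - p_h) / p_h ** 2
        mean_l = n_l * (1 - p_l) / p_l          # 0.5 at setting 1
        var_l = n_l * (1 - p_l) / p_l ** 2
        own = X[labels == 0][:, markers[0]]
        se_h = np.sqrt(var_h / own.size)
        assert abs(own.mean() - mean_h) < 3 * se_h
        other = X[labels == 0][:, markers[1]]
        se_l = np.sqrt(var_l / other.size)
        assert abs(other.mean() - mean_l) < 3 * se_l


class TestCommunicationPlanting:
    def test_zone_elevates_target_gene(self):
        cfg = SimulationConfig(n_cells=400, n_lr_pairs=10, seed=2)
        rng = np.random.default_rng(2)
        coords, labels = assign_cell_types(
            400, 100.0, cfg.n_cell_types, cfg.k_b, rng)
        X0, _ = sample_expression(labels, cfg, rng)
        X, lr_table, truth, zones = plant_communication(X0, coords, cfg, rng)
        target_of = {}
        for (c, g), lrs in truth.items():
            for lr_id in lrs:
                target_of.setdefault(lr_id, g)
        elevated = 0
        for lr_id, (cx, cy), r in zones:
            g = target_of[lr_id]
            dist = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
            inside = dist <= r
            # planting only ever adds counts
            assert np.all(X >= X0)
            if X[inside, g].mean() > X0[inside, g].mean():
                elevated += 1
        assert elevated >= 8  # at least 8 of 10 zones gained target counts

    def test_cells_outside_every_zone_have_no_truth(self):
        sim = generate(SimulationConfig(n_cells=300, n_lr_pairs=5, seed=3))
        in_any = set()
        for lr_id, (cx, cy), r in sim.zones:
            dist = np.hypot(sim.data.C[:, 0] - cx, sim.data.C[:, 1] - cy)
            in_any |= set(np.where(dist <= r)[0])
        cells_with_truth = {c for c, _ in sim.truth}
        assert cells_with_truth <= in_any

    def test_zone_count_equals_pair_count(self):
        sim = generate(SimulationConfig(n_cells=200, n_lr_pairs=7, seed=1))
        assert len(sim.zones) == 7
        assert len(sim.lr_table) == 7


class TestMasking:
    def test_masking_is_a_subset_of_nonzeros(self):
        rng = np.random.default_rng(0)
        dense = rng.integers(0, 4, (50, 20)).astype(float)
        masked = mask_to_density(dense, 0.2, np.random.default_rng(1))
        changed = dense != masked
        assert (masked[changed] == 0).all()
        assert (dense[changed] != 0).all()

    def test_full_density_on_dense_input_is_identity(self):
        dense = np.ones((10, 10))
        out = mask_to_density(dense, 1.0, np.random.default_rng(0))
        assert np.array_equal(out, dense)

    def test_unreachable_density_is_an_error(self):
        dense = np.zeros((10, 10))
        dense[0, 0] = 1.0
        with pytest.raises(ValueError, match="density"):
            mask_to_density(dense, 0.5, np.random.default_rng(0))


class TestGenerate:
    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(n_cells=150, n_lr_pairs=6, seed=9)
        a, b = generate(cfg), generate(cfg)
        assert (a.data.X_obs != b.data.X_obs).nnz == 0
        assert np.array_equal(a.data.C, b.data.C)
        assert a.truth == b.truth
        assert a.zones == b.zones
        assert a.prior.edges == b.prior.edges

    def test_presets_differ_as_documented(self):
        c8, c9 = preset_config(8), preset_config(9)
        assert c9.k_b == 20 and c8.k_b == 10
        assert (c8.r, c8.nb_high, c8.nb_low, c8.nb_comm) == \
            (c9.r, c9.nb_high, c9.nb_low, c9.nb_comm)

    def test_all_nine_presets_generate_with_truth(self):
        for setting in PRESETS:
            sim = generate(preset_config(setting, n_cells=200,
                                         n_lr_pairs=10, seed=setting))
            assert len(sim.truth) > 0
            density = sim.data.X_obs.nnz / (200 * sim.config.n_genes)
            assert abs(density - 0.2) <= 1.0 / (200 * sim.config.n_genes)

    def test_oracle_ranker_on_dense_truth_has_perfect_precision(self):
        """The planted ground truth is self-consistent: an oracle that knows
        the zones and target assignment retrieves every truth entry."""
        sim = generate(SimulationConfig(n_cells=250, n_lr_pairs=8, seed=4))
        target_of = {}
        for (c, g), lrs in sim.truth.items():
            for lr_id in lrs:
                target_of[lr_id] = g
        zone_members = {}
        for lr_id, (cx, cy), r in sim.zones:
            dist = np.hypot(sim.data.C[:, 0] - cx, sim.data.C[:, 1] - cy)
            zone_members[lr_id] = set(np.where(dist <= r)[0])
        hits = 0
        for (c, g), lrs in sim.truth.items():
            # oracle top-1: the pair whose zone contains c and targets g
            oracle = [lr_id for lr_id in target_of
                      if target_of[lr_id] == g and c in zone_members[lr_id]]
            if set(oracle) >= lrs:
                hits += 1
        assert hits == len(sim.truth)
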