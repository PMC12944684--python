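import numpy as np
import pytest
from rdkit import Chem
from scipy import stats

from cypred.chemio import StandardMolecule, standardize_structure
from cypred.featurize import build_dual_graph
from cypred.graph_model import (
    ContrastConfig,
    EncoderConfig,
    MixupConfig,
    RingGNNRegressor,
    augment_view,
    encode,
    info_nce_loss,
    init_params,
    make_batch,
    mix_pair,
    pair_score,
    sample_mix_lambda,
    select_mix_pairs,
    train_regressor,
)


def relabeled_graph(smiles: str, seed: int):
    m = standardize_structure(smiles)
    perm = [int(i) for i in np.random.default_rng(seed).permutation(m.graph_handle.GetNumAtoms())]
    shuffled = Chem.RenumberAtoms(m.graph_handle, perm)
    return build_dual_graph(
        StandardMolecule(Chem.MolToSmiles(shuffled, canonical=False), False, shuffled)
    )


class TestEncoder:
    def test_isomorphism_invariance_over_20_relabelings(self):
        cfg = EncoderConfig(n_layers=2, hidden_dim=8, seed=5)
        params = init_params(cfg)
        base = encode(build_dual_graph(standardize_structure("c1ccc2[nH]ccc2c1CCO")), params, cfg)
        for seed in range(20):
            other = encode(relabeled_graph("c1ccc2[nH]ccc2c1CCO", seed), params, cfg)
            assert np.allclose(base, other, atol=1e-6)

    def test_zero_depth_equals_mean_of_projected_features(self):
        from cypred.graph_model import encode_node_features

        cfg = EncoderConfig(n_layers=0, hidden_dim=4, seed=1)
        params = init_params(cfg)
        g = build_dual_graph(standardize_structure("CCO"))
        expected = (encode_node_features(g) @ params["w_in"].data + params["b_in"].data).mean(axis=0)
        assert np.allclose(encode(g, params, cfg), expected)

    def test_ringless_molecule_encodes(self):
        cfg = EncoderConfig(n_layers=2, hidden_dim=4, seed=0)
        emb = encode(build_dual_graph(standardize_structure("CCO")), init_params(cfg), cfg)
        assert emb.shape == (4,) and np.isfinite(emb).all()

    def test_sum_readout_scales_with_size(self):
        cfg = EncoderConfig(n_layers=0, hidden_dim=3, readout="sum", seed=2)
        params = init_params(cfg)
        g = build_dual_graph(standardize_structure("CCCC"))
        cfg_mean = EncoderConfig(n_layers=0, hidden_dim=3, readout="mean", seed=2)
        assert np.allclose(encode(g, params, cfg), 4 * encode(g, params, cfg_mean))


class TestAugmentView:
    def test_zero_rates_identity(self, small_graphs):
        cfg = ContrastConfig(atom_mask_rate=0, bond_drop_rate=0, subgraph_drop_rate=0)
        for g in small_graphs:
            v = augment_view(g, cfg, seed=1)
            assert np.array_equal(v.node_features, g.node_features)
            assert np.array_equal(v.edge_list, g.edge_list)
            assert not v.node_mask.any()

    def test_full_masking_keeps_topology(self):
        g = build_dual_graph(standardize_structure("c1ccncc1CC"))
        cfg = ContrastConfig(atom_mask_rate=1.0, bond_drop_rate=0, subgraph_drop_rate=0)
        v = augment_view(g, cfg, seed=3)
        assert v.node_mask.all()
        assert np.array_equal(v.edge_list, g.edge_list)
        assert v.rings == g.rings

    def test_seed_determinism(self, small_graphs):
        cfg = ContrastConfig()
        for g in small_graphs[:4]:
            a = augment_view(g, cfg, seed=7)
            b = augment_view(g, cfg, seed=7)
            assert np.array_equal(a.node_features, b.node_features)
            assert np.array_equal(a.edge_list, b.edge_list)
            assert np.array_equal(a.node_mask, b.node_mask)

    def test_subgraph_removal_bounds_and_validity(self):
        g = build_dual_graph(standardize_structure("c1ccc2ccccc2c1CCCCO"))
        cfg = ContrastConfig(atom_mask_rate=0, bond_drop_rate=0, subgraph_drop_rate=0.3)
        for seed in range(10):
            v = augment_view(g, cfg, seed)
            assert v.num_atoms >= g.num_atoms - int(0.3 * g.num_atoms)
            v.validate()


class TestInfoNCE:
    @pytest.mark.parametrize("B", [2, 8, 32])
    def test_identical_embeddings_closed_form(self, B):
        Z = np.tile([0.3, -1.2, 0.5], (2 * B, 1))
        assert np.isclose(info_nce_loss(Z, 0.1), np.log(2 * B - 1), atol=1e-9)

    def test_separated_positives_low_loss(self, rng):
        # positives identical, negatives orthogonal, small temperature -> ~0
        Z = np.zeros((8, 4))
        for k in range(4):
            Z[2 * k, k] = Z[2 * k + 1, k] = 1.0
        assert info_nce_loss(Z, 0.05) < 1e-6

    def test_invariant_to_negative_ordering(self, rng):
        Z = rng.normal(size=(12, 5))
        base = info_nce_loss(Z, 0.2)
        # permute the pair blocks
        order = rng.permutation(6)
        perm = np.concatenate([[2 * o, 2 * o + 1] for o in order])
        assert np.isclose(info_nce_loss(Z[perm], 0.2), base)


class TestPairScore:
    def test_identical_pair_scores_one(self, rng):
        h = rng.normal(size=6)
        assert np.isclose(pair_score(h, h, 40.0, 40.0, 100.0), 1.0)

    def test_reductions_and_arithmetic(self, rng):
        h1, h2 = rng.normal(size=5), rng.normal(size=5)
        cos = h1 @ h2 / (np.linalg.norm(h1) * np.linalg.norm(h2))
        assert np.isclose(pair_score(h1, h2, 10, 90, 100, w_g=1.0, w_y=0.0), cos)
        # s_g = 0.8, s_y = 0.6 -> S = 0.7
        a, b = np.array([1.0, 0.0]), np.array([0.8, 0.6])
        assert np.isclose(pair_score(a, b, 0, 40, 100), 0.5 * 0.8 + 0.5 * 0.6)

    def test_symmetry(self, rng):
        h1, h2 = rng.normal(size=5), rng.normal(size=5)
        assert np.isclose(pair_score(h1, h2, 10, 60, 100), pair_score(h2, h1, 60, 10, 100))

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError):
            pair_score(np.zeros(3), np.ones(3), 0, 0, 100)


class TestMixLambda:
    def test_mean_half_and_open_interval(self):
        rng = np.random.default_rng(123)
        draws = np.array([sample_mix_lambda(0.5, rng) for _ in range(100_000)])
        assert abs(draws.mean() - 0.5) < 0.01
        assert ((draws > 0) & (draws < 1)).all()

    def test_symmetry_two_sample(self):
        a = np.array([sample_mix_lambda(0.7, np.random.default_rng(1000 + i)) for i in range(3000)])
        b = 1 - np.array([sample_mix_lambda(0.7, np.random.default_rng(9000 + i)) for i in range(3000)])
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            sample_mix_lambda(0.0, 1)


class TestMixPair:
    def test_identity_and_midpoint(self, rng):
        h1, h2 = rng.normal(size=4), rng.normal(size=4)
        s = mix_pair(h1, h2, 20.0, 60.0, 1.0)
        assert np.allclose(s.h_tilde, h1) and s.y_tilde == 20.0
        assert mix_pair(h1, h2, 20.0, 60.0, 0.5).y_tilde == 40.0

    def test_coordinatewise_convexity(self, rng):
        h1, h2 = rng.normal(size=6), rng.normal(size=6)
        for lam in rng.uniform(0, 1, 20):
            s = mix_pair(h1, h2, 0.0, 100.0, float(lam))
            assert (s.h_tilde <= np.maximum(h1, h2) + 1e-12).all()
            assert (s.h_tilde >= np.minimum(h1, h2) - 1e-12).all()
            assert 0.0 <= s.y_tilde <= 100.0


class TestSelectPairs:
    def test_batch_of_two_selects_only_pair(self, rng):
        H = rng.normal(size=(2, 4))
        pairs = select_mix_pairs(H, np.array([10.0, 20.0]), MixupConfig(n_mix_per_batch=2, seed=0))
        assert [(i, j) for i, j, _ in pairs] == [(0, 1), (1, 0)]

    def test_weight_collapse_on_single_positive(self):
        # anchor 0: candidate 1 scores 1, candidates 2,3 score -1
        H = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [-1.0, 0.0]])
        y = np.array([50.0, 50.0, 50.0, 50.0])
        cfg = MixupConfig(w_g=1.0, w_y=0.0, top_k=3, n_mix_per_batch=1, seed=0)
        for seed in range(20):
            pairs = select_mix_pairs(H, y, cfg, rng=seed)
            assert pairs[0][1] == 1

    def test_frequencies_proportional_to_positive_scores(self):
        H = np.array([[1.0, 0.0], [0.9, np.sqrt(1 - 0.81)], [0.2, np.sqrt(1 - 0.04)], [0.0, 1.0]])
        y = np.zeros(4)
        cfg = MixupConfig(w_g=1.0, w_y=0.0, top_k=3, n_mix_per_batch=1)
        S = H @ H.T
        w = np.maximum(S[0, 1:], 0)
        expected = w / w.sum()
        rng = np.random.default_rng(5)
        counts = np.zeros(4)
        n_draws = 10_000
        for _ in range(n_draws):
            pairs = select_mix_pairs(H, y, cfg, rng=rng)
            counts[pairs[0][1]] += 1
        freq = counts[1:] / n_draws
        assert np.abs(freq - expected).max() < 0.02


@pytest.fixture(scope="module")
def linear_task():
    # noiseless: label = 10 * n_heavy_atoms (pure size signal)
    smiles = ["C" * k for k in range(1, 9)] + ["CCO", "CCN", "CCCO", "CCCN"]
    y = np.array([10.0 * standardize_structure(s).num_atoms for s in smiles])
    return smiles, y


class TestTraining:
    def test_loss_decreases_on_linear_task(self, linear_task):
        smiles, y = linear_task
        est = RingGNNRegressor(hidden_dim=16, n_layers=1, epochs=40, batch_size=6, mixup=False, seed=0)
        est.fit(smiles, y)
        first = np.mean(est.loss_history_[:4])
        last = np.mean(est.loss_history_[-4:])
        assert last < first / 2

    def test_seed_determinism(self, linear_task):
        smiles, y = linear_task
        kw = dict(hidden_dim=8, n_layers=1, epochs=5, contrastive_epochs=1, seed=3)
        p1 = RingGNNRegressor(**kw).fit(smiles, y).predict(smiles)
        p2 = RingGNNRegressor(**kw).fit(smiles, y).predict(smiles)
        assert np.array_equal(p1, p2)

    def test_mixup_disabled_equals_zero_mix_per_batch(self, linear_task):
        smiles, y = linear_task
        a = RingGNNRegressor(hidden_dim=8, epochs=5, mixup=False, seed=2).fit(smiles, y)
        b = RingGNNRegressor(hidden_dim=8, epochs=5, mixup=True, n_mix_per_batch=0, seed=2).fit(smiles, y)
        assert np.array_equal(a.predict(smiles), b.predict(smiles))

    def test_out_of_fold_partition(self, tiny_benchmark):
        _, truth = tiny_benchmark
        smiles = [m.canonical for m in truth.molecules[:40]]
        models, oof = train_regressor(
            smiles, truth.labels[:40], n_folds=4, seed=1,
            hidden_dim=8, n_layers=1, epochs=2,
        )
        assert len(models) == 4
        assert np.isfinite(oof).all() and len(oof) == 40

    def test_too_few_samples_for_folds(self):
        with pytest.raises(ValueError):
            train_regressor(["CCO", "CCN"], [1.0, 2.0], n_folds=5)
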