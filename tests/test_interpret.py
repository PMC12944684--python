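import numpy as np
import pytest
from scipy import stats

from cypred.chemio import standardize_structure
from cypred.featurize import build_dual_graph
from cypred.interpret import (
    cohens_d,
    mean_difference_ci,
    occlude,
    point_biserial,
    sar_report,
    spearman_matrix,
)


class TestOcclusion:
    def test_constant_model_all_zero(self):
        amap = occlude(lambda g: 42.0, "c1ccncc1CC", "atom")
        assert np.allclose(amap.deltas, 0.0)

    def test_additive_stub_recovers_per_atom_contributions(self):
        # stub: sum of the atomic-number channel over unmasked atoms
        def stub(g):
            return float(g.node_features[~g.node_mask, 0].sum())

        g = build_dual_graph(standardize_structure("CCO"))
        amap = occlude(stub, g, "atom")
        assert np.allclose(amap.deltas, g.node_features[:, 0])

    def test_one_delta_per_unit(self):
        g = build_dual_graph(standardize_structure("c1ccc2c(c1)OCO2"))
        assert len(occlude(lambda x: 0.0, g, "atom").deltas) == g.num_atoms
        assert len(occlude(lambda x: 0.0, g, "ring").deltas) == g.num_rings

    def test_ring_occlusion_masks_whole_ring(self):
        def stub(g):
            return float(g.node_features[~g.node_mask, 0].sum())

        g = build_dual_graph(standardize_structure("c1ccccc1CC"))
        amap = occlude(stub, g, "ring")
        ring_atoms = list(g.rings[0])
        assert np.isclose(amap.deltas[0], g.node_features[ring_atoms, 0].sum())


class TestPointBiserial:
    def test_hand_computed_value(self):
        r, p = point_biserial([10, 20, 80, 90], [0, 0, 1, 1])
        assert np.isclose(r, 0.9899, atol=1e-4)
        assert 0 <= p < 0.05

    def test_balanced_symmetric_labels_zero(self):
        r, _ = point_biserial([10, 90, 10, 90], [1, 1, 0, 0])
        assert np.isclose(r, 0.0)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            point_biserial([1.0, 2.0], [1, 1])

    def test_equals_pearson_on_indicator_100_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            y = rng.uniform(0, 100, n)
            pres = rng.integers(0, 2, n)
            if pres.min() == pres.max():
                pres[0] = 1 - pres[0]
            r, p = point_biserial(y, pres)
            ref = stats.pearsonr(y, pres.astype(float))
            assert np.isclose(r, ref.statistic, atol=1e-10)
            assert np.isclose(p, ref.pvalue, atol=1e-10)


class TestCohensD:
    def test_hand_computed_value(self):
        assert np.isclose(cohens_d([10, 20, 80, 90], [0, 0, 1, 1]), 9.899, atol=1e-3)

    def test_equal_means_zero(self):
        assert cohens_d([10, 20, 10, 20], [1, 1, 0, 0]) == 0.0

    def test_singleton_group_errors(self):
        with pytest.raises(ValueError):
            cohens_d([1, 2, 3], [1, 0, 0])


class TestMeanDifferenceCI:
    def test_difference_and_coverage(self):
        diff, ci = mean_difference_ci([10, 20, 80, 90], [0, 0, 1, 1], n_boot=500, seed=0)
        assert diff == 70.0
        assert ci[0] <= diff <= ci[1]

    def test_seed_determinism(self, rng):
        y = rng.uniform(0, 100, 40)
        p = rng.integers(0, 2, 40)
        a = mean_difference_ci(y, p, n_boot=300, seed=5)
        b = mean_difference_ci(y, p, n_boot=300, seed=5)
        assert a == b


class TestSpearman:
    def test_rank_invariances(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        names, rho = spearman_matrix({"a": x, "b": x**3, "c": x[::-1].copy()})
        assert np.allclose(np.diag(rho), 1.0)
        i, j, k = names.index("a"), names.index("b"), names.index("c")
        assert np.isclose(rho[i, j], 1.0)  # monotone transform preserves ranks
        assert np.isclose(rho[i, k], -1.0)

    def test_two_columns(self):
        _, rho = spearman_matrix({"y": np.array([1.0, 2, 3]), "d": np.array([9.0, 4, 1])})
        assert np.isclose(rho[0, 1], -1.0)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            spearman_matrix({"a": np.array([1.0, 2]), "b": np.array([2.0, 1])})


class TestSARReport:
    def test_signs_and_groups_on_tiny_benchmark(self, tiny_benchmark):
        cfg, truth = tiny_benchmark
        res = sar_report([m.canonical for m in truth.molecules], truth.labels, n_boot=200, seed=0)
        by_motif = {r.motif: r for r in res}
        # large planted effects must come out with the right sign
        for motif, beta in cfg.betas.items():
            if motif in by_motif and abs(beta) >= 5:
                r = by_motif[motif]
                assert np.sign(r.mean_diff) == np.sign(beta), motif
                assert np.sign(r.r_pb) == np.sign(r.mean_diff) == np.sign(r.cohens_d)
                assert r.n_with + r.n_without == len(truth.molecules)
                assert r.ci95[0] <= r.mean_diff <= r.ci95[1]

    def test_benzodioxole_ci_covers_planted_effect_in_most_repetitions(self):
        # marginal benzodioxole shift vs the planted +35, across 5 seeded sets
        from cypred.synthetic import GeneratorConfig, generate_molecules, plant_labels

        hits = 0
        for seed in range(5):
            cfg = GeneratorConfig(n_molecules=400, noise_sd=10.0, seed=100 + seed)
            truth = plant_labels(generate_molecules(cfg), cfg)
            res = sar_report([m.canonical for m in truth.molecules], truth.labels,
                             motifs=["benzodioxole"], n_boot=500, seed=seed)
            lo, hi = res[0].ci95
            hits += int(lo <= cfg.betas["benzodioxole"] <= hi)
        assert hits >= 4

    def test_bh_correction_only_raises_pvalues(self, tiny_benchmark):
        _, truth = tiny_benchmark
        smiles = [m.canonical for m in truth.molecules]
        plain = sar_report(smiles, truth.labels, n_boot=50, seed=0)
        adj = sar_report(smiles, truth.labels, n_boot=50, seed=0, bh_correct=True)
        for a, b in zip(plain, adj):
            assert b.p_value >= a.p_value - 1e-12
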