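import numpy as np
import pandas as pd
import pytest

from rarebiome import diversity as dv
from rarebiome import synthetic_data as sd


class TestSimulateTree:
    def test_two_tips_cherry(self):
        ph = sd.simulate_tree(2, seed=0)
        assert ph.n_tips == 2
        depths = [t.accumulate_to_ancestor(ph.tree) for t in ph.tree.tips()]
        assert depths[0] == pytest.approx(depths[1])

    def test_determinism(self):
        a = sd.simulate_tree(64, seed=42)
        b = sd.simulate_tree(64, seed=42)
        assert str(a.tree) == str(b.tree)

    def test_tip_labels(self):
        ph = sd.simulate_tree(10, seed=1)
        assert sorted(ph.tip_names) == sorted(f"OTU_{i+1}" for i in range(10))

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            sd.simulate_tree(1)

    @pytest.mark.slow
    def test_mean_depth_matches_yule_expectation(self):
        """E[root-to-tip depth] = sum_{k=2..n} 1/(lambda k)."""
        n, lam = 12, 1.3
        expected = sum(1 / (lam * k) for k in range(2, n + 1))
        depths = []
        for seed in range(500):
            ph = sd.simulate_tree(n, birth_rate=lam, seed=seed)
            tip = next(ph.tree.tips())
            depths.append(tip.accumulate_to_ancestor(ph.tree))
        se = np.std(depths) / np.sqrt(len(depths))
        assert np.mean(depths) == pytest.approx(expected, abs=4 * se + 0.01)


class TestBMTrait:
    def test_rate_zero_constant(self):
        ph = sd.simulate_tree(8, seed=0)
        trait = sd.simulate_trait_bm(ph, rate=0.0, seed=1)
        assert np.allclose(trait, trait.iloc[0])

    def test_negative_rate_rejected(self):
        ph = sd.simulate_tree(4, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_trait_bm(ph, rate=-1.0)

    def test_seed_reproducibility(self):
        ph = sd.simulate_tree(16, seed=3)
        a = sd.simulate_trait_bm(ph, rate=2.0, seed=4)
        b = sd.simulate_trait_bm(ph, rate=2.0, seed=4)
        pd.testing.assert_series_equal(a, b)

    def test_cherry_variance_closed_form(self):
        """Var(tipA - tipB) = 2 * rate * branch_length on a cherry."""
        from tests.conftest import tree_from_newick

        rate, bl = 1.7, 2.0
        ph = tree_from_newick(f"(A:{bl},B:{bl});")
        diffs = [np.diff(sd.simulate_trait_bm(ph, rate=rate, seed=s))[0]
                 for s in range(2000)]
        var = np.var(diffs)
        expected = 2 * rate * bl
        assert var == pytest.approx(expected, rel=0.15)


class TestBinaryTrait:
    def test_random_exact_prevalence(self):
        ph = sd.simulate_tree(64, seed=0)
        states = sd.simulate_binary_trait(ph, "random", 0.5, seed=1)
        assert states.sum() == 32

    def test_prevalence_bounds(self):
        ph = sd.simulate_tree(10, seed=0)
        with pytest.raises(ValueError):
            sd.simulate_binary_trait(ph, "random", 0.0)
        with pytest.raises(ValueError):
            sd.simulate_binary_trait(ph, "random", 0.01)

    def test_seed_reproducibility(self):
        ph = sd.simulate_tree(20, seed=2)
        a = sd.simulate_binary_trait(ph, "threshold_bm", 0.4, seed=3)
        b = sd.simulate_binary_trait(ph, "threshold_bm", 0.4, seed=3)
        pd.testing.assert_series_equal(a, b)

    @pytest.mark.slow
    def test_threshold_bm_clumped_by_parsimony(self):
        """Fitch parsimony change counts: threshold-BM < random shuffle."""

        def fitch_changes(ph, states):
            changes = 0
            sets = {}
            for node in ph.tree.postorder(include_self=True):
                if not node.children:
                    sets[id(node)] = {states[node.name]}
                    continue
                inter = set.intersection(*(sets[id(c)] for c in node.children))
                if inter:
                    sets[id(node)] = inter
                else:
                    sets[id(node)] = set.union(
                        *(sets[id(c)] for c in node.children))
                    changes += len(node.children) - 1
            return changes

        diffs = []
        for seed in range(200):
            ph = sd.simulate_tree(32, seed=seed)
            clumped = sd.simulate_binary_trait(ph, "threshold_bm", 0.5,
                                               seed=seed)
            random = sd.simulate_binary_trait(ph, "random", 0.5, seed=seed)
            diffs.append(fitch_changes(ph, random) - fitch_changes(ph, clumped))
        assert np.mean(diffs) > 0


class TestGradientMetacommunity:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            sd.SimulationConfig(regime="bogus")
        with pytest.raises(ValueError):
            sd.SimulationConfig(n_samples=1)
        with pytest.raises(ValueError):
            sd.SimulationConfig(gradient_min=5, gradient_max=1)

    def test_shapes_and_truth(self):
        cfg = sd.SimulationConfig(n_samples=12, n_otus=30, depth=1000, seed=0)
        ds = sd.simulate_gradient_metacommunity(cfg)
        assert ds.community.counts.shape == (12, 30)
        assert ds.tree.n_tips == 30
        assert len(ds.truth) == 30
        assert set(ds.env.env.columns) >= {"EC", "pH"}
        assert (ds.community.counts.sum(axis=1) == 1000).all()

    def test_determinism(self):
        cfg = sd.SimulationConfig(n_samples=8, n_otus=20, depth=500, seed=9)
        a = sd.simulate_gradient_metacommunity(cfg)
        b = sd.simulate_gradient_metacommunity(cfg)
        pd.testing.assert_frame_equal(a.community.counts, b.community.counts)

    def test_neutral_high_depth_converges(self):
        """Neutral regime at large depth: samples share one SAD, so mean
        Bray-Curtis shrinks with depth."""
        bc = {}
        for depth in (500, 50_000):
            cfg = sd.SimulationConfig(n_samples=10, n_otus=50,
                                      regime="neutral", depth=depth, seed=4)
            ds = sd.simulate_gradient_metacommunity(cfg)
            m = dv.bray_curtis_matrix(ds.community.counts.to_numpy())
            bc[depth] = m[np.triu_indices(10, 1)].mean()
        assert bc[50_000] < bc[500] / 3

    def test_huge_niche_breadth_approaches_neutral(self):
        cfg_sel = sd.SimulationConfig(n_samples=10, n_otus=50,
                                      regime="selection", niche_breadth=1e6,
                                      depth=20_000, seed=5)
        cfg_neu = sd.SimulationConfig(n_samples=10, n_otus=50,
                                      regime="neutral", depth=20_000, seed=5)
        a = sd.simulate_gradient_metacommunity(cfg_sel)
        b = sd.simulate_gradient_metacommunity(cfg_neu)
        bc_a = dv.bray_curtis_matrix(a.community.counts.to_numpy())
        bc_b = dv.bray_curtis_matrix(b.community.counts.to_numpy())
        assert abs(bc_a.mean() - bc_b.mean()) < 0.05

    @pytest.mark.slow
    def test_selection_distance_decay_in_expectation(self):
        """Bray-Curtis grows with gradient separation under selection."""
        from scipy.stats import spearmanr

        rhos = []
        for seed in range(50):
            cfg = sd.SimulationConfig(n_samples=8, n_otus=60,
                                      regime="selection", niche_breadth=2.0,
                                      depth=3000, seed=seed)
            ds = sd.simulate_gradient_metacommunity(cfg)
            bc = dv.bray_curtis_matrix(ds.community.counts.to_numpy())
            e = ds.env.env["EC"].to_numpy()
            de = np.abs(e[:, None] - e[None, :])
            iu = np.triu_indices(8, 1)
            rhos.append(spearmanr(de[iu], bc[iu]).statistic)
        assert np.mean(rhos) > 0.5


class TestFunctionData:
    def test_universal_function_tracks_abundance(self):
        cfg = sd.SimulationConfig(n_samples=8, n_otus=20, depth=1000, seed=0)
        ds = sd.simulate_gradient_metacommunity(cfg)
        inc, meas = sd.simulate_function_data(ds, n_functions=1,
                                              sharing="random", noise_sd=0.0,
                                              seed=1)
        inc.iloc[:, 0] = True
        _, meas = sd.simulate_function_data(ds, n_functions=1,
                                            sharing="random", noise_sd=0.0,
                                            seed=1)
        # all-carrier function: measurement = total relative abundance = 1
        rel = ds.community.rel_abund.to_numpy()
        expected = rel @ np.ones(20)
        inc_all = pd.DataFrame(True, index=inc.index, columns=inc.columns)
        manual = rel @ inc_all.to_numpy(dtype=float)
        assert np.allclose(manual[:, 0], expected)

    def test_single_clade_function(self):
        cfg = sd.SimulationConfig(n_samples=10, n_otus=30, depth=2000, seed=2)
        ds = sd.simulate_gradient_metacommunity(cfg)
        inc, meas = sd.simulate_function_data(ds, n_functions=5,
                                              sharing="clade", noise_sd=0.01,
                                              seed=3)
        assert inc.shape == (30, 5)
        assert meas.shape == (10, 5)
        assert inc.any(axis=0).all()  # every function has a carrier

    @pytest.mark.slow
    def test_clade_gain_is_phylogenetically_clustered(self):
        """Carriers of clade-gained functions are closer on the tree than a
        label-shuffled control."""
        rng = np.random.default_rng(0)
        clade_minus_shuffled = []
        for seed in range(15):
            cfg = sd.SimulationConfig(n_samples=6, n_otus=40, depth=500,
                                      seed=seed)
            ds = sd.simulate_gradient_metacommunity(cfg)
            dm = dv.cophenetic_matrix(ds.tree)
            inc, _ = sd.simulate_function_data(ds, n_functions=8,
                                               sharing="clade", seed=seed)
            for f in inc.columns:
                carriers = list(inc.index[inc[f]])
                if not 3 <= len(carriers) <= 35:
                    continue
                idx = dm.positions(carriers)
                sub = dm.data[np.ix_(idx, idx)]
                obs = sub[np.triu_indices(len(idx), 1)].mean()
                shuf = []
                for _ in range(20):
                    ridx = rng.choice(dm.n, size=len(idx), replace=False)
                    s = dm.data[np.ix_(ridx, ridx)]
                    shuf.append(s[np.triu_indices(len(idx), 1)].mean())
                clade_minus_shuffled.append(np.mean(shuf) - obs)
        assert np.mean(clade_minus_shuffled) > 0

    def test_invalid_inputs(self):
        cfg = sd.SimulationConfig(n_samples=6, n_otus=10, depth=200, seed=1)
        ds = sd.simulate_gradient_metacommunity(cfg)
        with pytest.raises(ValueError):
            sd.simulate_function_data(ds, n_functions=0)
        with pytest.raises(ValueError):
            sd.simulate_function_data(ds, n_functions=2, sharing="bogus")
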