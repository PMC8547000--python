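import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rarebiome import assembly as asm
from rarebiome import diversity as dv


class TestBetaNTI:
    def test_identical_communities_undefined(self, balanced_dmat):
        ab = pd.Series({"A": 0.5, "C": 0.5})
        res = asm.beta_nti(ab, ab, balanced_dmat, n_nulls=50, seed=0)
        assert not res["defined"]

    def test_singleton_pair_matches_enumeration(self, balanced_dmat):
        """{A} vs {C}: the null relabels the 2-taxon pool with any 2 of the
        4 tips, so null betaMNTD = d(tip1, tip2) over all unordered pairs."""
        d = balanced_dmat.data
        vals = [d[i, j] for i, j in itertools.combinations(range(4), 2)]
        mu, sd = np.mean(vals), np.std(vals)
        expected = (d[balanced_dmat.index["A"], balanced_dmat.index["C"]] - mu) / sd
        res = asm.beta_nti(pd.Series({"A": 1.0}), pd.Series({"C": 1.0}),
                           balanced_dmat, n_nulls=9999, seed=1)
        assert res["beta_mntd"] == pytest.approx(4.0)
        assert res["beta_nti"] == pytest.approx(expected, abs=0.15)

    def test_seed_reproducibility(self, balanced_dmat):
        k = pd.Series({"A": 0.6, "B": 0.4})
        l = pd.Series({"C": 1.0})
        a = asm.beta_nti(k, l, balanced_dmat, n_nulls=99, seed=3)
        b = asm.beta_nti(k, l, balanced_dmat, n_nulls=99, seed=3)
        assert a["beta_nti"] == b["beta_nti"]

    def test_pair_symmetry(self, balanced_dmat):
        k = pd.Series({"A": 0.6, "B": 0.4})
        l = pd.Series({"C": 0.3, "D": 0.7})
        a = asm.beta_nti(k, l, balanced_dmat, n_nulls=199, seed=4)
        b = asm.beta_nti(l, k, balanced_dmat, n_nulls=199, seed=4)
        assert a["beta_mntd"] == pytest.approx(b["beta_mntd"])
        # null distribution is exchangeable; estimates agree statistically
        assert a["beta_nti"] == pytest.approx(b["beta_nti"], abs=0.5)

    def test_matrix_agrees_with_pairwise_construction(self):
        """beta_nti_matrix and the per-pair routine share the same null
        distribution; check convergence on a small instance."""
        from rarebiome.synthetic_data import SimulationConfig, simulate_gradient_metacommunity

        ds = simulate_gradient_metacommunity(
            SimulationConfig(n_samples=4, n_otus=24, depth=300, seed=8))
        dm = dv.cophenetic_matrix(ds.tree)
        rel = ds.community.rel_abund
        tp = dm.positions(ds.community.otu_ids)
        _, nti = asm.beta_nti_matrix(rel.to_numpy(), dm.data, tp,
                                     n_nulls=4999, seed=0)
        pair = asm.beta_nti(rel.iloc[0], rel.iloc[2], dm, n_nulls=4999, seed=1)
        assert nti[0, 2] == pytest.approx(pair["beta_nti"], abs=0.35)


def _enumerate_null_communities(occ_w, abund_w, richness, n_reads):
    """Exact distribution of the two-step null assembly for tiny inputs."""
    n = len(occ_w)
    outcomes = {}
    for order in itertools.permutations(range(n), richness):
        p = 1.0
        remaining = list(range(n))
        weights = list(occ_w)
        for pick in order:
            total = sum(weights[i] for i in remaining)
            p *= weights[pick] / total
            remaining.remove(pick)
        subset = tuple(sorted(order))
        outcomes[subset] = outcomes.get(subset, 0.0) + p
    dist = {}
    for subset, p_subset in outcomes.items():
        w = np.array([abund_w[i] for i in subset], dtype=float)
        w = w / w.sum()
        extra = n_reads - richness
        for alloc in itertools.product(range(extra + 1), repeat=len(subset)):
            if sum(alloc) != extra:
                continue
            p_alloc = math.factorial(extra)
            for a, wi in zip(alloc, w):
                p_alloc = p_alloc * wi ** a / math.factorial(a)
            counts = np.zeros(n)
            for i, otu in enumerate(subset):
                counts[otu] = 1 + alloc[i]
            key = tuple(counts)
            dist[key] = dist.get(key, 0.0) + p_subset * p_alloc
    return dist


class TestRaupCrick:
    def test_extreme_ranks(self):
        # obs BC = 0 vs nulls rebuilt from a 2-OTU metacommunity: nulls
        # almost surely differ -> RC near -1
        ck = np.array([5, 5, 0])
        occ = np.array([1.0, 1.0, 1.0])
        ab = np.array([0.3, 0.3, 0.4])
        rc = asm.raup_crick_bray(ck, ck, occ, ab, n_nulls=499, seed=0)
        assert rc < -0.9

    def test_matches_full_enumeration(self):
        """3-OTU toy metacommunity: exact RC via enumeration of the null."""
        ck = np.array([2, 1, 0])
        cl = np.array([0, 1, 2])
        counts = np.stack([ck, cl])
        occ = (counts > 0).sum(axis=0).astype(float)
        ab = counts.sum(axis=0) / counts.sum()
        obs = np.abs(ck - cl).sum() / (ck.sum() + cl.sum())
        dist_k = _enumerate_null_communities(occ, ab, 2, 3)
        assert sum(dist_k.values()) == pytest.approx(1.0)
        below = ties = 0.0
        for a, pa in dist_k.items():
            for b, pb in dist_k.items():
                a_, b_ = np.array(a), np.array(b)
                bc = np.abs(a_ - b_).sum() / (a_.sum() + b_.sum())
                if bc < obs - 1e-12:
                    below += pa * pb
                elif abs(bc - obs) <= 1e-12:
                    ties += pa * pb
        exact_rc = 2 * ((below + 0.5 * ties) - 0.5)
        mc = asm.raup_crick_bray(ck, cl, occ, ab, n_nulls=9999, seed=5)
        assert mc == pytest.approx(exact_rc, abs=0.05)

    def test_richness_exceeding_metacommunity(self):
        with pytest.raises(Exception):
            asm.raup_crick_bray(np.array([1, 1]), np.array([1, 0]),
                                np.array([1.0, 0.0]), np.array([0.5, 0.5]),
                                n_nulls=9)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, (4, 10))
        counts[counts < 5] = 0
        counts += 1  # ensure non-degenerate
        occ = (counts > 0).sum(axis=0).astype(float)
        ab = counts.sum(axis=0) / counts.sum()
        mat = asm.raup_crick_bray_matrix(counts, n_nulls=2999, seed=0)
        pair = asm.raup_crick_bray(counts[0], counts[3], occ, ab,
                                   n_nulls=2999, seed=1)
        assert mat[0, 3] == pytest.approx(pair, abs=0.1)
        assert np.all(np.abs(mat) <= 1)


class TestClassifyPair:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (2.5, 0.3, "variable_selection"),
        (-2.5, 0.99, "homogeneous_selection"),
        (1.0, 0.99, "dispersal_limitation"),
        (1.0, -0.99, "homogenizing_dispersal"),
        (0.0, 0.0, "undominated"),
        (2.0, 0.0, "undominated"),          # |bNTI| = 2 inclusive boundary
        (-2.0, -0.99, "homogenizing_dispersal"),
        (0.0, 0.95, "undominated"),          # |RC| = 0.95 inclusive boundary
        (0.0, -0.95, "undominated"),
    ])
    def test_rules(self, bnti, rc, expected):
        assert asm.classify_pair(bnti, rc) == expected

    def test_undefined_propagates(self):
        assert asm.classify_pair(np.nan, 0.5) == "undefined"


class TestProcessFractions:
    def test_all_variable_selection(self):
        fr = asm.process_fractions(["variable_selection"] * 10)
        assert fr.deterministic == pytest.approx(1.0)
        assert fr.stochastic == pytest.approx(0.0)

    def test_one_of_each(self):
        fr = asm.process_fractions(list(asm.PROCESSES))
        for p in asm.PROCESSES:
            assert getattr(fr, p) == pytest.approx(0.2)
        assert fr.stochastic == pytest.approx(0.6)
        assert fr.homogenizing == pytest.approx(0.4)
        assert fr.differentiating == pytest.approx(0.4)

    def test_aggregate_identities_random(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(asm.PROCESSES, 200)
        fr = asm.process_fractions(labels)
        total = sum(getattr(fr, p) for p in asm.PROCESSES)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert fr.deterministic + fr.stochastic == pytest.approx(1.0)
        assert fr.homogenizing == pytest.approx(
            fr.homogeneous_selection + fr.homogenizing_dispersal)
        assert fr.differentiating == pytest.approx(
            fr.variable_selection + fr.dispersal_limitation)

    def test_undefined_excluded(self):
        fr = asm.process_fractions(["undominated", "undefined", "undefined"])
        assert fr.n_pairs == 1
        assert fr.n_undefined == 2

    def test_empty_rejected(self):
        with pytest.raises(Exception):
            asm.process_fractions(["undefined"])


class TestEnvMantel:
    def _bnti_frame(self, v):
        v = np.asarray(v, dtype=float)
        d = np.abs(v[:, None] - v[None, :])
        ids = [f"S{i}" for i in range(len(v))]
        return pd.DataFrame(d, index=ids, columns=ids)

    def test_proportional_gives_r_one(self):
        e = pd.Series([1.0, 3.0, 7.0, 12.0, 20.0],
                      index=[f"S{i}" for i in range(5)])
        b = self._bnti_frame(e.to_numpy())
        res = asm.env_mantel(b, e, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_env_flagged(self):
        b = self._bnti_frame([1, 2, 3, 4])
        e = pd.Series(5.0, index=b.index)
        res = asm.env_mantel(b, e)
        assert not res.defined

    def test_matches_enumeration(self):
        rng = np.random.default_rng(2)
        b = self._bnti_frame(rng.normal(size=5))
        e = pd.Series(rng.normal(size=5), index=b.index)
        res = asm.env_mantel(b, e, n_perm=9999, seed=1)
        # independent exhaustive Mantel
        ev = np.abs(e.to_numpy()[:, None] - e.to_numpy()[None, :])
        iu = np.triu_indices(5, 1)
        r_obs = np.corrcoef(b.to_numpy()[iu], ev[iu])[0, 1]
        count, total = 0, 0
        for perm in itertools.permutations(range(5)):
            ep = ev[np.ix_(perm, perm)]
            if np.corrcoef(b.to_numpy()[iu], ep[iu])[0, 1] >= r_obs - 1e-12:
                count += 1
            total += 1
        assert res.p == pytest.approx(count / total, abs=0.02)


class TestSalinityBins:
    def _pair_table(self, bnti_by_bin, samples_per_bin=10, seed=0):
        rng = np.random.default_rng(seed)
        ids, ec, rows = [], [], []
        for b, mu in enumerate(bnti_by_bin):
            for i in range(samples_per_bin):
                ids.append(f"B{b}_{i}")
                ec.append(b * 10 + rng.uniform(0, 5))
        ec = pd.Series(ec, index=ids)
        for b, mu in enumerate(bnti_by_bin):
            members = [s for s in ids if s.startswith(f"B{b}_")]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    rows.append({"sample_i": members[i],
                                 "sample_j": members[j],
                                 "beta_nti": rng.normal(mu, 1.0)})
        return pd.DataFrame(rows), ec

    def test_constant_ec_rejected(self):
        table, ec = self._pair_table([0, 0])
        with pytest.raises(Exception):
            asm.salinity_bin_analysis(table, pd.Series(1.0, index=ec.index),
                                      n_bins=4)

    def test_shifted_bins_detected(self):
        table, ec = self._pair_table([0.0, 2.0], samples_per_bin=20, seed=1)
        res = asm.salinity_bin_analysis(table, ec, n_bins=2)
        assert res["kruskal_wallis"].p < 0.05
        (pair_p,) = res["pairwise_wilcoxon"].values()
        assert pair_p < 0.05

    def test_order_invariance(self):
        table, ec = self._pair_table([0.0, 1.0, 2.0, 3.0], seed=2)
        res1 = asm.salinity_bin_analysis(table, ec, n_bins=4)
        shuffled = ec.sample(frac=1, random_state=3)
        res2 = asm.salinity_bin_analysis(table, shuffled, n_bins=4)
        pd.testing.assert_frame_equal(res1["bins"], res2["bins"])
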