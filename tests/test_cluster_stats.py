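"""Wilcoxon z maps, cluster formation, and the permutation engine.

Independent oracles: closed-form signed-rank moments, scipy's asymptotic
Wilcoxon/Mann-Whitney p-values, exhaustive sign-flip enumeration, and the
package's own exact-enumeration mode cross-checked against Monte Carlo.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from qeegperm.cluster_stats import (
    Cluster,
    ClusterTestResult,
    PointStatMap,
    form_clusters,
    permutation_test,
    pointwise_wilcoxon,
    significance_bars,
)
from qeegperm.montage import MontageGraph


@pytest.fixture(scope="module")
def montage():
    return MontageGraph.standard_1020()


class TestPointwiseWilcoxon:
    def test_all_positive_differences_closed_form(self):
        # n = 8, W at maximum 36: z = (36 - 18) / sqrt(8*9*17/24) = 2.521
        a = (np.arange(1, 9, dtype=float) + 10.0).reshape(8, 1, 1)
        b = np.full((8, 1, 1), 10.0)
        m = pointwise_wilcoxon(a, b, paired=True)
        assert m.z[0, 0] == pytest.approx(2.521, abs=1e-3)

    def test_identical_groups_degenerate(self):
        a = np.tile(np.arange(6.0).reshape(6, 1, 1), (1, 2, 3))
        m = pointwise_wilcoxon(a, a.copy(), paired=True)
        assert np.all(m.p == 1.0)
        assert np.all(m.z == 0.0)
        assert np.all(m.degenerate)

    def test_sign_convention(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 1, 1))
        m = pointwise_wilcoxon(base + 5.0, base, paired=True)
        assert m.z[0, 0] > 0
        m2 = pointwise_wilcoxon(base, base + 5.0, paired=False)
        assert m2.z[0, 0] < 0

    def test_matches_scipy_signed_rank(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(12, 3, 5))
        b = rng.normal(size=(12, 3, 5))
        m = pointwise_wilcoxon(a, b, paired=True)
        for i in range(3):
            for j in range(5):
                ref = stats.wilcoxon(a[:, i, j], b[:, i, j], zero_method="wilcox",
                                     correction=True, method="approx")
                assert m.p[i, j] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_scipy_rank_sum_with_ties(self):
        rng = np.random.default_rng(2)
        a = np.round(rng.normal(size=(9, 2, 4)), 1)     # rounding forces ties
        b = np.round(rng.normal(size=(14, 2, 4)), 1)
        m = pointwise_wilcoxon(a, b, paired=False)
        for i in range(2):
            for j in range(4):
                ref = stats.mannwhitneyu(a[:, i, j], b[:, i, j],
                                         method="asymptotic", use_continuity=True)
                assert m.p[i, j] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_enumeration(self):
        # n <= 9: exhaustive sign-flip null of W+ vs the normal approximation
        rng = np.random.default_rng(3)
        for n in (6, 8, 9):
            d = rng.normal(0.5, 1.0, size=n)
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            mu = n * (n + 1) / 4
            null = [r_sub for bits in itertools.product([0, 1], repeat=n)
                    for r_sub in [np.dot(ranks, bits)]]
            exact_p = np.mean(np.abs(np.array(null) - mu) >= abs(w_obs - mu) - 1e-12)
            m = pointwise_wilcoxon(d.reshape(n, 1, 1), np.zeros((n, 1, 1)), paired=True)
            assert m.p[0, 0] == pytest.approx(exact_p, abs=0.05)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            pointwise_wilcoxon(np.zeros((1, 2, 2)), np.zeros((1, 2, 2)), paired=True)


class TestFormClusters:
    def _map(self, z, p):
        return PointStatMap(z=z, p=p, test_type="rank_sum_independent",
                            degenerate=np.zeros_like(z, dtype=bool))

    def test_single_point(self, montage):
        z = np.zeros((19, 10)); p = np.ones((19, 10))
        z[5, 3] = 3.0; p[5, 3] = 0.002
        cl = form_clusters(self._map(z, p), montage)
        assert len(cl) == 1 and cl[0].points == [(5, 3)]
        assert cl[0].mass == pytest.approx(3.0)

    def test_nonadjacent_channels_stay_separate(self, montage):
        f7, o2 = montage.index("F7"), montage.index("O2")
        assert not montage.adjacency[f7, o2]
        z = np.zeros((19, 10)); p = np.ones((19, 10))
        for ch in (f7, o2):
            z[ch, 4] = 2.5; p[ch, 4] = 0.01
        cl = form_clusters(self._map(z, p), montage)
        assert len(cl) == 2

    def test_adjacent_channels_merge(self, montage):
        cz, pz = montage.index("Cz"), montage.index("Pz")
        assert montage.adjacency[cz, pz]
        z = np.zeros((19, 10)); p = np.ones((19, 10))
        for ch in (cz, pz):
            z[ch, 4] = 2.5; p[ch, 4] = 0.01
        assert len(form_clusters(self._map(z, p), montage)) == 1

    def test_run_mass_additivity(self, montage):
        z = np.zeros((19, 10)); p = np.ones((19, 10))
        z[2, 3:6] = [2.0, 2.5, 3.0]; p[2, 3:6] = 0.01
        cl = form_clusters(self._map(z, p), montage)
        assert len(cl) == 1
        assert cl[0].mass == pytest.approx(7.5)

    def test_opposite_signs_split(self, montage):
        z = np.zeros((19, 10)); p = np.ones((19, 10))
        z[2, 3:5] = [2.5, -2.5]; p[2, 3:5] = 0.01
        cl = form_clusters(self._map(z, p), montage)
        assert sorted(c.sign for c in cl) == [-1, 1]

    def test_invalid_threshold(self, montage):
        z = np.zeros((19, 4)); p = np.ones((19, 4))
        with pytest.raises(ValueError):
            form_clusters(self._map(z, p), montage, p_threshold=1.5)


class TestPermutationTest:
    def test_exact_matches_monte_carlo_paired(self, montage):
        rng = np.random.default_rng(5)
        a = rng.normal(0.9, 1.0, size=(5, 19, 6))
        b = rng.normal(0.0, 1.0, size=(5, 19, 6))
        ex = permutation_test(a, b, montage, design="paired", exact=True)
        n_perm = 10000
        mc = permutation_test(a, b, montage, design="paired", n_perm=n_perm, seed=3)
        tol = 2 / np.sqrt(n_perm)
        for ce, cm in zip(ex.clusters, mc.clusters):
            assert cm.perm_p == pytest.approx(ce.perm_p, abs=tol)

    def test_exact_matches_monte_carlo_independent(self, montage):
        rng = np.random.default_rng(6)
        a = rng.normal(0.7, 1.0, size=(4, 19, 6))
        b = rng.normal(0.0, 1.0, size=(6, 19, 6))
        ex = permutation_test(a, b, montage, design="independent", exact=True)
        mc = permutation_test(a, b, montage, design="independent", n_perm=10000, seed=4)
        tol = 2 / np.sqrt(10000)
        for ce, cm in zip(ex.clusters, mc.clusters):
            assert cm.perm_p == pytest.approx(ce.perm_p, abs=tol)

    def test_seed_reproducibility(self, montage):
        rng = np.random.default_rng(7)
        a = rng.normal(0.5, 1, size=(8, 19, 8))
        b = rng.normal(0.0, 1, size=(9, 19, 8))
        r1 = permutation_test(a, b, montage, n_perm=300, seed=11)
        r2 = permutation_test(a, b, montage, n_perm=300, seed=11)
        assert np.array_equal(r1.null_max_mass, r2.null_max_mass)
        assert [c.perm_p for c in r1.clusters] == [c.perm_p for c in r2.clusters]

    def test_relabeling_invariance_of_exact_null(self, montage):
        rng = np.random.default_rng(8)
        a = rng.normal(0.5, 1, size=(4, 19, 5))
        b = rng.normal(0.0, 1, size=(4, 19, 5))
        base = permutation_test(a, b, montage, design="independent", exact=True)
        perm = rng.permutation(4)
        shuf = permutation_test(a[perm], b[perm], montage, design="independent", exact=True)
        assert np.allclose(np.sort(base.null_max_mass), np.sort(shuf.null_max_mass))
        assert sorted(round(c.mass, 9) for c in base.clusters) == \
            sorted(round(c.mass, 9) for c in shuf.clusters)

    def test_perm_p_monotone_in_effect_size(self, montage):
        rng = np.random.default_rng(9)
        noise_a = rng.normal(size=(8, 19, 12))
        noise_b = rng.normal(size=(10, 19, 12))
        pattern = np.zeros((19, 12))
        pattern[montage.index("F7"), 4:8] = 1.0
        pattern[montage.index("T3"), 4:8] = 1.0
        ps = []
        for scale in (0.4, 0.9, 1.8):
            a = noise_a + scale * pattern[None]
            res = permutation_test(a, noise_b, montage, n_perm=500, seed=21)
            ps.append(min((c.perm_p for c in res.clusters), default=1.0))
        assert ps[0] >= ps[1] >= ps[2]

    def test_perm_p_never_zero(self, montage):
        rng = np.random.default_rng(10)
        a = rng.normal(5.0, 0.5, size=(8, 19, 6))
        b = rng.normal(0.0, 0.5, size=(8, 19, 6))
        res = permutation_test(a, b, montage, n_perm=200, seed=1)
        assert all(c.perm_p > 0 for c in res.clusters)

    def test_small_n_perm_rejected(self, montage):
        a = np.zeros((4, 19, 3)); b = np.zeros((4, 19, 3))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(a, b, montage, n_perm=10)

    def test_result_serializes(self, montage, tmp_path):
        rng = np.random.default_rng(11)
        a = rng.normal(1.0, 1, size=(6, 19, 5))
        b = rng.normal(0.0, 1, size=(6, 19, 5))
        res = permutation_test(a, b, montage, n_perm=100, seed=0,
                               channel_labels=montage.channels)
        res.save_json(tmp_path / "r.json")
        import json
        d = json.loads((tmp_path / "r.json").read_text())
        assert d["n_permutations"] == 100
        assert all("mass" in c and "perm_p" in c for c in d["clusters"])


class TestSignificanceBars:
    def _result(self, clusters):
        z = np.zeros((19, 20)); p = np.ones((19, 20))
        sm = PointStatMap(z=z, p=p, test_type="rank_sum_independent",
                          degenerate=np.zeros_like(z, dtype=bool))
        return ClusterTestResult(clusters=clusters, stat_map=sm,
                                 null_max_mass=np.zeros(100), n_permutations=100,
                                 p_threshold=0.05, design="independent",
                                 seed=0, exact=False)

    def test_no_clusters_no_bars(self):
        bars = significance_bars(self._result([]), 0)
        assert bars[0.05] == [] and bars[0.01] == []

    def test_strong_cluster_both_levels(self):
        c = Cluster(points=[(2, 4), (2, 5), (2, 6)], mass=9.0, sign=1, perm_p=0.003)
        bars = significance_bars(self._result([c]), 2)
        assert bars[0.05] == [(4, 6)] and bars[0.01] == [(4, 6)]

    def test_weak_cluster_one_level(self):
        c = Cluster(points=[(2, 4), (2, 5)], mass=5.0, sign=1, perm_p=0.03)
        bars = significance_bars(self._result([c]), 2)
        assert bars[0.05] == [(4, 5)] and bars[0.01] == []

    def test_other_channels_unaffected(self):
        c = Cluster(points=[(2, 4)], mass=3.0, sign=1, perm_p=0.001)
        bars = significance_bars(self._result([c]), 5)
        assert bars[0.05] == []
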