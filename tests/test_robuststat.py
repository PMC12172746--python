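"""Trimmed-mean tests, clustering, bootstrap correction, hierarchical model."""

import numpy as np
import pytest
from scipy import stats

from tapflow import robuststat as rs
from tapflow.montage import Montage


@pytest.fixture(scope="module")
def adj16():
    m = Montage(16)
    return rs.build_adjacency(m.positions, names=m.names)


def _yuen_oracle(x, trim=0.2, mu0=0.0):
    """Independent scalar implementation of the Tukey-McLaughlin test."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    g = int(np.floor(trim * n))
    tm = x[g : n - g].mean()
    w = x.copy()
    w[:g] = x[g]
    w[n - g :] = x[n - g - 1]
    sw2 = w.var(ddof=1)
    se = np.sqrt(sw2) / ((1 - 2 * g / n) * np.sqrt(n))
    T = (tm - mu0) / se
    df = n - 2 * g - 1
    return T, df, 2 * stats.t.sf(abs(T), df)


class TestTrimmedMean:
    def test_constant_vector(self):
        assert rs.trimmed_mean(np.full(9, 4.2)) == pytest.approx(4.2)

    def test_one_to_ten_hand_computed(self):
        assert rs.trimmed_mean(np.arange(1.0, 11.0), 0.2) == pytest.approx(5.5)

    def test_zero_trim_is_arithmetic_mean(self, rng):
        x = rng.standard_normal(17)
        assert rs.trimmed_mean(x, 0.0) == pytest.approx(x.mean())

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            rs.trimmed_mean(np.arange(4.0), 0.25)


class TestYuen:
    def test_symmetric_data_gives_zero_statistic(self):
        x = np.array([-3.0, -2, -1, 0, 1, 2, 3])
        T, _, _ = rs.yuen_one_sample(x)
        assert T == pytest.approx(0.0, abs=1e-12)

    def test_trim_zero_equals_classical_t(self, rng):
        for _ in range(10):
            x = rng.standard_normal(rng.integers(6, 40)) + 0.3
            T, df, p = rs.yuen_one_sample(x, trim=0.0)
            ref = stats.ttest_1samp(x, 0.0)
            assert abs(T - ref.statistic) < 1e-10
            assert abs(p - ref.pvalue) < 1e-10
            assert df == x.size - 1

    def test_matches_independent_oracle(self, rng):
        x = rng.standard_normal(20) + 0.5
        T, df, p = rs.yuen_one_sample(x, trim=0.2)
        To, dfo, po = _yuen_oracle(x, 0.2)
        assert abs(T - To) < 1e-10 and df == dfo and abs(p - po) < 1e-10

    def test_paired_is_one_sample_on_differences(self, rng):
        a = rng.standard_normal(15)
        b = rng.standard_normal(15)
        Tp, dfp, pp = rs.yuen_paired(a, b)
        To, dfo, po = rs.yuen_one_sample(a - b)
        assert Tp == pytest.approx(To) and pp == pytest.approx(po)
        Ts, _, _ = rs.yuen_paired(b, a)
        assert Ts == pytest.approx(-Tp)

    def test_identical_pairs_zero(self, rng):
        a = rng.standard_normal(12)
        with pytest.raises(ValueError):
            rs.yuen_paired(a, a.copy())  # zero variance is undefined

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rs.yuen_one_sample(np.arange(4.0))

    def test_mask_mode_degenerate_cells(self):
        x = np.stack([np.full(12, 2.0), np.zeros(12),
                      np.arange(12.0)], axis=1)
        T, df, p = rs.yuen_one_sample(x, errors="mask")
        assert T[0] > 1e5 and p[0] == 0.0    # constant nonzero
        assert T[1] == 0.0 and p[1] == 1.0   # constant at mu0
        assert np.isfinite(T[2]) and 0 < p[2] < 1


class TestAdjacency:
    def test_radius_below_spacing_isolates_everything(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        adj = rs.build_adjacency(pos, radius=0.5)
        assert not adj.matrix.any()
        assert len(adj.isolated) == 3

    def test_radius_above_extent_is_complete(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        adj = rs.build_adjacency(pos, radius=5.0)
        assert adj.matrix.sum() == 6

    def test_collinear_chain(self):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        adj = rs.build_adjacency(pos, radius=1.0)
        assert adj.matrix[0, 1] and adj.matrix[1, 2] and not adj.matrix[0, 2]

    def test_default_radius_connects_montage(self, adj16):
        assert not adj16.isolated
        assert np.array_equal(adj16.matrix, adj16.matrix.T)


def _bfs_components(active, neighbor_pairs):
    """Pure-python connected components over active cells (oracle)."""
    cells = list(zip(*np.nonzero(active)))
    cellset = set(cells)
    pair_set = set()
    for i, j in neighbor_pairs:
        pair_set.add((i, j))
        pair_set.add((j, i))
    seen, comps = set(), []
    for start in cells:
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            c, *grid = cur
            for ax in range(len(grid)):
                for d in (-1, 1):
                    nxt = list(grid)
                    nxt[ax] += d
                    cand = (c, *nxt)
                    if cand in cellset and cand not in seen:
                        seen.add(cand)
                        stack.append(cand)
            for c2 in range(active.shape[0]):
                if (c, c2) in pair_set:
                    cand = (c2, *grid)
                    if cand in cellset and cand not in seen:
                        seen.add(cand)
                        stack.append(cand)
        comps.append(frozenset(comp))
    return set(comps)


class TestClustering:
    def test_empty_map_yields_no_clusters(self, adj16):
        clusters, labels = rs.find_clusters(np.zeros((16, 30)),
                                            np.ones((16, 30)), 0.05, adj16)
        assert clusters == [] and not labels.any()

    def test_island_mass_equals_brute_sum(self, adj16):
        stat = np.zeros((16, 60))
        p = np.ones((16, 60))
        chans = [i for i, ch in enumerate(adj16.names)
                 if adj16.matrix[i].any()][:3]
        # make sure chosen channels form a connected set
        chans = [chans[0]] + [j for j in np.flatnonzero(adj16.matrix[chans[0]])[:2]]
        for c in chans:
            stat[c, 5:55] = 3.0
            p[c, 5:55] = 0.01
        clusters, labels = rs.find_clusters(stat, p, 0.05, adj16)
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(3.0 * len(chans) * 50)

    def test_non_neighboring_islands_stay_separate(self):
        pos = np.array([[0.0, 0, 0], [0.001, 0, 0], [1.0, 0, 0]])
        adj = rs.build_adjacency(pos, radius=0.01, names=["a", "b", "c"])
        stat = np.zeros((3, 20))
        p = np.ones((3, 20))
        stat[[0, 2], 5:10] = 2.0
        p[[0, 2], 5:10] = 0.01
        clusters, _ = rs.find_clusters(stat, p, 0.05, adj)
        assert len(clusters) == 2

    def test_opposite_signs_never_join(self, adj16):
        stat = np.zeros((16, 20))
        p = np.ones((16, 20))
        stat[0, 5:10] = 3.0
        stat[0, 10:15] = -3.0
        p[0, 5:15] = 0.01
        clusters, _ = rs.find_clusters(stat, p, 0.05, adj16)
        assert sorted(c.sign for c in clusters) == [-1, 1]

    def test_matches_bfs_oracle_on_random_grids(self, rng):
        pos = Montage(6).positions
        adj = rs.build_adjacency(pos, names=[f"c{i}" for i in range(6)])
        pairs = [tuple(p) for p in adj.pairs()]
        for rep in range(100):
            stat = rng.standard_normal((6, 15))
            p = 2 * stats.norm.sf(np.abs(stat))
            alpha = 0.4  # dense enough to form nontrivial shapes
            clusters, labels = rs.find_clusters(stat, p, alpha, adj)
            got = {frozenset(zip(*c.cells)) for c in clusters}
            expect = set()
            for sign in (1, -1):
                active = (p < alpha) & (np.sign(stat) == sign)
                expect |= _bfs_components(active, pairs)
            assert got == expect


class TestClusterCorrect:
    def test_same_seed_identical_result(self, adj16, rng):
        x = rng.standard_normal((12, 16, 40))
        a = rs.cluster_correct(x, adj16, n_boot=120, seed=3)
        b = rs.cluster_correct(x, adj16, n_boot=120, seed=3)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.cluster_pvalues, b.cluster_pvalues)
        assert np.array_equal(a.boot_max_mass, b.boot_max_mass)

    def test_too_few_units_rejected(self, adj16):
        with pytest.raises(ValueError, match="10 units"):
            rs.cluster_correct(np.zeros((5, 16, 10)), adj16)

    def test_small_bootstrap_warns(self, adj16, rng):
        with pytest.warns(UserWarning, match="n_boot"):
            rs.cluster_correct(rng.standard_normal((12, 16, 10)), adj16,
                               n_boot=50, seed=0)

    def test_injected_effect_recovered_in_place(self, adj16, rng):
        x = rng.standard_normal((24, 16, 60))
        seeded_ch = [0] + list(np.flatnonzero(adj16.matrix[0])[:2])
        x[:, seeded_ch, 20:40] += 1.5
        res = rs.cluster_correct(x, adj16, n_boot=150, seed=7)
        seeded = np.zeros((16, 60), dtype=bool)
        seeded[np.ix_(seeded_ch, range(20, 40))] = True
        coverage = res.mask[seeded].mean()
        outside = res.mask & ~seeded
        # allow a 1-channel / 5-sample halo around the seeded block
        halo = np.zeros_like(seeded)
        halo_ch = set(seeded_ch)
        for c in seeded_ch:
            halo_ch |= set(np.flatnonzero(adj16.matrix[c]))
        halo[np.ix_(sorted(halo_ch), range(15, 45))] = True
        assert coverage >= 0.5
        assert not (outside & ~halo).any()

    def test_detection_monotone_in_amplitude(self, adj16, rng):
        rates = []
        for amp in (0.0, 0.8, 2.0):
            hits = 0
            for rep in range(5):
                x = rng.standard_normal((20, 16, 30))
                x[:, [0, 1], 10:20] += amp
                res = rs.cluster_correct(x, adj16, n_boot=120,
                                         seed=50 * rep + int(10 * amp))
                hits += int(res.mask.any())
            rates.append(hits)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 5

    def test_paired_design_equals_one_sample_on_differences(self, adj16, rng):
        a = rng.standard_normal((12, 16, 20))
        b = rng.standard_normal((12, 16, 20))
        pa = rs.cluster_correct((a, b), adj16, design="paired", n_boot=100,
                                seed=2)
        os = rs.cluster_correct(a - b, adj16, design="one_sample", n_boot=100,
                                seed=2)
        assert np.allclose(pa.stat_map, os.stat_map)
        assert np.array_equal(pa.mask, os.mask)


class TestHierarchical:
    def test_orthogonal_covariate_contrast_equals_mean_difference(self, rng):
        n = 40
        cond = np.repeat([0.0, 1.0], n // 2)
        cov = np.tile([-1.0, 1.0], n // 2)  # orthogonal to condition
        y = rng.standard_normal((n, 2, 5)) + cond[:, None, None] * 2.0
        maps = rs.first_level_covariate(y, cond, cov)
        diff = y[cond == 1].mean(axis=0) - y[cond == 0].mean(axis=0)
        assert np.allclose(maps["condition"], diff, atol=1e-10)

    def test_confounded_covariate_rejected(self, rng):
        cond = np.repeat([0.0, 1.0], 10)
        y = rng.standard_normal((20, 2, 3))
        with pytest.raises(ValueError, match="rank"):
            rs.first_level_covariate(y, cond, 2.0 * cond + 1.0)

    def test_generative_slope_recovered(self, rng):
        n, slope = 120, 1.7
        cond = rng.integers(0, 2, n).astype(float)
        cov = rng.standard_normal(n)
        y = (0.5 * cond[:, None, None] + slope * cov[:, None, None]
             + 0.3 * rng.standard_normal((n, 2, 4)))
        maps = rs.first_level_covariate(y, cond, cov)
        assert np.abs(maps["covariate"] - slope).max() < 0.2

    def test_second_level_sign_symmetry(self, adj16, rng):
        maps = rng.standard_normal((12, 16, 20)) + 0.4
        a = rs.second_level(maps, adj16, n_boot=100, seed=4)
        b = rs.second_level(-maps, adj16, n_boot=100, seed=4)
        assert np.allclose(a.stat_map, -b.stat_map)

    def test_constant_coefficient_map_fully_significant(self, adj16):
        maps = np.full((12, 16, 20), 0.8)
        res = rs.second_level(maps, adj16, n_boot=100, seed=1)
        assert res.mask.all()
        assert len(res.clusters) == 1

    def test_too_few_subjects_rejected(self, adj16):
        with pytest.raises(ValueError, match="10 subjects"):
            rs.second_level(np.zeros((6, 16, 5)), adj16)
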