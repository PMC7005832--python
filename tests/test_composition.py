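import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paleocomm.composition import (
    DissimilarityMatrix,
    bray_curtis,
    centroid_dissimilarity,
    dissimilarity_matrix,
    kulczynski_pa,
    nmds,
    permanova,
    sequential_centroid_dissimilarity,
    transform,
)
from paleocomm.occurrences import aggregate_to_rank, filter_min_specimens
from paleocomm.synthetic import ScenarioConfig, simulate


class TestTransform:
    def test_relative_rows_sum_to_one(self, tiny_table):
        rel = transform(tiny_table, "relative")
        assert np.allclose(rel.sum(axis=1), 1.0)
        assert rel.loc["s1", "Ostrea alpha"] == pytest.approx(0.5)

    def test_relative_sqrt(self, tiny_table):
        rel = transform(tiny_table, "relative")
        sq = transform(tiny_table, "relative_sqrt")
        assert np.allclose(sq.to_numpy(), np.sqrt(rel.to_numpy()))

    def test_presence_absence(self, tiny_table):
        pa = transform(tiny_table, "presence_absence")
        assert set(np.unique(pa.to_numpy())) <= {0.0, 1.0}
        assert pa.loc["s1"].sum() == 3

    def test_zero_sample_rejected(self, tiny_table):
        bad = tiny_table.copy()
        bad.counts.loc["s1"] = 0
        with pytest.raises(ValueError, match="zero total"):
            transform(bad, "relative")


class TestCoefficients:
    def test_bray_curtis_examples(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0], [0, 2]) == 1.0
        assert bray_curtis([0.75, 0.25], [0.25, 0.75]) == pytest.approx(0.5)

    def test_kulczynski_examples(self):
        assert kulczynski_pa([1, 1], [1, 1]) == 0.0
        assert kulczynski_pa([1, 0], [0, 1]) == 1.0
        # a=2, b=2, c=0
        assert kulczynski_pa([1, 1, 1, 1], [1, 1, 0, 0]) == pytest.approx(0.25)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])
        with pytest.raises(ValueError):
            kulczynski_pa([0, 0], [1, 0])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=2, max_size=8),
           st.lists(st.integers(0, 20), min_size=2, max_size=8))
    def test_symmetry_and_bounds(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) > 0:
            d = bray_curtis(x, y)
            assert 0 <= d <= 1
            assert d == pytest.approx(bray_curtis(y, x))
            if x == y:
                assert d == 0.0
        if sum(x) > 0 and sum(y) > 0:
            k = kulczynski_pa(x, y)
            assert 0 <= k <= 1
            assert k == pytest.approx(kulczynski_pa(y, x))

    def test_matrix_agrees_with_pairwise(self, tiny_table):
        d = dissimilarity_matrix(tiny_table, "bray_curtis", "relative")
        rel = transform(tiny_table, "relative")
        for i, a in enumerate(tiny_table.sample_ids):
            for j, b in enumerate(tiny_table.sample_ids):
                if i < j:
                    assert d.values[i, j] == pytest.approx(
                        bray_curtis(rel.loc[a], rel.loc[b]), abs=1e-12)


class TestNMDS:
    def test_collinear_points_embed_perfectly(self):
        xs = np.array([0.0, 1.0, 2.0, 3.2, 4.5])
        D = np.abs(xs[:, None] - xs[None, :]) / 10.0
        d = DissimilarityMatrix(list("abcde"), D)
        res = nmds(d, k=1, n_restarts=4, seed=0)
        assert res.stress < 1e-6

    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(2)
        pts = rng.random((6, 3))
        pts[5] = pts[0]  # exact duplicate
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        D /= D.max()
        d = DissimilarityMatrix(list(range(6)), D)
        res = nmds(d, k=2, n_restarts=4, seed=1)
        gap = np.linalg.norm(res.coordinates[0] - res.coordinates[5])
        spread = np.linalg.norm(res.coordinates.std(axis=0))
        assert gap < 1e-4 * max(spread, 1e-9) + 1e-6

    def test_best_of_restarts_dominates_single_start(self):
        rng = np.random.default_rng(7)
        D = rng.random((20, 20))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        d = DissimilarityMatrix(list(range(20)), D / D.max())
        multi = nmds(d, k=2, n_restarts=6, seed=3, stress_threshold=np.inf)
        single = nmds(d, k=2, n_restarts=1, seed=3, stress_threshold=np.inf)
        assert multi.stress <= single.stress + 1e-9

    def test_high_stress_samples_excluded(self):
        rng = np.random.default_rng(0)
        D = rng.random((12, 12)) * 0.05
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        # one sample wildly inconsistent with the rest
        D[0, 1:] = D[1:, 0] = np.linspace(0.1, 1.0, 11)
        d = DissimilarityMatrix(list(range(12)), np.clip(D, 0, 1))
        res = nmds(d, k=2, n_restarts=2, seed=0, stress_threshold=0.1)
        assert isinstance(res.excluded, list)
        assert len(res.ids) + len(res.excluded) == 12


class TestPermanova:
    def _null_matrix(self, rng, n=16, p=6):
        X = rng.multinomial(80, np.ones(p) / p, size=n) / 80.0
        mins = np.minimum(X[:, None, :], X[None, :, :]).sum(axis=2)
        D = 1 - mins
        np.fill_diagonal(D, 0.0)
        return DissimilarityMatrix(list(range(n)), (D + D.T) / 2)

    def test_two_group_t_is_sqrt_f(self):
        rng = np.random.default_rng(1)
        d = self._null_matrix(rng)
        res = permanova(d, [0] * 8 + [1] * 8, n_permutations=99, seed=0)
        assert res.t ** 2 == pytest.approx(res.pseudo_F, abs=1e-12)

    def test_disjoint_groups_minimal_p(self):
        # two groups on disjoint taxa: every permutation that mixes them
        # scores lower, so p hits its floor
        rng = np.random.default_rng(0)
        X = np.zeros((16, 8))
        X[:8, :4] = rng.integers(1, 6, size=(8, 4))
        X[8:, 4:] = rng.integers(1, 6, size=(8, 4))
        rel = X / X.sum(axis=1, keepdims=True)
        mins = np.minimum(rel[:, None, :], rel[None, :, :]).sum(axis=2)
        D = 1 - mins
        np.fill_diagonal(D, 0.0)
        d = DissimilarityMatrix(list(range(16)), (D + D.T) / 2)
        res = permanova(d, [0] * 8 + [1] * 8, n_permutations=999, seed=5)
        assert res.p_perm == pytest.approx(1 / 1000)

    def test_single_sample_group_rejected(self):
        rng = np.random.default_rng(2)
        d = self._null_matrix(rng, n=5)
        with pytest.raises(ValueError, match="fewer than two"):
            permanova(d, [0, 0, 0, 0, 1])

    def test_monte_carlo_p_reported_for_small_groups(self):
        rng = np.random.default_rng(3)
        d = self._null_matrix(rng, n=6)
        res = permanova(d, [0, 0, 0, 1, 1, 1], n_permutations=99, seed=1)
        assert res.n_distinct_relabelings == 20
        assert res.p_mc is not None and 0 <= res.p_mc <= 1

    def test_super_uniform_under_relabelling(self):
        """p-values on a fixed null dataset are super-uniform."""
        rng = np.random.default_rng(8)
        d = self._null_matrix(rng, n=14)
        ps = []
        for s in range(300):
            labels = np.array([0] * 7 + [1] * 7)
            rng.shuffle(labels)
            ps.append(permanova(d, labels, n_permutations=99, seed=s).p_perm)
        ps = np.array(ps)
        for alpha in (0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 300)


class TestSequential:
    def test_identical_bins_near_zero_centroid(self):
        rng = np.random.default_rng(4)
        X = rng.multinomial(200, np.ones(6) / 6, size=12) / 200.0
        X[6:] = X[:6]  # bin 1 duplicates bin 0 exactly
        mins = np.minimum(X[:, None, :], X[None, :, :]).sum(axis=2)
        D = 1 - mins
        np.fill_diagonal(D, 0.0)
        d = DissimilarityMatrix(list(range(12)), (D + D.T) / 2)
        cd = centroid_dissimilarity(d, np.arange(6), np.arange(6, 12))
        assert abs(cd) < 1e-9

    def test_single_point_centroids_reduce_to_pairwise(self):
        D = np.array([[0, 0.3, 0.7], [0.3, 0, 0.4], [0.7, 0.4, 0]])
        d = DissimilarityMatrix(list("abc"), D)
        cd = centroid_dissimilarity(d, [0], [2])
        assert cd == pytest.approx(0.7, abs=1e-9)

    def test_planted_shift_detected_at_boundary(self):
        cfg = ScenarioConfig(n_bins=8, n_genera=25, samples_per_bin=6,
                             extinction_prob=0.05, origination_prob=0.05,
                             composition_shift=4, seed=9)
        tab, truth = simulate(cfg)
        gen = aggregate_to_rank(filter_min_specimens(tab))
        d = dissimilarity_matrix(gen, "bray_curtis")
        bins = dict(zip(gen.sample_ids, gen.meta["time_bin"]))
        seq = sequential_centroid_dissimilarity(d, bins, n_permutations=199,
                                                seed=0)
        best = seq.loc[seq["t"].idxmax()]
        assert best["bin"] == 4
        assert seq.loc[seq["centroid_dissimilarity"].idxmax(), "bin"] == 4

    def test_missing_bin_assignment_rejected(self):
        D = np.zeros((3, 3))
        d = DissimilarityMatrix(list("abc"), D)
        with pytest.raises(ValueError, match="without bin"):
            sequential_centroid_dissimilarity(d, {"a": 0, "b": 1}, 99, 0)
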