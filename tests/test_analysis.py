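"""Correlation matrix, profile search, and k-means clustering."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pmkinetics import (
    ProfilePattern,
    RecordSet,
    correlation_matrix,
    kmeans_cluster,
    pearson_with_p,
    profile_search,
)
from pmkinetics.curves import zscore

from conftest import logistic_curve, make_record


def set_of(curves, strains=None):
    t = np.arange(0, len(curves[0]) * 10, 10.0)
    wells = [f"{row}{col:02d}" for row in "ABCDEFGH" for col in range(1, 13)]
    return RecordSet(
        make_record(
            strain=(strains[i] if strains else "S1"),
            phenotype=f"P{i}",
            well=wells[i],
            times=t,
            values=v,
        )
        for i, v in enumerate(curves)
    )


def pearson_oracle(x, y):
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


class TestCorrelationMatrix:
    def test_identical_curves_fully_correlated(self):
        v = logistic_curve(np.arange(0, 300, 10.0), midpoint=150, rate=0.05)
        cm = correlation_matrix(set_of([v, v.copy()]))
        assert cm.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_reversed_ramp_anticorrelated(self):
        ramp = np.linspace(0, 100, 11)
        cm = correlation_matrix(set_of([ramp, ramp[::-1]]))
        assert cm.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(21)
        curves = [rng.uniform(0, 100, 30) for _ in range(5)]
        cm = correlation_matrix(set_of(curves))
        for i in range(5):
            for j in range(5):
                expected = 1.0 if i == j else pearson_oracle(curves[i], curves[j])
                assert cm.matrix[i, j] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(cm.matrix, cm.matrix.T, atol=1e-15)

    def test_permutation_of_records_permutes_matrix(self):
        rng = np.random.default_rng(6)
        curves = [rng.uniform(0, 100, 20) for _ in range(4)]
        cm = correlation_matrix(set_of(curves))
        perm = (2, 0, 3, 1)
        cm_p = correlation_matrix(set_of([curves[i] for i in perm]))
        for a, i in enumerate(perm):
            for b, j in enumerate(perm):
                assert cm_p.matrix[a, b] == pytest.approx(cm.matrix[i, j], abs=1e-12)

    def test_zero_variance_record_marked_undefined(self):
        v = logistic_curve(np.arange(0, 300, 10.0), midpoint=150, rate=0.05)
        flat = np.full(v.size, 7.0)
        cm = correlation_matrix(set_of([v, flat, v * 2]))
        assert cm.degenerate == (1,)
        assert np.isnan(cm.matrix[1]).all() and np.isnan(cm.matrix[:, 1]).all()
        assert cm.matrix[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            correlation_matrix(set_of([np.arange(10.0)]))


class TestPearsonWithP:
    def test_perfect_correlation_gives_p_zero(self):
        x = np.arange(10.0)
        r, p = pearson_with_p(x, x)
        assert (r, p) == (1.0, 0.0)

    def test_zero_correlation_gives_p_one(self):
        # orthogonal by construction: x alternates ±1 within constant-y pairs
        x = np.tile([1.0, -1.0], 6)
        y = np.repeat(np.arange(6.0), 2)
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_reference_implementation(self):
        x = [1, 2, 4, 8, 16]
        y = [1, 3, 5, 7, 11]
        r, p = pearson_with_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_matches_reference_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = rng.integers(3, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_p_monotone_decreasing_in_abs_r(self):
        # same n, increasing |r| -> decreasing p
        n = 12
        rng = np.random.default_rng(1)
        base = rng.normal(size=n)
        noise = rng.normal(size=n)
        results = []
        for w in (0.2, 0.5, 0.8, 0.95):
            y = w * base + (1 - w) * noise
            r, p = pearson_with_p(base, y)
            results.append((abs(r), p))
        results.sort()
        ps = [p for _, p in results]
        assert ps == sorted(ps, reverse=True)

    def test_errors_on_short_or_constant_input(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_with_p([1, 2], [3, 4])
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p([1, 1, 1], [1, 2, 3])


class TestProfileSearch:
    def test_self_match_ranks_first_with_r_one(self):
        t = np.arange(0, 300, 10.0)
        target = logistic_curve(t, midpoint=150, rate=0.05)
        others = [np.full(t.size, 20.0) + np.linspace(0, 5, t.size),
                  logistic_curve(t, midpoint=280, rate=0.01)]
        rs = set_of([target] + others)
        matches = profile_search(rs, ProfilePattern(t, target))
        assert matches[0].label[1] == "P0"
        assert matches[0].r == pytest.approx(1.0, abs=1e-9)
        assert matches[0].rank == 1

    def test_decreasing_record_anticorrelates_with_increasing_pattern(self):
        t = np.arange(0, 200, 10.0)
        rs = set_of([np.linspace(100, 0, t.size)])
        pattern = ProfilePattern([0.0, 190.0], [0.0, 100.0])
        matches = profile_search(rs, pattern)
        assert matches[0].r < 0

    def test_planted_sigmoid_outranks_flat_and_noise(self):
        # same 10-min axis that set_of assigns to 288-point curves
        t = np.arange(0, 2880, 10.0)
        rng = np.random.default_rng(2)
        planted = np.clip(logistic_curve(t) + rng.normal(0, 2, t.size), 0, None)
        decoys = [
            np.clip(np.full(t.size, 25.0) + rng.normal(0, 2, t.size), 0, None)
            for _ in range(5)
        ]
        rs = set_of(decoys[:2] + [planted] + decoys[2:])
        anchor_t = np.array([0.0, 400, 700, 900, 1000, 1100, 1300, 1600, 2870])
        pattern = ProfilePattern(anchor_t, logistic_curve(anchor_t))
        matches = profile_search(rs, pattern)
        assert matches[0].label[1] == "P2"
        assert matches[0].r > 0.95

    def test_results_ordered_by_descending_r(self):
        t = np.arange(0, 300, 10.0)
        rng = np.random.default_rng(14)
        rs = set_of([rng.uniform(0, 100, t.size) for _ in range(6)])
        pattern = ProfilePattern(t, logistic_curve(t, midpoint=150, rate=0.05))
        matches = profile_search(rs, pattern)
        rvals = [m.r for m in matches]
        assert rvals == sorted(rvals, reverse=True)
        assert [m.rank for m in matches] == list(range(1, 7))

    def test_disjoint_pattern_range_rejected(self):
        t = np.arange(0, 100, 10.0)
        rs = set_of([np.linspace(0, 50, t.size)])
        with pytest.raises(ValueError, match="overlap"):
            profile_search(rs, ProfilePattern([500.0, 600.0], [0.0, 1.0]))


def brute_force_best_wss(X, k):
    """Minimum within-cluster sum of squares over all k-partitions."""
    n = X.shape[0]
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        wss = 0.0
        for c in range(k):
            members = X[np.array(assignment) == c]
            wss += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, wss)
    return best


class TestKmeans:
    def _families(self, n_per=6, noise=0.5, seed=0):
        t = np.arange(0, 4320, 60.0)
        rng = np.random.default_rng(seed)
        ups = [
            np.clip(logistic_curve(t, midpoint=1000 + 100 * i)
                    + rng.normal(0, noise, t.size), 0, None)
            for i in range(n_per)
        ]
        downs = [
            np.clip(220 - logistic_curve(t, midpoint=1000 + 100 * i)
                    + rng.normal(0, noise, t.size), 0, None)
            for i in range(n_per)
        ]
        return ups, downs

    def test_k1_centroid_is_mean_of_scaled_curves(self):
        ups, downs = self._families(3)
        rs = set_of(ups + downs)
        cr = kmeans_cluster(rs, k=1, seed=0)
        scaled = np.vstack([zscore(v)[0] for v in (
            np.vstack([r.curve.values for r in rs])
        )])
        np.testing.assert_allclose(cr.centroids[0], scaled.mean(axis=0), atol=1e-10)
        assert set(cr.memberships.values()) == {1}

    def test_two_planted_families_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        ups, downs = self._families(6, noise=0.5, seed=3)
        rs = set_of(ups + downs)
        cr = kmeans_cluster(rs, k=2, seed=42)
        truth = [0] * 6 + [1] * 6
        found = [cr.memberships[r.label] for r in rs]
        assert adjusted_rand_score(truth, found) == 1.0

    def test_six_records_match_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(77)
        curves = [rng.uniform(0, 100, 15) for _ in range(6)]
        rs = set_of(curves)
        cr = kmeans_cluster(rs, k=2, seed=1, restarts=20)
        X = np.vstack([zscore(c)[0] for c in curves])
        assert cr.inertia == pytest.approx(brute_force_best_wss(X, 2), rel=1e-9)

    def test_same_seed_bit_reproducible(self):
        ups, downs = self._families(4, noise=1.0, seed=5)
        rs = set_of(ups + downs)
        a = kmeans_cluster(rs, k=3, seed=7)
        b = kmeans_cluster(rs, k=3, seed=7)
        assert a.memberships == b.memberships
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.inertia == b.inertia

    def test_objective_never_increases_with_more_restarts(self):
        rng = np.random.default_rng(13)
        curves = [rng.uniform(0, 100, 20) for _ in range(12)]
        rs = set_of(curves)
        previous = np.inf
        for restarts in (1, 5, 15):
            cr = kmeans_cluster(rs, k=3, seed=2, restarts=restarts)
            assert cr.inertia <= previous + 1e-9
            previous = cr.inertia

    def test_member_centroid_correlation_reported(self):
        ups, downs = self._families(5, noise=0.5, seed=9)
        rs = set_of(ups + downs)
        cr = kmeans_cluster(rs, k=2, seed=0)
        assert set(cr.member_centroid_r) == set(cr.memberships)
        assert all(r > 0.9 for r in cr.member_centroid_r.values())

    def test_zero_variance_records_excluded_with_warning(self):
        ups, _ = self._families(3, noise=0.5)
        flat = np.full(ups[0].size, 10.0)
        rs = set_of(ups + [flat])
        cr = kmeans_cluster(rs, k=2, seed=0)
        assert len(cr.excluded) == 1
        assert len(cr.memberships) == 3

    def test_k_exceeding_usable_records_rejected(self):
        ups, _ = self._families(2, noise=0.5)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(set_of(ups), k=5, seed=0)
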