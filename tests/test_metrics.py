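"""Clustering metrics: exact k-means DP, Ripley curve, nulls, calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichecluster import (
    RegionalPool,
    kmeans_gap_metric,
    make_fixture,
    make_nulls,
    ripley_deficit_curve,
    ripley_gap_metric,
    weighted_kmeans_dispersion,
    zscore_pvalue,
)
from nichecluster.metrics import _logW_curve, default_d_grid


def _uniform_pool(n, rng, equal_q=True):
    traits = rng.uniform(0, 1, n)
    q = np.full(n, 1.0 / n)
    return RegionalPool(
        species_id=np.arange(n), trait=traits, q=q, theta=1.0,
        metacommunity_size=max(n, 1000),
    )


# ---------------------------------------------------------------------------
# null ensemble


class TestNulls:
    def test_abundance_multiset_conserved(self, rng):
        pool = _uniform_pool(40, rng)
        N = np.zeros(40, dtype=np.int64)
        N[rng.choice(40, 15, replace=False)] = rng.integers(1, 100, 15)
        nulls = make_nulls(N, pool, B=50, rng=rng)
        target = np.sort(N[N > 0])
        for row in nulls.communities:
            assert np.array_equal(np.sort(row[row > 0]), target)

    def test_shuffle_is_uniform_over_species(self, rng):
        """Each pool species receives the largest abundance ~1/S of the time."""
        S, B = 10, 6000
        pool = _uniform_pool(S, rng)
        N = np.arange(1, S + 1, dtype=np.int64)  # distinct abundances
        nulls = make_nulls(N, pool, B=B, rng=rng)
        hits = np.bincount(np.argmax(nulls.communities, axis=1), minlength=S)
        expected = B / S
        assert np.all(np.abs(hits - expected) < 5 * np.sqrt(expected))

    def test_rejects_empty_ensemble(self, rng):
        pool = _uniform_pool(5, rng)
        with pytest.raises(ValueError):
            make_nulls(np.ones(5, dtype=np.int64), pool, B=0, rng=rng)


# ---------------------------------------------------------------------------
# exact weighted k-means


def _brute_force_Wk(x, w, k):
    """Minimal weighted within-cluster SS over all contiguous partitions."""
    order = np.argsort(x)
    x, w = x[order], w[order]
    n = x.size

    def seg(i, j):
        sw = w[i:j].sum()
        mu = (w[i:j] * x[i:j]).sum() / sw
        return (w[i:j] * (x[i:j] - mu) ** 2).sum()

    best = np.inf
    for bounds in itertools.combinations(range(1, n), k - 1):
        cuts = (0, *bounds, n)
        W = sum(seg(a, b) for a, b in zip(cuts, cuts[1:]))
        best = min(best, W)
    return best


class TestWeightedKMeans:
    def test_k1_is_weighted_variance(self, rng):
        x = rng.uniform(0, 1, 20)
        w = rng.integers(1, 50, 20).astype(float)
        _, logW = weighted_kmeans_dispersion(x, w, k=1)
        mu = (w * x).sum() / w.sum()
        assert logW == pytest.approx(np.log((w * (x - mu) ** 2).sum() + 1e-12))

    def test_two_point_masses_are_two_perfect_clusters(self):
        x = np.array([0.2, 0.2, 0.8, 0.8])
        w = np.array([3.0, 2.0, 1.0, 4.0])
        labels, logW = weighted_kmeans_dispersion(x, w, k=2)
        assert np.exp(logW) == pytest.approx(1e-12, rel=1e-2)  # W_2 = 0 + floor
        assert len(set(labels[:2])) == 1 and len(set(labels[2:])) == 1

    def test_three_species_partition_by_hand(self):
        x = np.array([0.1, 0.2, 0.9])
        w = np.ones(3)
        labels, logW = weighted_kmeans_dispersion(x, w, k=2)
        # optimal split: {0.1, 0.2} | {0.9}; SS = 2*(0.05)^2
        assert labels[0] == labels[1] != labels[2]
        assert logW == pytest.approx(np.log(2 * 0.05**2 + 1e-12))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(3, 12), st.integers(1, 4), st.integers(0, 10**6))
    def test_dp_matches_brute_force(self, n, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, n)
        w = rng.integers(1, 30, n).astype(float)
        k = min(k, n)
        _, logW = weighted_kmeans_dispersion(x, w, k)
        assert np.exp(logW) == pytest.approx(
            _brute_force_Wk(x, w, k), rel=1e-9, abs=1e-11
        )

    def test_dp_never_beaten_by_sklearn(self, rng):
        """The exact optimum is at most sklearn's restarted local optimum."""
        sklearn = pytest.importorskip("sklearn.cluster")
        for _ in range(5):
            x = rng.uniform(0, 1, 60)
            w = rng.integers(1, 100, 60).astype(float)
            for k in (2, 5, 9):
                _, logW = weighted_kmeans_dispersion(x, w, k)
                km = sklearn.KMeans(n_clusters=k, n_init=10, random_state=0)
                km.fit(x.reshape(-1, 1), sample_weight=w)
                assert np.exp(logW) <= km.inertia_ * (1 + 1e-9) + 1e-12

    def test_k_clamped_with_warning(self):
        x = np.array([0.3, 0.3, 0.7])
        w = np.ones(3)
        with pytest.warns(UserWarning, match="clamp"):
            _, logW = weighted_kmeans_dispersion(x, w, k=3)
        assert np.isfinite(logW)

    def test_zero_abundance_species_ignored(self):
        x = np.array([0.1, 0.5, 0.9])
        w = np.array([2.0, 0.0, 3.0])
        labels, logW = weighted_kmeans_dispersion(x, w, k=2)
        assert labels[1] == -1
        assert logW == pytest.approx(np.log(1e-12))


# ---------------------------------------------------------------------------
# z-scores and p-values


class TestZscorePvalue:
    def test_hand_example(self):
        z, p = zscore_pvalue(3.0, np.array([1.0, 2.0, 3.0, 4.0]))
        assert z == pytest.approx(0.5 / np.std([1, 2, 3, 4], ddof=1))
        assert p == pytest.approx(0.6)

    def test_observation_above_all_nulls(self):
        z, p = zscore_pvalue(1000.0, np.arange(100, dtype=float))
        assert p == pytest.approx(1 / 101)

    def test_at_null_mean(self):
        z, p = zscore_pvalue(2.5, np.array([1.0, 2.0, 3.0, 4.0]))
        assert z == pytest.approx(0.0)

    def test_zero_spread_gives_undefined_z(self):
        z, p = zscore_pvalue(1.0, np.array([1.0, 1.0, 1.0]))
        assert z is None
        assert p == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Ripley curve


class TestRipleyCurve:
    def test_single_species_curve_is_zero(self, rng):
        pool = _uniform_pool(10, rng)
        N = np.zeros(10, dtype=np.int64)
        N[4] = 100
        K = ripley_deficit_curve(N, pool)
        assert np.all(K == 0.0)

    def test_two_species_step_function(self, rng):
        pool = RegionalPool(
            species_id=np.arange(2), trait=np.array([0.2, 0.5]),
            q=np.array([0.5, 0.5]), theta=1.0, metacommunity_size=100,
        )
        a, b = 7, 3
        d_grid = np.array([0.1, 0.2, 0.3, 0.4])
        K = ripley_deficit_curve(np.array([a, b]), pool, d_grid)
        J = a + b
        expect = 2 * a * b / (J * (J - 1))
        np.testing.assert_allclose(K, [0.0, 0.0, expect, expect])

    def test_monotone_nondecreasing(self, rng):
        pool = _uniform_pool(50, rng)
        N = rng.integers(0, 40, 50).astype(np.int64)
        K = ripley_deficit_curve(N, pool)
        assert np.all(np.diff(K) >= 0)

    def test_uniform_traits_match_analytic_overlap(self, rng):
        """Equal-abundance uniform traits: E K(d) = 2d - d^2."""
        pool = _uniform_pool(2000, rng)
        N = np.ones(2000, dtype=np.int64)
        d_grid = default_d_grid(50)
        K = ripley_deficit_curve(N, pool, d_grid)
        expect = 2 * d_grid - d_grid**2
        assert np.max(np.abs(K - expect)) < 0.05


# ---------------------------------------------------------------------------
# full gap metrics


class TestGapMetrics:
    def test_thirteen_clumps_recovered(self, rng):
        community, pool = make_fixture("k_clumps", rng, k=13, width=0.005)
        km = kmeans_gap_metric(community, pool, B=100, rng=rng)
        assert km.k_est == 13
        assert km.p <= 0.01
        rp = ripley_gap_metric(community, pool, B=100, rng=rng)
        assert rp.p <= 0.01
        # gap scale falls between clump width and clump spacing
        assert 0.005 < rp.d_gap < 1 / 13

    def test_single_cluster_detected_as_one(self, rng):
        community, pool = make_fixture("single_cluster", rng, width=0.05)
        km = kmeans_gap_metric(community, pool, B=100, rng=rng)
        assert km.k_est == 1
        assert km.significant
        assert not km.multiple_clusters

    def test_reflection_invariance(self, rng):
        community, pool = make_fixture("k_clumps", rng, k=5, width=0.01)
        mirrored = RegionalPool(
            species_id=pool.species_id, trait=1.0 - pool.trait, q=pool.q,
            theta=pool.theta, metacommunity_size=pool.metacommunity_size,
        )
        for fn in (kmeans_gap_metric, ripley_gap_metric):
            a = fn(community.N, pool, B=40, rng=np.random.default_rng(7))
            b = fn(community.N, mirrored, B=40, rng=np.random.default_rng(7))
            assert a.statistic == pytest.approx(b.statistic, rel=1e-9)
            assert a.p == b.p

    def test_species_relabeling_invariance(self, rng):
        community, pool = make_fixture("k_clumps", rng, k=4, width=0.01, pool_size=60)
        perm = np.random.default_rng(3).permutation(pool.S)
        pool_p = RegionalPool(
            species_id=np.arange(pool.S), trait=pool.trait[perm], q=pool.q[perm],
            theta=pool.theta, metacommunity_size=pool.metacommunity_size,
        )
        a = kmeans_gap_metric(community.N, pool, B=40, rng=np.random.default_rng(5))
        b = kmeans_gap_metric(
            community.N[perm], pool_p, B=40, rng=np.random.default_rng(5)
        )
        # same observed dispersion curve in either labeling
        np.testing.assert_allclose(
            _logW_curve(pool.trait, community.N, 10),
            _logW_curve(pool_p.trait, community.N[perm], 10),
            rtol=1e-9,
        )
        assert a.k_est == b.k_est

    def test_power_grows_as_clumps_tighten(self):
        zs = []
        for width in (0.03, 0.012, 0.004):
            rng = np.random.default_rng(42)
            community, pool = make_fixture("k_clumps", rng, k=13, width=width)
            res = kmeans_gap_metric(community, pool, B=60, rng=rng)
            zs.append(res.z)
        assert zs[0] < zs[1] < zs[2]

    @pytest.mark.parametrize("method", ["kmeans", "ripley"])
    def test_null_calibration_at_five_percent(self, method):
        """Feeding shuffled (null-generated) communities into the metric
        rejects at ~5%: the permutation test is exact by construction."""
        fn = kmeans_gap_metric if method == "kmeans" else ripley_gap_metric
        rng = np.random.default_rng(99)
        pool = _uniform_pool(100, rng)
        base = rng.multinomial(5000, pool.q).astype(np.int64)
        n_rep, hits = 150, 0
        for _ in range(n_rep):
            N = rng.permutation(base)
            res = fn(N, pool, B=60, rng=rng)
            hits += res.significant
        # Binomial(150, ~3/61): mean ~7.4, accept within ~4 sigma
        assert hits <= 22

    def test_small_null_ensemble_warns(self, rng):
        community, pool = make_fixture("k_clumps", rng, k=3, width=0.01, pool_size=40)
        with pytest.warns(UserWarning, match="nulls"):
            kmeans_gap_metric(community, pool, B=10, rng=rng)

    def test_result_serialization(self, rng, tmp_path):
        community, pool = make_fixture("k_clumps", rng, k=3, width=0.01, pool_size=40)
        res = ripley_gap_metric(community, pool, B=30, rng=rng)
        res.save(tmp_path / "m.json")
        import json

        payload = json.loads((tmp_path / "m.json").read_text())
        assert payload["method"] == "ripley"
        assert len(payload["curve"]) == len(res.curve)
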