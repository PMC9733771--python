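"""GFP, peak picking, polarity-invariant clustering, GEV/CV, K selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msfusion import microstates as ms
from msfusion.containers import MsfusionError


def random_maps(rng, c, l):
    maps = rng.standard_normal((c, l))
    return maps - maps.mean(axis=0, keepdims=True)


class TestGfp:
    def test_constant_map_zero(self):
        g = ms.compute_gfp(np.array([[5.0], [5.0], [5.0], [5.0]]))
        assert g.values[0] == 0.0

    def test_alternating_unit_map(self):
        g = ms.compute_gfp(np.array([[1.0], [-1.0], [1.0], [-1.0]]))
        assert g.values[0] == pytest.approx(1.0)

    def test_matches_population_sd_oracle(self):
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((32, 50))
        g = ms.compute_gfp(maps)
        oracle = np.array([np.sqrt(np.mean((m - m.mean()) ** 2))
                           for m in maps.T])
        assert np.allclose(g.values, oracle, atol=1e-12)

    @given(offset=st.floats(-100, 100, allow_nan=False))
    @settings(deadline=None, max_examples=25)
    def test_reference_shift_invariance(self, offset):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((16, 20))
        a = ms.compute_gfp(maps).values
        b = ms.compute_gfp(maps + offset).values
        assert np.allclose(a, b, atol=1e-9)

    def test_nan_rejected(self):
        maps = np.full((4, 3), np.nan)
        with pytest.raises(MsfusionError):
            ms.compute_gfp(maps)


class TestGfpPeaks:
    def test_monotone_series_has_no_peaks(self):
        g = ms.GfpSeries(values=np.linspace(0, 1, 100), fs=250.0)
        with pytest.raises(MsfusionError, match="peak"):
            ms.find_gfp_peaks(g, np.zeros((4, 100)))

    def test_minimum_distance_keeps_larger(self):
        v = np.zeros(200) + 0.1
        v[100] = 1.0
        v[101] = 0.9  # 4 ms apart at 250 Hz: below the 10 ms floor
        g = ms.GfpSeries(values=v, fs=250.0)
        rng = np.random.default_rng(0)
        maps = rng.standard_normal((4, 200))
        peaks = ms.find_gfp_peaks(g, maps, sd_reject=np.inf, seed=0)
        idx = [p.sample_index for p in peaks]
        assert 100 in idx and 101 not in idx

    def test_known_peaks_found_matches_scan_oracle(self):
        rng = np.random.default_rng(1)
        fs = 250.0
        n = 20000
        v = np.full(n, 1.0)
        locs = np.arange(200, n - 200, 390)  # > 10 ms apart
        heights = rng.uniform(2.0, 3.0, locs.size)  # none outlying
        for loc, h in zip(locs, heights):
            v[loc] = h
        g = ms.GfpSeries(values=v, fs=fs)
        maps = rng.standard_normal((4, n))
        peaks = ms.find_gfp_peaks(g, maps, n_per_subject=10000,
                                  sd_reject=np.inf, seed=0)
        found = sorted(p.sample_index for p in peaks)
        # brute-force scan oracle: strictly greater than both neighbours
        oracle = [i for i in range(1, n - 1)
                  if v[i] > v[i - 1] and v[i] > v[i + 1]]
        assert found == oracle
        assert set(found) == set(locs)

    def test_outlier_rejection_upper_cut(self):
        v = np.full(2000, 1.0)
        v[::40] = 2.0
        v[100] = 50.0  # far above mean + 1 SD
        g = ms.GfpSeries(values=v, fs=250.0)
        maps = np.random.default_rng(2).standard_normal((4, 2000))
        peaks = ms.find_gfp_peaks(g, maps, sd_reject=1.0, seed=0)
        assert 100 not in [p.sample_index for p in peaks]

    def test_subsampling_respects_budget(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(1, 2, 50000)
        g = ms.GfpSeries(values=v, fs=250.0)
        maps = rng.standard_normal((4, 50000))
        peaks = ms.find_gfp_peaks(g, maps, n_per_subject=100, seed=0)
        assert len(peaks) == 100


class TestModifiedKmeans:
    def test_noiseless_two_state_recovery(self):
        rng = np.random.default_rng(0)
        p1 = rng.standard_normal(16)
        p1 -= p1.mean()
        p1 /= np.linalg.norm(p1)
        p2 = rng.standard_normal(16)
        p2 -= p2.mean()
        p2 -= (p2 @ p1) * p1
        p2 /= np.linalg.norm(p2)
        protos = np.vstack([p1, p2])
        labels = rng.integers(0, 2, 300)
        X = protos[labels] * (rng.choice([-1.0, 1.0], 300)
                              * rng.uniform(0.5, 2.0, 300))[:, None]
        model = ms.modified_kmeans(X, 2, restarts=10, seed=1)
        corr = np.abs(model.prototypes @ protos.T)
        # permutation-free check: every truth matched by some prototype
        assert corr.max(axis=0).min() > 0.999
        assert model.gev_total > 0.999

    def test_single_cluster_identical_samples(self):
        rng = np.random.default_rng(1)
        p = rng.standard_normal(8)
        p -= p.mean()
        p /= np.linalg.norm(p)
        X = p[None, :] * rng.choice([-1.0, 1.0], 20)[:, None]
        model = ms.modified_kmeans(X, 1, restarts=3, seed=0)
        assert abs(model.prototypes[0] @ p) == pytest.approx(1.0, abs=1e-12)
        assert model.gev_total == pytest.approx(1.0)
        assert model.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_search_on_tiny_instance(self):
        """Residual variance equals brute force over every polarity-
        invariant assignment of 6 samples to 2 clusters."""
        rng = np.random.default_rng(2)
        X = random_maps(rng, 4, 6).T  # 6 samples, C=4
        n, c = X.shape
        total = np.sum(X ** 2)
        best = np.inf
        for assign in itertools.product([0, 1], repeat=n):
            if 0 not in assign or 1 not in assign:
                continue
            resid = total
            for j in (0, 1):
                S = X[np.array(assign) == j]
                w = np.linalg.eigvalsh(S.T @ S)
                resid -= w[-1]
            best = min(best, resid / (n * (c - 1)))
        model = ms.modified_kmeans(X, 2, restarts=50, seed=3)
        assert model.sigma2 == pytest.approx(best, rel=1e-9)

    def test_polarity_invariance_of_fit(self):
        rng = np.random.default_rng(4)
        X = random_maps(rng, 8, 60).T
        flips = rng.choice([-1.0, 1.0], 60)[:, None]
        m1 = ms.modified_kmeans(X, 3, restarts=20, seed=5)
        m2 = ms.modified_kmeans(X * flips, 3, restarts=20, seed=5)
        assert m1.sigma2 == pytest.approx(m2.sigma2, rel=1e-9)
        corr = np.abs(m1.prototypes @ m2.prototypes.T)
        assert np.allclose(np.sort(corr.max(axis=1)), 1.0, atol=1e-6)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        X = random_maps(rng, 8, 100).T
        a = ms.modified_kmeans(X, 3, restarts=5, seed=7)
        b = ms.modified_kmeans(X, 3, restarts=5, seed=7)
        assert np.array_equal(a.prototypes, b.prototypes)
        assert a.sigma2 == b.sigma2

    def test_too_few_samples_rejected(self):
        with pytest.raises(MsfusionError):
            ms.modified_kmeans(np.zeros((3, 8)), 4)


class TestGev:
    def test_perfect_fit_gives_one(self):
        rng = np.random.default_rng(0)
        protos = random_maps(rng, 8, 3).T
        protos /= np.linalg.norm(protos, axis=1, keepdims=True)
        labels = rng.integers(0, 3, 40)
        gains = rng.uniform(0.5, 3.0, 40)
        maps = (protos[labels] * gains[:, None]).T
        total, per_state = ms.compute_gev(maps, labels, protos)
        assert total == pytest.approx(1.0)
        assert per_state.sum() == pytest.approx(total)

    def test_orthogonal_prototypes_give_zero(self):
        c = 8
        maps = np.zeros((c, 10))
        maps[0] = 1.0
        maps[1] = -1.0
        maps -= maps.mean(axis=0, keepdims=True)
        proto = np.zeros((1, c))
        proto[0, 2] = 1.0
        proto[0, 3] = -1.0
        proto -= proto.mean(axis=1, keepdims=True)
        proto /= np.linalg.norm(proto)
        total, _ = ms.compute_gev(maps, np.zeros(10, int), proto)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_matches_literal_formula_oracle(self):
        rng = np.random.default_rng(1)
        c, l, k = 8, 200, 3
        maps = random_maps(rng, c, l)
        protos = random_maps(rng, c, k).T
        protos /= np.linalg.norm(protos, axis=1, keepdims=True)
        labels = rng.integers(0, k, l)
        total, per_state = ms.compute_gev(maps, labels, protos)
        # term-by-term transcription
        num = 0.0
        den = 0.0
        for t in range(l):
            m = maps[:, t] - maps[:, t].mean()
            gfp = np.sqrt(np.mean(m ** 2))
            a = protos[labels[t]] - protos[labels[t]].mean()
            corr = np.corrcoef(m, a)[0, 1]
            num += (corr * gfp) ** 2
            den += gfp ** 2
        assert total == pytest.approx(num / den, abs=1e-9)

    def test_zero_gfp_rejected(self):
        with pytest.raises(MsfusionError):
            ms.compute_gev(np.zeros((4, 5)), np.zeros(5, int),
                           np.eye(4)[:1])


class TestCv:
    def test_arithmetic_oracle(self):
        assert ms.compute_cv(1.0, 32, 6) == pytest.approx((31 / 25) ** 2)
        assert ms.compute_cv(1.0, 32, 6) == pytest.approx(1.5376)

    def test_zero_residual(self):
        for k in (2, 5, 10):
            assert ms.compute_cv(0.0, 32, k) == 0.0

    def test_multiplier_strictly_increasing_in_k(self):
        vals = [ms.compute_cv(1.0, 32, k) for k in range(2, 30)]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_k_rejected(self):
        with pytest.raises(MsfusionError):
            ms.compute_cv(1.0, 8, 7)


class TestSelectK:
    def _samples(self, rng, k_true=3, n=400, c=16):
        protos = random_maps(rng, c, k_true).T
        # orthogonalize for a crisp instance
        q, _ = np.linalg.qr(protos.T)
        protos = q.T[:k_true]
        protos -= protos.mean(axis=1, keepdims=True)
        protos /= np.linalg.norm(protos, axis=1, keepdims=True)
        labels = rng.integers(0, k_true, n)
        X = protos[labels] * rng.choice([-1.0, 1.0], n)[:, None]
        X = X + 0.15 * rng.standard_normal((n, c))
        return X

    def test_trivial_range_returns_k2(self):
        rng = np.random.default_rng(0)
        X = self._samples(rng)
        model, table = ms.select_k(X, k_range=(2, 2), restarts=5, seed=1)
        assert model.k == 2
        assert list(table["k"]) == [2]

    def test_gev_nondecreasing_within_restart_noise(self):
        rng = np.random.default_rng(1)
        X = self._samples(rng, n=600)
        _, table = ms.select_k(X, k_range=(2, 6), restarts=20, seed=2)
        gev = table["gev"].to_numpy()
        assert np.all(np.diff(gev) > -0.005)

    def test_invalid_range_rejected(self):
        rng = np.random.default_rng(2)
        X = self._samples(rng)
        with pytest.raises(MsfusionError):
            ms.select_k(X, k_range=(2, 15), restarts=2, seed=0)
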