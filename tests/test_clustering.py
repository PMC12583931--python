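"""DTW/xcorr distances, initialization, k-medoids, representatives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scgpipe.clustering import (
    BeatDistanceCache,
    BeatKMedoids,
    cluster_space_plot,
    dtw_distance,
    initial_medoids,
    kmedoids_two,
    representative_beat,
    select_best_clustering,
    xcorr_distance,
)
from scgpipe.errors import DegenerateSplitError, InvalidConfigError
from scgpipe.features import wv_inter, wv_intra


def brute_force_dtw(a, b):
    """Enumerate all monotone warping paths; return (min cost, optimal lengths)."""
    n, m = len(a), len(b)
    memo = {}

    def rec(i, j):
        if (i, j) in memo:
            return memo[(i, j)]
        c = abs(a[i] - b[j])
        if i == n - 1 and j == m - 1:
            res = (c, {1})
        else:
            opts = []
            if i + 1 < n and j + 1 < m:
                opts.append(rec(i + 1, j + 1))
            if i + 1 < n:
                opts.append(rec(i + 1, j))
            if j + 1 < m:
                opts.append(rec(i, j + 1))
            mc = min(o[0] for o in opts)
            lens = set()
            for o in opts:
                if o[0] == mc:
                    lens |= o[1]
            res = (c + mc, {l + 1 for l in lens})
        memo[(i, j)] = res
        return res

    return rec(0, 0)


def _waveform(rng, length=40):
    t = np.linspace(0, 1, length)
    return np.sin(2 * np.pi * rng.uniform(1, 4) * t) + 0.1 * rng.standard_normal(length)


class TestDTW:
    def test_identity(self):
        x = np.array([0.3, 1.2, -0.5, 0.8])
        r = dtw_distance(x, x)
        assert r.distance == 0.0
        assert r.path_length == len(x)

    def test_hand_example(self):
        r = dtw_distance([0.0, 0.0], [1.0, 1.0])
        assert r.distance == 2.0
        assert r.path_length == 2

    def test_matches_brute_force_on_small_integer_series(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n, m = rng.integers(2, 9, size=2)
            a = rng.integers(0, 10, n).astype(float)
            b = rng.integers(0, 10, m).astype(float)
            r = dtw_distance(a, b)
            cost, lengths = brute_force_dtw(a, b)
            assert r.distance == pytest.approx(cost, abs=1e-12)
            assert r.path_length in lengths

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=15),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=15),
    )
    def test_metric_axioms(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        dab = dtw_distance(a, b)
        dba = dtw_distance(b, a)
        assert dab.distance >= 0
        assert dab.distance == pytest.approx(dba.distance, rel=1e-12)
        assert dtw_distance(a, a).distance == 0.0


class TestXcorr:
    def test_identity_zero(self):
        rng = np.random.default_rng(1)
        w = _waveform(rng)
        assert xcorr_distance(w, w).distance == pytest.approx(0.0, abs=1e-12)

    def test_shifted_copy_near_zero(self):
        rng = np.random.default_rng(2)
        w = _waveform(rng, length=100)
        for k in (3, 10):
            shifted = np.concatenate([np.zeros(k), w[:-k]])
            assert xcorr_distance(w, shifted).distance < 0.05

    @staticmethod
    def _oracle(a, b, min_frac=0.5):
        """Independent double-loop per-lag normalized cross-correlation."""
        a0 = a - a.mean()
        b0 = b - b.mean()
        la, lb = len(a0), len(b0)
        best = -np.inf
        for s in range(-(lb - 1), la):
            lo, hi = max(0, s), min(la, s + lb)
            if hi - lo < max(2, int(np.ceil(min_frac * min(la, lb)))):
                continue
            seg_a = a0[lo:hi]
            seg_b = b0[lo - s : hi - s]
            na, nb = np.linalg.norm(seg_a), np.linalg.norm(seg_b)
            if na > 0 and nb > 0:
                best = max(best, float(seg_a @ seg_b) / (na * nb))
        return max(1.0 - best, 0.0)

    def test_negated_asymmetric_template_matches_direct_computation(self):
        # at zero lag a sign flip is perfectly anticorrelated (distance 2),
        # but lag freedom lets a half-period shift realign oscillatory
        # content, so the distance is whatever the direct computation gives
        t = np.linspace(0, 1, 80)
        w = np.exp(-t * 3) * np.sin(2 * np.pi * 5 * t)
        w0 = w - w.mean()
        zero_lag = float(w0 @ (-w0)) / (np.linalg.norm(w0) ** 2)
        assert zero_lag == pytest.approx(-1.0)
        got = xcorr_distance(w, -w).distance
        assert got == pytest.approx(self._oracle(w, -w), abs=1e-9)

    def test_matches_per_lag_oracle_on_random_pairs(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            a = _waveform(rng, length=int(rng.integers(30, 60)))
            b = _waveform(rng, length=int(rng.integers(30, 60)))
            assert xcorr_distance(a, b).distance == pytest.approx(
                self._oracle(a, b), abs=1e-9
            )

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidConfigError):
            xcorr_distance(np.ones(10), np.arange(10.0))


class TestInitialMedoids:
    def test_median_split_on_increasing_covariate(self, make_beatset):
        rng = np.random.default_rng(3)
        waves = [_waveform(rng) for _ in range(6)]
        bs = make_beatset(waves, lv=np.arange(6.0))
        cache = BeatDistanceCache(bs)
        m_low, m_high = initial_medoids(bs, "lung_volume", "dtw", cache)
        assert m_low in {0, 1, 2}
        assert m_high in {3, 4, 5}

    def test_center_matches_row_sum_argmin(self, make_beatset):
        rng = np.random.default_rng(4)
        waves = [_waveform(rng) for _ in range(6)]
        bs = make_beatset(waves, lv=np.arange(6.0))
        cache = BeatDistanceCache(bs)
        for metric in ("dtw", "xcorr"):
            M = cache.metric_matrix(metric)
            m_low, m_high = initial_medoids(bs, "lung_volume", metric, cache)
            low, high = [0, 1, 2], [3, 4, 5]
            assert m_low == low[np.argmin(M[np.ix_(low, low)].sum(axis=1))]
            assert m_high == high[np.argmin(M[np.ix_(high, high)].sum(axis=1))]

    def test_constant_covariate_degenerate(self, make_beatset):
        rng = np.random.default_rng(5)
        bs = make_beatset([_waveform(rng) for _ in range(4)], lv=np.ones(4))
        with pytest.raises(DegenerateSplitError):
            initial_medoids(bs, "lung_volume", "dtw")


def _two_template_beatset(make_beatset, n_per=4, noise=0.01, seed=6):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 50)
    ta = np.sin(2 * np.pi * 2 * t)
    tb = np.sign(np.sin(2 * np.pi * 2 * t)) * 0.5
    waves, truth = [], []
    for i in range(2 * n_per):
        base = ta if i % 2 == 0 else tb
        waves.append(base + noise * rng.standard_normal(len(t)))
        truth.append(i % 2)
    lv = [0.0 if g == 0 else 1.0 for g in truth]
    return make_beatset(waves, lv=lv), np.array(truth)


class TestKMedoids:
    def test_recovers_well_separated_templates(self, make_beatset):
        bs, truth = _two_template_beatset(make_beatset)
        cache = BeatDistanceCache(bs)
        init = initial_medoids(bs, "lung_volume", "dtw", cache)
        res = kmedoids_two(bs, init, cache)
        lab = res.labels == res.labels[0]
        assert np.all(lab == (truth == truth[0]))

    def test_identical_beats_converge_quickly(self, make_beatset):
        w = np.sin(np.linspace(0, 6, 40))
        bs = make_beatset([w.copy() for _ in range(6)], lv=np.arange(6.0))
        cache = BeatDistanceCache(bs)
        res = kmedoids_two(bs, (0, 3), cache)
        assert res.converged
        assert res.n_iterations <= 2
        assert wv_intra(cache, res) == 0.0

    def test_no_single_medoid_swap_improves(self, make_beatset):
        bs, _ = _two_template_beatset(make_beatset, noise=0.05, seed=8)
        cache = BeatDistanceCache(bs)
        D = cache.dtw_cost
        init = initial_medoids(bs, "lung_volume", "dtw", cache)
        res = kmedoids_two(bs, init, cache)

        def within_cost(m1, m2):
            return np.minimum(D[:, m1], D[:, m2]).sum()

        final = within_cost(res.medoid_1, res.medoid_2)
        n = len(bs)
        for alt in range(n):
            if alt != res.medoid_2:
                assert within_cost(alt, res.medoid_2) >= final - 1e-12
            if alt != res.medoid_1:
                assert within_cost(res.medoid_1, alt) >= final - 1e-12
        # on this well-separated set the local optimum is global
        best = min(
            within_cost(i, j) for i in range(n) for j in range(i + 1, n)
        )
        assert final == pytest.approx(best, abs=1e-12)

    def test_stable_when_rerun_from_own_output(self, make_beatset):
        bs, _ = _two_template_beatset(make_beatset, seed=9)
        cache = BeatDistanceCache(bs)
        res = kmedoids_two(bs, (0, 1), cache)
        res2 = kmedoids_two(bs, (res.medoid_1, res.medoid_2), cache)
        assert np.array_equal(res.labels, res2.labels)
        assert (res2.medoid_1, res2.medoid_2) == (res.medoid_1, res.medoid_2)


class TestSelectBest:
    def test_chosen_run_minimizes_wv_intra(self, make_beatset):
        bs, _ = _two_template_beatset(make_beatset, noise=0.05, seed=10)
        cache = BeatDistanceCache(bs)
        res = select_best_clustering(bs, cache)
        chosen = wv_intra(cache, res)
        finite = [v for v in res.audit.values() if np.isfinite(v)]
        assert chosen == pytest.approx(min(finite), abs=1e-12)
        assert res.init_basis in ("lung_volume", "flow_rate")
        assert res.init_metric in ("dtw", "xcorr")

    def test_label_swap_leaves_wv_features_unchanged(self, make_beatset):
        import dataclasses

        bs, _ = _two_template_beatset(make_beatset, noise=0.05, seed=11)
        cache = BeatDistanceCache(bs)
        res = select_best_clustering(bs, cache)
        swapped = dataclasses.replace(
            res,
            labels=np.where(res.labels == 1, 2, 1),
            medoid_1=res.medoid_2,
            medoid_2=res.medoid_1,
        )
        assert wv_inter(cache, res) == pytest.approx(wv_inter(cache, swapped))
        assert wv_intra(cache, res) == pytest.approx(wv_intra(cache, swapped))


class TestRepresentative:
    def test_identical_cluster_returns_the_beat(self):
        w = np.sin(np.linspace(0, 5, 30))
        rep = representative_beat([w.copy() for _ in range(5)], np.zeros(5))
        assert np.allclose(rep, w)

    def test_small_cluster_takes_single_nearest(self):
        rng = np.random.default_rng(12)
        waves = [np.sin(np.linspace(0, 5, 30)) + 0.1 * rng.standard_normal(30) for _ in range(6)]
        d = np.array([0.0, 1, 2, 3, 4, 5])
        rep = representative_beat(waves, d, frac=0.15)  # k = max(1, round(0.9)) = 1
        assert np.allclose(rep, waves[0])

    def test_average_closer_to_template_than_any_jittered_beat(self):
        rng = np.random.default_rng(13)
        t = np.linspace(0, 1, 60)
        template = np.sin(2 * np.pi * 3 * t)
        eps = [0.05 * rng.standard_normal(60) for _ in range(3)]
        waves = [template + e for e in eps] + [template - e for e in eps]
        d = np.ones(6)
        rep = representative_beat(waves, d, frac=1.0)
        d_rep = dtw_distance(rep, template).distance
        d_each = [dtw_distance(w, template).distance for w in waves]
        assert d_rep < min(d_each)


def test_cluster_space_plot_smoke(tmp_path, make_beatset):
    bs, truth = _two_template_beatset(make_beatset)
    lv = truth.astype(float)
    fr = 1.0 - truth.astype(float)
    bs2 = make_beatset([b.samples for b in bs.beats], lv=lv, fr=fr)
    labels = truth + 1
    out = tmp_path / "clusters.png"
    cluster_space_plot(bs2, labels, out)
    assert out.exists() and out.stat().st_size > 0


def test_estimator_interface(make_beatset):
    bs, truth = _two_template_beatset(make_beatset)
    km = BeatKMedoids()
    assert km.get_params()["init_basis"] == "auto"
    labels = km.set_params(max_iter=30).fit_predict(bs)
    assert set(labels) == {1, 2}
    assert km.medoid_indices_[0] != km.medoid_indices_[1]
    assert len(km.representatives_) == 2
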