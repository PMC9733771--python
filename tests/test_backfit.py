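"""Backfitting, temporal smoothing, per-state statistics, transitions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msfusion import backfit as bf
from msfusion import simulate as sim
from msfusion.config import SimConfig
from msfusion.containers import MsfusionError
from msfusion.microstates import MicrostateModel


def _model(protos):
    k = protos.shape[0]
    return MicrostateModel(prototypes=protos, k=k, gev_total=0.0,
                           gev_per_state=np.zeros(k), cv=0.0)


@pytest.fixture(scope="module")
def ortho_protos():
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.standard_normal((16, 6)))
    p = q.T[:6]
    p -= p.mean(axis=1, keepdims=True)
    return p / np.linalg.norm(p, axis=1, keepdims=True)


class TestTopoSimilarity:
    def test_identical_maps(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(16)
        corr, gmd = bf.topo_similarity(a, a)
        assert corr == pytest.approx(1.0)
        assert gmd == pytest.approx(0.0, abs=1e-9)

    def test_negated_map(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(16)
        a -= a.mean()
        corr, gmd = bf.topo_similarity(a, -a)
        assert corr == pytest.approx(-1.0)
        assert gmd == pytest.approx(2.0)

    def test_orthogonal_zero_mean_maps(self):
        a = np.array([1.0, -1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, -1.0])
        corr, gmd = bf.topo_similarity(a, b)
        assert corr == pytest.approx(0.0, abs=1e-12)
        assert gmd == pytest.approx(np.sqrt(2.0))

    @given(seed=st.integers(0, 1000))
    @settings(deadline=None, max_examples=30)
    def test_gmd_squared_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        corr, gmd = bf.topo_similarity(a, b)
        assert gmd ** 2 == pytest.approx(2.0 * (1.0 - corr), abs=1e-9)

    def test_zero_gfp_rejected(self):
        with pytest.raises(MsfusionError):
            bf.topo_similarity(np.ones(8), np.arange(8.0))


class TestBackfitLabels:
    def test_repeated_prototype_with_random_gains(self, ortho_protos):
        rng = np.random.default_rng(3)
        model = _model(ortho_protos)
        gains = rng.uniform(0.1, 3.0, 100) * rng.choice([-1, 1], 100)
        epoch = np.outer(ortho_protos[4], gains)
        seg = bf.backfit_labels(epoch, model)
        assert np.all(seg.labels == 4)

    def test_equidistant_tie_breaks_to_lower_index(self, ortho_protos):
        model = _model(ortho_protos)
        sample = ortho_protos[1] + ortho_protos[4]  # equal corr^2 with both
        seg = bf.backfit_labels(sample[:, None], model)
        assert seg.labels[0] == 1

    def test_brute_force_gmd_oracle(self, ortho_protos):
        rng = np.random.default_rng(4)
        model = _model(ortho_protos)
        epoch = rng.standard_normal((16, 120))
        seg = bf.backfit_labels(epoch, model)
        for t in range(120):
            gmds = []
            for k in range(6):
                corr, gmd = bf.topo_similarity(epoch[:, t],
                                               model.prototypes[k])
                _, gmd_neg = bf.topo_similarity(epoch[:, t],
                                                -model.prototypes[k])
                gmds.append(min(gmd, gmd_neg))
            assert seg.labels[t] == int(np.argmin(gmds))

    def test_sign_flip_and_scale_invariance(self, ortho_protos):
        rng = np.random.default_rng(5)
        model = _model(ortho_protos)
        epoch = rng.standard_normal((16, 50))
        a = bf.backfit_labels(epoch, model)
        b = bf.backfit_labels(-3.7 * epoch, model)
        assert np.array_equal(a.labels, b.labels)

    def test_channel_mismatch_rejected(self, ortho_protos):
        model = _model(ortho_protos)
        with pytest.raises(MsfusionError):
            bf.backfit_labels(np.zeros((8, 10)), model)


class TestTemporalSmooth:
    def _seg(self, labels, corr2=None, k=3, fs=250.0):
        labels = np.asarray(labels)
        if corr2 is None:
            corr2 = np.full((labels.size, k), 0.5)
            corr2[np.arange(labels.size), labels] = 0.9
        corr = np.sqrt(corr2)
        return bf.SegmentationResult(labels=labels, fs=fs, k=k, corr=corr)

    def test_short_segment_absorbed(self):
        fs = 250.0
        labels = np.concatenate([np.zeros(50), np.ones(2), np.zeros(50)])
        seg = self._seg(labels.astype(int), fs=fs)
        out = bf.temporal_smooth(seg, min_segment_ms=30.0)
        assert np.all(out.labels == 0)

    def test_no_short_segments_identity(self):
        labels = np.concatenate([np.zeros(100), np.ones(100)]).astype(int)
        seg = self._seg(labels)
        out = bf.temporal_smooth(seg, min_segment_ms=30.0)
        assert np.array_equal(out.labels, labels)

    def test_worst_case_alternation_terminates(self):
        # 4 ms segments alternating between three states
        labels = np.tile(np.repeat([0, 1, 2], 1), 300)
        rng = np.random.default_rng(6)
        corr2 = rng.uniform(0.1, 0.9, (labels.size, 3))
        seg = bf.SegmentationResult(labels=labels, fs=250.0, k=3,
                                    corr=np.sqrt(corr2))
        out = bf.temporal_smooth(seg, min_segment_ms=30.0)
        starts, labs = out.segments()
        lengths = np.diff(np.append(starts, labels.size))
        assert np.all(lengths >= int(0.030 * 250.0)) or len(labs) == 1

    def test_split_point_follows_similarity(self):
        # short middle segment between two different neighbours: samples
        # go to whichever side correlates better
        labels = np.array([0] * 50 + [2] * 4 + [1] * 50)
        corr2 = np.full((labels.size, 3), 0.1)
        corr2[:, 0] = 0.2
        corr2[:, 1] = 0.2
        corr2[50:52, 0] = 0.9   # first half prefers the left label
        corr2[52:54, 1] = 0.9   # second half prefers the right label
        seg = bf.SegmentationResult(labels=labels, fs=250.0, k=3,
                                    corr=np.sqrt(corr2))
        out = bf.temporal_smooth(seg, min_segment_ms=30.0)
        assert np.all(out.labels[50:52] == 0)
        assert np.all(out.labels[52:54] == 1)

    def test_longer_than_epoch_rejected(self):
        seg = self._seg(np.zeros(10, int))
        with pytest.raises(MsfusionError):
            bf.temporal_smooth(seg, min_segment_ms=1000.0)


class TestSegmentStats:
    def _seg(self, labels, k=3, fs=250.0):
        return bf.SegmentationResult(labels=np.asarray(labels, int), fs=fs,
                                     k=k)

    def test_single_state_epoch(self):
        seg = self._seg(np.zeros(2500))
        stats = bf.segment_stats(seg)
        t = stats.table
        assert t.loc[0, "occurrence"] == pytest.approx(0.1)
        assert t.loc[0, "duration_ms"] == pytest.approx(10000.0)
        assert t.loc[0, "coverage"] == pytest.approx(1.0)
        assert not t.loc[1, "present"]
        assert t.loc[1, "occurrence"] == 0.0
        assert np.isnan(t.loc[1, "mean_gfp"])

    def test_two_equal_segments(self):
        seg = self._seg([0] * 1250 + [1] * 1250)
        t = bf.segment_stats(seg).table
        for j in (0, 1):
            assert t.loc[j, "occurrence"] == pytest.approx(0.1)
            assert t.loc[j, "duration_ms"] == pytest.approx(5000.0)
            assert t.loc[j, "coverage"] == pytest.approx(0.5)

    def test_bookkeeping_identity(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, 5000)
        t = bf.segment_stats(self._seg(labels)).table
        # occurrence * duration == coverage * 1000 (ms/s), per state
        lhs = t["occurrence"] * t["duration_ms"]
        rhs = t["coverage"] * 1000.0
        assert np.allclose(lhs, rhs, rtol=1e-9)
        assert t["coverage"].sum() == pytest.approx(1.0)

    def test_map_metrics_on_known_epoch(self, ortho_protos):
        model = _model(ortho_protos)
        epoch = np.concatenate(
            [np.outer(ortho_protos[0], 2.0 * np.ones(100)),
             np.outer(ortho_protos[1], 3.0 * np.ones(100))], axis=1)
        seg = bf.backfit_labels(epoch, model)
        stats = bf.segment_stats([seg], [epoch], model)
        t = stats.table
        assert t.loc[0, "mean_spatial_corr"] == pytest.approx(1.0)
        assert t.loc[1, "mean_spatial_corr"] == pytest.approx(1.0)
        gfp0 = 2.0 / np.sqrt(16)
        assert t.loc[0, "mean_gfp"] == pytest.approx(gfp0 * np.sqrt(16) / 4)


class TestTransitionMatrix:
    def _seg(self, labels, k=3):
        return bf.SegmentationResult(labels=np.asarray(labels, int),
                                     fs=250.0, k=k)

    def test_alternating_sequence(self):
        seg = self._seg([0] * 10 + [1] * 10 + [0] * 10 + [1] * 10, k=2)
        tm = bf.transition_matrix(seg)
        assert tm.probs[0, 1] == 1.0
        assert tm.probs[1, 0] == 1.0
        assert np.all(np.diag(tm.probs) == 0)

    def test_monte_carlo_recovery(self):
        gen = np.array([[0.0, 0.7, 0.3], [0.5, 0.0, 0.5], [0.2, 0.8, 0.0]])
        rng = np.random.default_rng(8)
        labels = [0]
        for _ in range(10000):
            labels.append(rng.choice(3, p=gen[labels[-1]]))
        expanded = np.repeat(labels, 3)  # arbitrary segment lengths
        tm = bf.transition_matrix(self._seg(expanded))
        assert np.abs(tm.probs - gen).max() < 0.03

    def test_single_state_warns_zero_matrix(self):
        with pytest.warns(UserWarning, match="no transitions"):
            tm = bf.transition_matrix(self._seg(np.zeros(100)))
        assert np.all(tm.probs == 0)


class TestEndToEndRecovery:
    def test_duration_and_transitions_from_noisy_eeg(self, protos6):
        """Headline parameter recovery: backfit + smoothing on rendered
        EEG reproduces the generator's temporal structure. Discretization,
        backfit misassignment and the smoothing floor bias the duration
        estimate, so tolerances are wider than for the label-level
        Monte-Carlo checks."""
        from msfusion import eeg as eegmod

        cfg = SimConfig(trial_duration_s=120, n_trials=2, rest_duration_s=10,
                        seed=0)
        truth = sim.gen_state_sequence(cfg, 42, prototypes=protos6)
        eeg = sim.gen_eeg(truth, cfg, 43)
        clean, _ = eegmod.preprocess_eeg(eeg)
        model = _model(protos6)
        segs = []
        step = int(10 * clean.fs)
        for s in range(0, clean.n_samples - step, step):
            seg = bf.backfit_labels(clean.data[:, s:s + step], model,
                                    fs=clean.fs)
            segs.append(bf.temporal_smooth(seg, 30.0))
        stats = bf.segment_stats(segs)
        pooled = np.average(stats.duration_ms, weights=stats.occurrence)
        assert abs(pooled - 80.0) / 80.0 < 0.20
        tm = bf.transition_matrix(segs)
        assert np.abs(tm.probs - cfg.transition_matrix).max() < 0.06
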