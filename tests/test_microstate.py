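"""Segmentation stack: GFP, peak picking, AAHC, GEV/SSE, elbow, back-fit."""

import numpy as np
import pytest

from eegstc import microstate as ms
from eegstc import synthgen as sg


class TestGfp:
    def test_constant_topography_zero(self):
        assert ms.gfp(np.full((4, 3), 2.5)).max() == 0

    def test_two_channel_unit(self):
        assert ms.gfp(np.array([[1.0], [-1.0]]))[0] == pytest.approx(1.0)

    def test_four_channel_direct(self):
        val = ms.gfp(np.array([[2.0], [0.0], [-2.0], [0.0]]))[0]
        assert val == pytest.approx(np.sqrt(8 / 4))

    def test_single_channel_error(self):
        with pytest.raises(ValueError):
            ms.gfp(np.ones((1, 10)))


class TestGfpPeaks:
    def test_monotone_empty(self):
        assert ms.gfp_peaks(np.arange(10.0)).size == 0

    def test_alternating(self):
        assert list(ms.gfp_peaks(np.array([0, 1, 0, 1, 0.0]))) == [1, 3]

    def test_sinusoid_count(self):
        t = np.linspace(0, 5, 1000, endpoint=False)
        g = 1 + np.sin(2 * np.pi * t)  # 5 cycles
        assert ms.gfp_peaks(g).size == 5


def orthogonal_templates(n_ch, K, seed=0):
    """Exactly orthonormal zero-mean maps (rotated Helmert basis)."""
    from scipy.linalg import helmert

    rng = np.random.default_rng(seed)
    basis = helmert(n_ch)  # (n_ch-1, n_ch), orthonormal zero-sum rows
    q, _ = np.linalg.qr(rng.standard_normal((n_ch - 1, n_ch - 1)))
    return (q @ basis)[:K]


class TestAahc:
    def test_separable_clusters_recovered(self):
        maps3 = orthogonal_templates(16, 3)
        rng = np.random.default_rng(0)
        amps = rng.uniform(0.5, 2, 120)  # amplitude independent of identity
        data = np.repeat(maps3, 40, axis=0) * amps[:, None]
        sets = ms.aahc_cluster(data, k_range=[3])
        c = np.abs(ms.spatial_correlation(sets[3].maps, maps3))
        assert np.allclose(c.max(axis=1), 1.0, atol=1e-6)

    def test_polarity_invariance(self, rng):
        maps3 = orthogonal_templates(16, 3, seed=2)
        data = np.repeat(maps3, 30, axis=0) + 0.05 * rng.standard_normal((90, 16))
        flipped = data.copy()
        flipped[::2] *= -1
        a = ms.aahc_cluster(data, k_range=[3])[3]
        b = ms.aahc_cluster(flipped, k_range=[3])[3]
        c = np.abs(ms.spatial_correlation(a.maps, b.maps))
        assert np.allclose(np.sort(c.max(axis=1)), 1.0, atol=1e-10)

    def test_noisy_recovery_20db(self):
        cfg = sg.SynthConfig(n_channels=30, K=5, duration=30.0, snr_db=20, seed=4)
        tpl = sg.generate_templates(30, 5, seed=4)
        rec = sg.generate_eeg(tpl, sg.generate_label_sequence(cfg), cfg)
        g = ms.gfp(rec.data)
        pk = ms.gfp_peaks(g)
        sets = ms.aahc_cluster(rec.data[:, pk].T, k_range=[5], gfp_values=g[pk])
        c = np.abs(ms.spatial_correlation(sets[5].maps, tpl.maps))
        assert c.max(axis=1).mean() >= 0.9

    def test_input_order_stability(self, rng):
        cfg = sg.SynthConfig(n_channels=20, K=4, duration=10.0, snr_db=20, seed=6)
        tpl = sg.generate_templates(20, 4, seed=6)
        rec = sg.generate_eeg(tpl, sg.generate_label_sequence(cfg), cfg)
        g = ms.gfp(rec.data)
        pk = ms.gfp_peaks(g)
        maps, w = rec.data[:, pk].T, g[pk]
        perm = rng.permutation(len(w))
        a = ms.aahc_cluster(maps, k_range=[4], gfp_values=w)[4]
        b = ms.aahc_cluster(maps[perm], k_range=[4], gfp_values=w[perm])[4]
        assert abs(a.gev_total - b.gev_total) < 0.01

    def test_too_few_maps(self):
        with pytest.raises(ValueError):
            ms.aahc_cluster(np.random.default_rng(0).standard_normal((3, 8)), k_range=[5])


class TestGev:
    def test_exact_match_is_one(self):
        maps = orthogonal_templates(10, 4)
        total, per = ms.gev(maps, maps, np.ones(4), assignment=np.arange(4))
        assert total == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        maps = orthogonal_templates(10, 4)
        # assign each map to a template it is orthogonal to
        total, _ = ms.gev(maps, maps, np.ones(4), assignment=(np.arange(4) + 1) % 4)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_half_and_half(self):
        maps = orthogonal_templates(10, 2)
        data = np.vstack([maps[0], maps[0]])
        total, _ = ms.gev(maps, data, np.ones(2), assignment=np.array([0, 1]))
        assert total == pytest.approx(0.5)

    def test_zero_gfp_error(self):
        maps = orthogonal_templates(10, 2)
        with pytest.raises(ValueError):
            ms.gev(maps, maps[:1], np.zeros(1))


class TestSse:
    def test_exact_templates_zero(self):
        maps = orthogonal_templates(12, 3)
        data = np.repeat(maps, 5, axis=0) * 2.7
        assert ms.sse(maps, data) == pytest.approx(0.0, abs=1e-20)

    def test_nesting_non_increasing(self, rng):
        data = rng.standard_normal((200, 12))
        sets = ms.aahc_cluster(data, k_range=range(1, 7))
        sses = [sets[k].sse for k in range(1, 7)]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_hand_computed_case(self):
        t = np.array([[1.0, -1.0]]) / np.sqrt(2)
        data = np.array([[2.0, 0.0], [0.0, 3.0]])
        # brute force: center, project on t, residual
        expected = 0.0
        for x in data:
            xc = x - x.mean()
            a = xc @ t[0]
            expected += np.sum((xc - a * t[0]) ** 2)
        assert ms.sse(t, data) == pytest.approx(expected)


class TestElbow:
    def test_recovers_true_k_noiseless(self):
        maps5 = orthogonal_templates(20, 5)
        rng = np.random.default_rng(1)
        data = maps5[rng.integers(0, 5, 400)] * rng.uniform(0.5, 2, 400)[:, None]
        sets = ms.aahc_cluster(data, k_range=range(1, 11))
        k = ms.select_k_elbow({k: s.sse for k, s in sets.items()},
                              {k: s.gev_total for k, s in sets.items()})
        assert k == 5

    def test_two_template_recovery(self):
        maps2 = orthogonal_templates(20, 2)
        rng = np.random.default_rng(2)
        data = maps2[rng.integers(0, 2, 300)] + 0.05 * rng.standard_normal((300, 20))
        sets = ms.aahc_cluster(data, k_range=range(1, 8))
        k = ms.select_k_elbow({k: s.sse for k, s in sets.items()},
                              {k: s.gev_total for k, s in sets.items()})
        assert k == 2

    def test_linear_decay_falls_back(self):
        sse = {k: 100.0 - 10 * k for k in range(1, 8)}
        gev = {k: 0.5 + 0.05 * k for k in range(1, 8)}
        with pytest.warns(UserWarning, match="no elbow"):
            k = ms.select_k_elbow(sse, gev, gev_threshold=0.65)
        assert k == 3  # smallest K with GEV >= 0.65

    def test_threshold_unmet_error_lists_gevs(self):
        sse = {k: 1.0 / k for k in range(1, 5)}
        gev = {k: 0.1 * k for k in range(1, 5)}
        with pytest.raises(ValueError, match="attained"):
            ms.select_k_elbow(sse, gev, gev_threshold=0.65)


class TestBackfit:
    def test_noiseless_exact(self):
        maps = orthogonal_templates(14, 4)
        labels = np.array([1, 2, 3, 4, 2, 2, 1], dtype=np.int64)
        data = (maps[labels - 1] * 1.3).T
        seq = ms.backfit(maps, data, fs=100.0)
        assert np.array_equal(seq.labels, labels)

    def test_polarity_invariance(self):
        maps = orthogonal_templates(14, 4)
        labels = np.array([1, 2, 3, 4, 2], dtype=np.int64)
        data = (maps[labels - 1]).T
        a = ms.backfit(maps, data, fs=100.0)
        b = ms.backfit(maps, -data, fs=100.0)
        assert np.array_equal(a.labels, b.labels)

    def test_zero_variance_inherits_previous(self):
        maps = orthogonal_templates(14, 3)
        data = np.vstack([maps[1], np.zeros(14), np.zeros(14)]).T
        seq = ms.backfit(maps, data, fs=100.0)
        assert list(seq.labels) == [2, 2, 2]

    def test_zero_variance_first_sample_label_one(self):
        maps = orthogonal_templates(14, 3)
        data = np.vstack([np.zeros(14), maps[2]]).T
        seq = ms.backfit(maps, data, fs=100.0)
        assert list(seq.labels) == [1, 3]

    def test_channel_mismatch(self):
        maps = orthogonal_templates(14, 3)
        with pytest.raises(ValueError, match="channel"):
            ms.backfit(maps, np.zeros((10, 5)), fs=100.0)


class TestParams:
    def test_hand_counted_example(self):
        seq = ms.LabelSequence(np.array([1, 1, 2, 2, 2]), fs=5.0, K=2)
        p = ms.microstate_params(seq)
        np.testing.assert_allclose(p.coverage, [0.4, 0.6])
        np.testing.assert_allclose(p.mean_duration_ms, [400.0, 600.0])
        np.testing.assert_allclose(p.occurrence, [1.0, 1.0])
        assert p.transition_matrix[0, 1] == 1.0

    def test_constant_sequence(self):
        seq = ms.LabelSequence(np.ones(100, dtype=int), fs=250.0, K=3)
        p = ms.microstate_params(seq)
        assert p.coverage[0] == 1.0
        assert p.occurrence[0] == pytest.approx(2.5)  # one run in 0.4 s
        assert p.transition_matrix.sum() == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_coverage_partition(self, seed):
        rng = np.random.default_rng(seed)
        seq = ms.LabelSequence(rng.integers(1, 6, 500), fs=250.0, K=5)
        p = ms.microstate_params(seq)
        assert p.coverage.sum() == pytest.approx(1.0, abs=1e-10)


class TestPipelineRecovery:
    def test_dwell_time_recovered_within_10pct(self):
        cfg = sg.SynthConfig(n_channels=24, K=4, fs=250.0, duration=40.0,
                             snr_db=20, seed=8)  # 1e4 samples, ~80 ms dwell
        tpl = sg.generate_templates(24, 4, seed=8)
        seq_true = sg.generate_label_sequence(cfg)
        rec = sg.generate_eeg(tpl, seq_true, cfg)
        fitted = ms.backfit(tpl, rec.data, fs=cfg.fs)
        p = ms.microstate_params(fitted)
        mean_dwell = np.nanmean(p.mean_duration_ms)
        assert abs(mean_dwell - 80.0) / 80.0 < 0.10

    def test_selected_templateset_meets_gev_threshold(self):
        cfg = sg.SynthConfig(n_channels=30, K=5, duration=60.0, snr_db=20, seed=13)
        tpl = sg.generate_templates(30, 5, seed=13)
        rec = sg.generate_eeg(tpl, sg.generate_label_sequence(cfg), cfg)
        chosen, k, _ = ms.fit_microstates(rec.data, rec.fs, max_maps=1500)
        assert chosen.gev_total >= 0.65
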