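"""Signal-analysis chain: LFP construction, band power, PLV, event
detection, correlations and regime clustering."""

import numpy as np
import pytest

from tcsleep.analysis import (LfpSeries, SpectralFeatureTable, band_power,
                              band_power_windows, cluster_states, compute_lfp,
                              detect_events, feature_table, load_lfp_text,
                              mean_pairwise_plv, plv, project_clusters,
                              spindle_delta_correlation)

FS = 1000.0


def _sine(freq, dur_s, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestComputeLfp:
    def test_constant_voltages_give_constant_lfp(self):
        v = np.full((1000, 20), -65.0)
        lfp = compute_lfp(v, FS, "all")
        assert np.allclose(lfp.channel(0), -65.0)

    def test_grouping_five_channels_from_five_hundred_cells(self):
        v = np.zeros((100, 500))
        lfp = compute_lfp(v, FS, 100)
        assert lfp.n_channels == 5

    def test_linearity_of_the_average(self):
        x = np.random.default_rng(0).normal(size=(200, 2))
        v = np.column_stack([x[:, 0], -x[:, 0]])
        lfp = compute_lfp(v, FS, 1)
        assert np.allclose(lfp.channel(0), v[:, 0])
        assert np.allclose(lfp.channel(1), -v[:, 0])
        assert np.allclose(compute_lfp(v, FS, "all").channel(0), 0.0)

    def test_remainder_rule_last_group_smaller(self):
        v = np.zeros((10, 7))
        lfp = compute_lfp(v, FS, 3)
        assert lfp.n_channels == 3   # 3 + 3 + 1

    def test_text_round_trip(self, tmp_path):
        t = np.arange(500) / FS
        data = np.column_stack([t, _sine(5, 0.5), _sine(9, 0.5)])
        path = tmp_path / "lfp.txt"
        np.savetxt(path, data)
        lfp = load_lfp_text(path)
        assert lfp.fs == pytest.approx(FS, rel=1e-3)
        assert lfp.n_channels == 2


class TestBandPower:
    def test_pure_sinusoid_concentrates_in_its_band(self):
        x = _sine(10.0, 10.0)
        spindle = band_power(x, FS, (7, 15))
        delta = band_power(x, FS, (0.5, 4))
        assert spindle / max(delta, 1e-30) > 100.0

    def test_dc_signal_has_no_spindle_power(self):
        assert band_power(np.full(5000, 3.0), FS, (7, 15)) == \
            pytest.approx(0.0, abs=1e-20)

    def test_parseval_partition_with_rectangular_window(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4096)
        edges = [0.0, 4.0, 15.0, 100.0, 500.0]
        total = sum(band_power(x, FS, (a, b), window="rect")
                    for a, b in zip(edges[:-1], edges[1:]))
        assert total == pytest.approx(np.var(x), rel=1e-2)

    def test_white_noise_fills_equal_bands_equally(self):
        rng = np.random.default_rng(2)
        p1 = p2 = 0.0
        for _ in range(30):
            x = rng.normal(size=2000)
            p1 += band_power(x, FS, (50, 100))
            p2 += band_power(x, FS, (200, 250))
        assert p1 / p2 == pytest.approx(1.0, abs=0.1)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            band_power(_sine(5, 1.0), FS, (15, 7))
        with pytest.raises(ValueError):
            band_power(_sine(5, 1.0), FS, (10, 9999.0))

    def test_windowed_power_follows_amplitude_modulation(self):
        x = np.r_[_sine(10, 2.0, amp=0.1), _sine(10, 2.0, amp=2.0)]
        t, p = band_power_windows(x, FS, (7, 15), window_s=2.0)
        assert p[1] / p[0] > 100.0

    def test_offset_invariance(self):
        x = _sine(10.0, 4.0)
        assert band_power(x + 55.0, FS, (7, 15)) == \
            pytest.approx(band_power(x, FS, (7, 15)), rel=1e-6)


class TestPlv:
    def test_identical_channels_are_perfectly_locked(self):
        x = _sine(8.0, 5.0) + 0.1 * np.random.default_rng(0).normal(size=5000)
        assert plv(x, x, FS) == pytest.approx(1.0)

    def test_constant_phase_shift_is_still_locked(self):
        a = _sine(8.0, 5.0)
        b = _sine(8.0, 5.0, phase=1.2)
        assert plv(a, b, FS) > 0.99

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=100000), rng.normal(size=100000)
        assert plv(a, b, FS) < 0.1

    def test_zero_variance_channel_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(1000), _sine(8, 1.0), FS)

    def test_mean_pairwise_over_channels(self):
        x = _sine(8.0, 5.0)
        lfp = LfpSeries(fs=FS, data=np.column_stack([x, x, x]))
        assert mean_pairwise_plv(lfp) == pytest.approx(1.0)


class TestDetectEvents:
    def test_synthetic_spindle_burst_recovered(self, rng):
        noise = 0.25 * rng.normal(size=20000)
        burst = np.zeros(20000)
        i0, i1 = 9000, 10500        # 1.5 s burst at 10 Hz
        burst[i0:i1] = _sine(10.0, 1.5)
        eps = detect_events(noise + burst, FS, kind="spindle")
        assert len(eps) == 1
        # the dual-threshold boundary rule plus envelope smoothing widen
        # the detection by a few hundred ms on either side
        assert eps[0].duration_s == pytest.approx(2.0, abs=0.55)
        assert eps[0].onset_s == pytest.approx(8.8, abs=0.4)
        assert 8.0 < eps[0].peak_freq_hz < 12.0

    def test_amplitude_rescaling_preserves_detections(self, rng):
        x = 0.05 * rng.normal(size=20000)
        x[5000:7000] += _sine(11.0, 2.0)
        n1 = len(detect_events(x, FS, kind="spindle"))
        n2 = len(detect_events(7.3 * x, FS, kind="spindle"))
        assert n1 == n2 == 1

    def test_slow_alternation_detected_as_slow_oscillation(self):
        from scipy import signal as sps
        t = np.arange(30000) / FS
        x = sps.square(2 * np.pi * 0.8 * t) * 3.0
        eps = detect_events(x, FS, kind="slow_oscillation")
        assert len(eps) >= 1
        freqs = [e.peak_freq_hz for e in eps]
        assert 0.4 < np.median(freqs) < 1.4

    def test_flat_signal_yields_no_events(self):
        assert detect_events(np.zeros(5000), FS, kind="spindle") == []
        assert detect_events(np.zeros(5000), FS,
                             kind="slow_oscillation") == []

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.zeros(100), 50.0, kind="spindle")


class TestCorrelation:
    def _table(self, sp, de):
        import pandas as pd
        return pd.DataFrame(dict(spindle_power=sp, delta_power=de))

    def test_equal_powers_give_unit_correlation(self):
        x = np.linspace(1, 10, 50)
        r, p = spindle_delta_correlation(self._table(x, x))
        assert r == pytest.approx(1.0)

    def test_anticorrelated_powers(self):
        x = np.linspace(1, 10, 50)
        r, _ = spindle_delta_correlation(self._table(x, -x + 20))
        assert r == pytest.approx(-1.0)

    def test_bivariate_normal_recovers_rho(self, rng):
        rho, n = 0.4, 500
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        r, p = spindle_delta_correlation(
            self._table(xy[:, 0] + 5, xy[:, 1] + 5))
        assert 0.32 < r < 0.47    # sampling band for rho=0.4, n=500
        assert p < 1e-6

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            spindle_delta_correlation(self._table([1, 2], [1, 2]))


def _blob_table(rng, centers, n_each, scale=0.05):
    import pandas as pd
    rows = []
    for cx, cy, cz in centers:
        sp = 10.0 ** (cx + scale * rng.normal(size=n_each))
        de = 10.0 ** (cy + scale * rng.normal(size=n_each))
        pl = np.clip(cz + scale * rng.normal(size=n_each), 0, 1)
        rows.append(np.column_stack([sp, de, pl]))
    arr = np.vstack(rows)
    return pd.DataFrame(dict(spindle_power=arr[:, 0], delta_power=arr[:, 1],
                             plv=arr[:, 2]))


class TestClustering:
    def test_three_separated_blobs_recovered(self, rng):
        tbl = _blob_table(rng, [(0.0, 0.0, 0.2), (2.0, 0.0, 0.5),
                                (0.0, 2.0, 0.8)], 300)
        model = cluster_states(tbl, max_components=6, seed=0)
        assert model.n_components == 3

    def test_single_gaussian_selects_one_component(self, rng):
        tbl = _blob_table(rng, [(1.0, 1.0, 0.5)], 1000)
        model = cluster_states(tbl, max_components=6, seed=0)
        assert model.n_components == 1

    def test_identical_seed_gives_identical_model(self, rng):
        tbl = _blob_table(rng, [(0, 0, 0.2), (2, 1, 0.7)], 200)
        m1 = cluster_states(tbl, seed=3)
        m2 = cluster_states(tbl, seed=3)
        assert m1.n_components == m2.n_components
        assert np.array_equal(m1.assignments, m2.assignments)
        assert np.allclose(m1.means, m2.means)

    def test_weights_sum_to_one_and_aic_has_full_length(self, rng):
        tbl = _blob_table(rng, [(0, 0, 0.2), (2, 1, 0.7)], 150)
        m = cluster_states(tbl, max_components=5, seed=0)
        assert np.sum(m.weights) == pytest.approx(1.0)
        assert len(m.aic) == 5


class TestProjection:
    def test_point_cluster_gives_zero_volume(self, rng):
        tbl = _blob_table(rng, [(0, 0, 0.2)], 50, scale=1e-3)
        model = cluster_states(tbl, max_components=2, seed=0)
        coords = np.tile([80.0, 40.0, 115.0], (50, 1))
        ell = project_clusters(model, coords)
        k = model.assignments[0]
        assert not ell[k]["degenerate"]
        assert np.allclose(ell[k]["center"], [80, 40, 115])
        assert np.all(ell[k]["axes"] < 1e-9)

    def test_grid_cloud_gives_axis_aligned_ellipsoid(self, rng):
        tbl = _blob_table(rng, [(0, 0, 0.5)], 125, scale=1e-3)
        model = cluster_states(tbl, max_components=1, seed=0)
        g = np.array(np.meshgrid([0, 10, 20], [0, 5, 10],
                                 [0, 1, 2])).reshape(3, -1).T
        coords = np.vstack([g] * 5)[:125]
        ell = project_clusters(model, coords)[0]
        assert np.allclose(ell["center"], coords.mean(axis=0))
        # eigenvectors close to the coordinate axes
        d = np.abs(ell["directions"])
        assert np.allclose(np.sort(d.max(axis=0)), [1, 1, 1], atol=1e-6)

    def test_small_cluster_flagged_degenerate(self, rng):
        tbl = _blob_table(rng, [(0, 0, 0.2), (3, 3, 0.9)], 3)
        model = cluster_states(tbl, max_components=2, seed=0)
        coords = rng.normal(size=(6, 3))
        ell = project_clusters(model, coords)
        assert any(v["degenerate"] for v in ell.values())

    def test_coordinate_mismatch_rejected(self, rng):
        tbl = _blob_table(rng, [(0, 0, 0.2)], 10)
        model = cluster_states(tbl, max_components=1, seed=0)
        with pytest.raises(ValueError):
            project_clusters(model, np.zeros((5, 3)))


class TestFeatureTable:
    def test_windowing_and_columns(self):
        x = np.column_stack([_sine(10, 8.0), _sine(10, 8.0)])
        lfp = LfpSeries(fs=FS, data=x)
        tbl = feature_table(lfp, window_s=2.0)
        assert len(tbl.frame) == 4
        assert set(SpectralFeatureTable.REQUIRED) <= set(tbl.frame.columns)
        assert (tbl.frame["spindle_power"] > tbl.frame["delta_power"]).all()
        assert np.all(tbl.frame["plv"] > 0.99)

    def test_text_round_trip(self, tmp_path):
        lfp = LfpSeries(fs=FS, data=_sine(10, 4.0)[:, None])
        tbl = feature_table(lfp, window_s=2.0)
        path = tmp_path / "features.tsv"
        tbl.to_text(path)
        back = SpectralFeatureTable.from_text(path)
        assert np.allclose(back.frame["spindle_power"],
                           tbl.frame["spindle_power"])

    def test_negative_power_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            SpectralFeatureTable(frame=pd.DataFrame(dict(
                t_start=[0], t_end=[2], delta_power=[-1.0],
                spindle_power=[1.0], plv=[0.5])))
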