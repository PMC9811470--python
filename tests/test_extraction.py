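import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rampscope.extraction import (
    Component,
    FluorMovie,
    QCThresholds,
    compute_dff,
    detect_events,
    event_phase_stats,
    extract_trace_mli,
    extract_trace_pc,
    pca_ica,
    qc_components,
    spatial_downsample,
)
from rampscope.simulate import (
    SimConfig,
    kernel_peak_factor,
    make_background,
    make_population,
    render_movie,
    spikes_to_fluorescence,
)

FR = 30.0


def _movie(frames):
    return FluorMovie(frames=np.asarray(frames, dtype=float), frame_rate=FR)


class TestDownsample:
    def test_constant_block_pools_to_same_value(self):
        m = _movie(np.full((3, 4, 4), 7.0))
        out = spatial_downsample(m, 4)
        assert out.frames.shape == (3, 1, 1)
        assert np.allclose(out.frames, 7.0)
        assert out.pixel_size == pytest.approx(4 * m.pixel_size)

    def test_checkerboard_pools_to_half(self):
        board = np.indices((2, 2)).sum(axis=0) % 2
        m = _movie(board[None].astype(float))
        assert np.allclose(spatial_downsample(m, 2).frames, 0.5)

    def test_shape_contract(self):
        m = _movie(np.zeros((5, 8, 8)))
        assert spatial_downsample(m, 4).frames.shape == (5, 2, 2)

    def test_trailing_edge_cropped(self):
        m = _movie(np.zeros((2, 9, 10)))
        assert spatial_downsample(m, 4).frames.shape == (2, 2, 2)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            spatial_downsample(_movie(np.zeros((2, 4, 4))), 0)


class TestDff:
    def test_constant_movie_gives_zeros(self):
        dff = compute_dff(_movie(np.full((4, 2, 2), 3.0)))
        assert np.allclose(dff.values, 0.0)
        assert dff.valid.all()

    def test_single_pixel_series_oracle(self):
        """Pixel [1,1,1,3]: F0=1.5, dff=[-1/3,-1/3,-1/3,1]."""
        frames = np.array([1.0, 1.0, 1.0, 3.0]).reshape(4, 1, 1)
        dff = compute_dff(_movie(frames))
        assert dff.f0[0, 0] == pytest.approx(1.5)
        assert np.allclose(dff.values[:, 0, 0], [-1 / 3, -1 / 3, -1 / 3, 1.0])

    def test_zero_baseline_pixel_masked(self):
        frames = np.zeros((4, 1, 2))
        frames[:, 0, 1] = [1, 2, 3, 4]
        dff = compute_dff(_movie(frames))
        assert not dff.valid[0, 0] and dff.valid[0, 1]
        assert np.all(dff.values[:, 0, 0] == 0)

    def test_round_trip_reconstruction(self, rng):
        frames = rng.uniform(10, 100, size=(20, 6, 6))
        dff = compute_dff(_movie(frames))
        recon = dff.f0[None] * (1.0 + dff.values)
        assert np.allclose(recon, frames, rtol=1e-6)


@pytest.fixture(scope="module")
def planted_movie():
    """Three disjoint planted sources on a vessel-shadowed background."""
    rng = np.random.default_rng(8)
    T = 800
    cfg = SimConfig(noise_sd=0.0, transient_amplitude=1.0)
    pop = make_population({"uphill": 3}, frame_shape=(48, 48), seed=8,
                          min_separation_px=16, margin_px=8)
    traces = []
    for i in range(3):
        st = np.sort(rng.uniform(1, T / FR - 2, 12))
        _, clean = spikes_to_fluorescence(st, T, cfg, seed=i)
        traces.append(clean)
    traces = np.asarray(traces)
    movie, vessel, fps = render_movie(pop, traces, seed=9, pixel_noise_sd=1.5)
    return movie, vessel, fps, traces, pop


class TestPcaIca:
    def test_recovers_planted_sources(self, planted_movie):
        movie, vessel, fps, traces, pop = planted_movie
        dff = compute_dff(movie)
        comps = pca_ica(dff, n_ics=5, seed=0)
        for i in range(3):
            rs = [np.corrcoef(c.spatial_filter.ravel(), fps[i].ravel())[0, 1]
                  for c in comps]
            best = comps[int(np.argmax(rs))]
            assert max(rs) > 0.9
            rt = np.corrcoef(best.temporal_signal, traces[i])[0, 1]
            assert rt > 0.9

    def test_white_noise_components_have_low_skewness(self):
        rng = np.random.default_rng(3)
        frames = 100.0 + rng.normal(0, 1.0, size=(400, 24, 24))
        dff = compute_dff(_movie(frames))
        comps = pca_ica(dff, n_ics=5, seed=1)
        assert all(c.skewness < 1.0 for c in comps)
        qc_components(comps, None, dff.pixel_size)
        assert not any(c.accepted for c in comps)

    def test_deterministic_under_fixed_seed(self, planted_movie):
        movie = planted_movie[0]
        dff = compute_dff(movie)
        a = pca_ica(dff, n_ics=4, seed=7)
        b = pca_ica(dff, n_ics=4, seed=7)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.spatial_filter, cb.spatial_filter)
            assert np.array_equal(ca.temporal_signal, cb.temporal_signal)

    def test_sign_convention_temporal_skewness_nonnegative(self, planted_movie):
        dff = compute_dff(planted_movie[0])
        comps = pca_ica(dff, n_ics=5, seed=0)
        assert all(c.skewness >= 0 for c in comps)

    def test_too_many_ics_rejected(self, planted_movie):
        dff = compute_dff(planted_movie[0])
        with pytest.raises(ValueError):
            pca_ica(dff, n_ics=10, n_pcs=5, seed=0)


def _component_from_filter(filt, signal=None, skewness=2.0):
    T = 50
    sig = np.zeros(T) if signal is None else signal
    return Component(spatial_filter=filt, temporal_signal=sig, skewness=skewness)


class TestQc:
    def _round_filter(self, shape=(32, 32), center=(16, 16), sigma=2.0):
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        return np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                      / (2 * sigma**2))

    def test_low_skewness_rejected(self):
        comp = _component_from_filter(self._round_filter(), skewness=0.5)
        qc_components([comp], None, pixel_size=1.3)
        assert not comp.accepted and comp.cell_class == "artifact"

    def test_small_round_footprint_is_mli(self):
        comp = _component_from_filter(self._round_filter(sigma=2.0))
        qc_components([comp], None, pixel_size=1.3)
        assert comp.cell_class == "MLI" and comp.accepted
        assert 3.0 < comp.equivalent_diameter_um < 12.0

    def test_large_footprint_is_pc_and_rejected_from_mli_set(self):
        comp = _component_from_filter(self._round_filter(sigma=7.0))
        qc_components([comp], None, pixel_size=1.3)
        assert comp.cell_class == "PC" and not comp.accepted

    def test_striped_footprint_is_pc(self):
        rr, cc = np.mgrid[0:32, 0:32].astype(float)
        stripe = np.exp(-((rr - 16) ** 2) / (2 * 1.0**2)
                        - ((cc - 16) ** 2) / (2 * 8.0**2))
        comp = _component_from_filter(stripe)
        qc_components([comp], None, pixel_size=1.3)
        assert comp.cell_class == "PC"

    def test_vessel_overlap_rejected(self):
        filt = self._round_filter()
        vessel = np.zeros((32, 32), dtype=bool)
        vessel[10:22, 10:22] = True
        comp = _component_from_filter(filt)
        qc_components([comp], vessel, pixel_size=1.3)
        assert comp.cell_class == "artifact"
        assert comp.vessel_overlap > 0.5


class TestTraceExtraction:
    def test_mli_trace_matches_planted_source(self, planted_movie):
        movie, vessel, fps, traces, pop = planted_movie
        dff = compute_dff(movie)
        comps = pca_ica(dff, n_ics=5, seed=0)
        qc_components(comps, vessel, dff.pixel_size)
        for i in range(3):
            rs = [np.corrcoef(c.spatial_filter.ravel(), fps[i].ravel())[0, 1]
                  for c in comps]
            tr = extract_trace_mli(dff, comps[int(np.argmax(rs))])
            assert np.corrcoef(tr, traces[i])[0, 1] > 0.99

    def test_uniform_frame_offset_cancels(self, planted_movie):
        movie = planted_movie[0]
        dff = compute_dff(movie)
        comps = pca_ica(dff, n_ics=4, seed=0)
        base = extract_trace_mli(dff, comps[0])
        shifted = compute_dff(movie)
        shifted.values = shifted.values + 0.37  # spatially uniform offset
        off = extract_trace_mli(shifted, comps[0])
        assert np.allclose(base, off, atol=1e-9)

    def test_window_centered_on_unique_maximum(self):
        filt = np.zeros((16, 16))
        filt[5, 9] = 1.0
        vals = np.zeros((3, 16, 16))
        vals[:, 4:7, 8:11] = 2.0
        dff = compute_dff(_movie(np.full((3, 16, 16), 1.0)))
        dff.values = vals
        tr = extract_trace_mli(dff, _component_from_filter(filt))
        assert np.allclose(tr, 2.0)  # background median is 0

    def test_pc_trace_matches_planted_striped_source(self):
        rng = np.random.default_rng(4)
        T = 400
        cfg = SimConfig(noise_sd=0.0)
        pop = make_population({"pc_like": 1}, frame_shape=(48, 48), seed=5)
        st = np.sort(rng.uniform(1, T / FR - 2, 10))
        _, clean = spikes_to_fluorescence(st, T, cfg, seed=0)
        movie, _, fps = render_movie(pop, clean[None], seed=1, pixel_noise_sd=0.5)
        dff = compute_dff(movie)
        comps = pca_ica(dff, n_ics=2, seed=0)
        rs = [np.corrcoef(c.spatial_filter.ravel(), fps[0].ravel())[0, 1]
              for c in comps]
        tr = extract_trace_pc(dff, comps[int(np.argmax(rs))])
        assert np.corrcoef(tr, clean)[0, 1] > 0.99

    def test_pc_trace_scale_invariant(self, planted_movie):
        dff = compute_dff(planted_movie[0])
        comps = pca_ica(dff, n_ics=4, seed=0)
        comp = comps[0]
        doubled = Component(spatial_filter=2.0 * comp.spatial_filter,
                            temporal_signal=comp.temporal_signal,
                            skewness=comp.skewness)
        assert np.allclose(extract_trace_pc(dff, comp),
                           extract_trace_pc(dff, doubled), atol=1e-9)

    def test_uniform_filter_degenerate(self):
        dff = compute_dff(_movie(np.full((4, 8, 8), 2.0)))
        comp = _component_from_filter(np.full((8, 8), 1.0))
        with pytest.raises(ValueError, match="degenerate"):
            extract_trace_pc(dff, comp)


class TestDetectEvents:
    def test_single_noiseless_transient_timing(self):
        cfg = SimConfig(noise_sd=0.0,
                        transient_amplitude=1 / kernel_peak_factor(0.1, 1.0))
        _, clean = spikes_to_fluorescence(np.array([5.0]), 600, cfg)
        bl = np.zeros(600, dtype=bool)
        bl[:120] = True
        ev = detect_events(clean, FR, baseline_frames=bl)
        assert len(ev) == 1
        assert abs(ev.rise_start_frame.iloc[0] - 5.0 * FR) <= 1
        assert ev.rise_end_frame.iloc[0] == int(np.argmax(clean))

    def test_flat_trace_has_no_events(self):
        ev = detect_events(np.zeros(500), FR)
        assert len(ev) == 0

    def test_subthreshold_peak_gated_out(self, rng):
        """A transient peaking at 2x the baseline SD fails the 3-SD gate."""
        noise = rng.normal(0, 0.1, size=900)
        cfg = SimConfig(noise_sd=0.0,
                        transient_amplitude=0.2 / kernel_peak_factor(0.1, 1.0))
        _, clean = spikes_to_fluorescence(np.array([20.0]), 900, cfg)
        bl = np.zeros(900, dtype=bool)
        bl[:300] = True
        ev = detect_events(clean + noise, FR, baseline_frames=bl)
        starts = ev.rise_start_frame.to_numpy()
        assert not np.any(np.abs(starts - 600) <= 5)

    def test_event_count_monotone_in_amplitude_threshold(self, rng):
        cfg = SimConfig(noise_sd=0.1,
                        transient_amplitude=1 / kernel_peak_factor(0.1, 1.0))
        st = np.sort(rng.uniform(12, 110, 25))
        noisy, _ = spikes_to_fluorescence(st, 3600, cfg, seed=2)
        bl = np.zeros(3600, dtype=bool)
        bl[:300] = True
        counts = [len(detect_events(noisy, FR, baseline_frames=bl, peak_sd_mult=k))
                  for k in (1.0, 2.0, 3.0, 5.0, 8.0, 12.0)]
        assert counts == sorted(counts, reverse=True)

    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_events(np.zeros(100), FR, baseline_frames=np.arange(5))

    def test_events_never_overlap(self, rng):
        cfg = SimConfig(noise_sd=0.12,
                        transient_amplitude=1 / kernel_peak_factor(0.1, 1.0))
        st = np.sort(rng.uniform(5, 115, 40))
        noisy, _ = spikes_to_fluorescence(st, 3600, cfg, seed=3)
        ev = detect_events(noisy, FR)
        assert (ev.rise_start_frame <= ev.rise_end_frame).all()
        assert (ev.rise_start_frame.to_numpy()[1:]
                > ev.rise_end_frame.to_numpy()[:-1]).all()


class TestEventPhaseStats:
    def test_frequency_arithmetic(self):
        phases = np.array(["uphill"] * 3000 + ["flat"] * 1500)
        ev = pd.DataFrame({
            "rise_start_frame": np.linspace(10, 2900, 10, dtype=int),
            "rise_end_frame": np.linspace(15, 2905, 10, dtype=int),
            "peak_dff": np.full(10, 0.5),
            "duration_s": np.full(10, 0.2),
        })
        out = event_phase_stats(ev, phases, FR)
        assert out.loc["uphill", "frequency_hz"] == pytest.approx(10 / 100.0)
        assert out.loc["uphill", "intensity_dff"] == pytest.approx(0.5)
        assert out.loc["flat", "frequency_hz"] == 0.0
        assert np.isnan(out.loc["flat", "intensity_dff"])
        assert np.isnan(out.loc["quiescent", "frequency_hz"])  # never visited


class TestEndToEnd:
    def test_movie_to_events_recovers_planted_spikes(self):
        """Movie -> components -> traces -> events recovers >=85% of spikes."""
        rng = np.random.default_rng(12)
        T = 2000
        cfg = SimConfig(noise_sd=0.0,
                        transient_amplitude=1 / kernel_peak_factor(0.1, 1.0))
        pop = make_population({"uphill": 4}, frame_shape=(48, 48), seed=12,
                              min_separation_px=15, margin_px=8)
        spikes, traces = [], []
        for i in range(4):
            st = [rng.uniform(8, 10)]
            while st[-1] < T / FR - 3:
                st.append(st[-1] + rng.uniform(1.5, 4.0))
            st = np.asarray(st[:-1])
            _, clean = spikes_to_fluorescence(st, T, cfg, seed=i)
            spikes.append(st)
            traces.append(clean)
        movie, vessel, fps = render_movie(pop, np.asarray(traces), seed=13,
                                          pixel_noise_sd=1.5)
        dff = compute_dff(movie)
        comps = pca_ica(dff, n_ics=6, seed=0)
        qc_components(comps, vessel, dff.pixel_size)
        bl = np.zeros(T, dtype=bool)
        bl[: int(6 * FR)] = True
        hit = total = 0
        for i in range(4):
            rs = [np.corrcoef(c.spatial_filter.ravel(), fps[i].ravel())[0, 1]
                  for c in comps]
            tr = extract_trace_mli(dff, comps[int(np.argmax(rs))])
            ev = detect_events(tr, FR, baseline_frames=bl)
            starts = ev.rise_start_frame.to_numpy() / FR
            used = np.zeros(len(starts), dtype=bool)
            for t0 in spikes[i]:
                total += 1
                d = np.abs(starts - t0)
                d[used] = np.inf
                if len(d) and d.min() <= 3 / FR + 1e-9:
                    hit += 1
                    used[int(np.argmin(d))] = True
        assert hit / total >= 0.85
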