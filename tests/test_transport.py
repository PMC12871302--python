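"""Kymograph tracing and SVP transport metrics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axonsynkit import synthetic as syn
from axonsynkit import transport as tp


def _simple_track(points, axon="a"):
    return syn.Track(axon, points)


class TestClassify:
    @pytest.mark.parametrize("net,expected", [
        (15.0, "anterograde"),
        (10.0, "non_motile"),   # boundary is strict
        (-10.0, "non_motile"),
        (-12.0, "retrograde"),
        (3.0, "non_motile"),
    ])
    def test_net_displacement_rule(self, net, expected):
        tr = _simple_track([(0.0, 20.0), (30.0, 20.0 + net)])
        assert tp.classify_track(tr) == expected

    def test_partition_covers_all_tracks(self, wt_small_run):
        for _, _, _, traced in wt_small_run:
            classes = [tp.classify_track(t) for t in traced]
            counts = {c: classes.count(c) for c in set(classes)}
            assert sum(counts.values()) == len(traced)
            assert set(counts) <= {"anterograde", "retrograde", "non_motile"}


class TestSegmentVelocities:
    def test_single_segment_arithmetic(self):
        assert tp.segment_velocities(
            _simple_track([(0.0, 0.0), (5.0, 20.0)])) == pytest.approx([4.0])

    def test_collinear_points_equal_speeds(self):
        v = tp.segment_velocities(
            _simple_track([(0.0, 0.0), (5.0, 10.0), (10.0, 20.0)]))
        assert v == pytest.approx([2.0, 2.0])

    def test_pause_segment_near_zero_included(self):
        v = tp.segment_velocities(
            _simple_track([(0.0, 0.0), (5.0, 20.0), (8.0, 20.1), (10.0, 28.1)]))
        assert v == pytest.approx([4.0, 0.1 / 3.0, 4.0])

    def test_repeated_timestamps_rejected(self):
        tr = _simple_track([(0.0, 0.0), (5.0, 20.0)])
        tr.points = [(0.0, 0.0), (0.0, 5.0)]
        with pytest.raises(ValueError):
            tp.segment_velocities(tr)


def _brute_force_topk(speeds, k=5):
    pool = sorted((s for s in speeds if s >= 0.1), reverse=True)
    return float(np.mean(pool[:k])) if pool else float("nan")


class TestMaxVelocity:
    def test_matches_sort_oracle_on_known_pool(self):
        # pooled speeds {5,4,3,2,1,0.5} -> mean of five fastest = 3.0
        tracks = [
            _simple_track([(0.0, 0.0), (4.0, 20.0)]),            # 5
            _simple_track([(0.0, 0.0), (5.0, 20.0)]),            # 4
            _simple_track([(0.0, 0.0), (5.0, 15.0), (10.0, 25.0),
                           (35.0, 37.5), (60.0, 62.5)]),         # 3,2,0.5,1
        ]
        got = tp.max_velocity(tracks, "anterograde", k=5)
        speeds = np.concatenate([tp.segment_velocities(t) for t in tracks])
        assert got == pytest.approx(_brute_force_topk(speeds))
        assert got == pytest.approx(3.0)

    @given(st.lists(st.floats(0.15, 8.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_equals_brute_force_oracle(self, speeds):
        # build one anterograde track whose segments have exactly these speeds
        pts = [(0.0, 0.0)]
        t = x = 0.0
        for s in speeds:
            t += 1.0
            x += s
            pts.append((t, x))
        tr = _simple_track(pts)
        if tp.classify_track(tr) != "anterograde":
            return
        assert tp.max_velocity([tr], "anterograde") == pytest.approx(
            _brute_force_topk(tp.segment_velocities(tr)))

    def test_fewer_than_k_uses_all_with_warning(self):
        tr = _simple_track([(0.0, 0.0), (5.0, 20.0)])
        with pytest.warns(UserWarning):
            assert tp.max_velocity([tr], "anterograde") == pytest.approx(4.0)

    def test_no_motile_track_undefined_not_zero(self):
        tr = _simple_track([(0.0, 0.0), (5.0, 2.0)])
        with pytest.warns(UserWarning):
            assert np.isnan(tp.max_velocity([tr], "anterograde"))


class TestFlux:
    def test_count_normalised_to_minutes(self):
        tracks = [_simple_track([(0.0, 0.0), (10.0, 20.0)]) for _ in range(10)]
        assert tp.flux(tracks, "anterograde", 300.0) == pytest.approx(2.0)

    def test_empty_is_zero(self):
        assert tp.flux([], "anterograde", 300.0) == 0.0

    def test_flux_ratio(self):
        assert tp.flux_ratio(5.0, 3.0) == pytest.approx(0.6)
        assert tp.flux_ratio(2.0, 2.0) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            assert np.isnan(tp.flux_ratio(0.0, 3.0))


class TestTracer:
    def test_noise_free_round_trip_exact_count_subpixel_error(self):
        # well-separated constant-velocity tracks, no noise
        tracks = [
            syn.Track("a", [(5.0 + 12.0 * i, 0.0), (25.0 + 12.0 * i, 80.0)],
                      intensity=500.0)
            for i in range(10)
        ]
        kymo = syn.render_kymograph(tracks, 100.0, 160.0, noise_sd=0.0)
        traced = tp.trace_tracks(kymo)
        assert len(traced) == 10
        traced = sorted(traced, key=lambda t: t.times[0])
        for tr, gt in zip(traced, sorted(tracks, key=lambda t: t.times[0])):
            for t_end in (tr.times[0], tr.times[-1]):
                x_tr = np.interp(t_end, tr.times, tr.positions)
                x_gt = np.interp(t_end, gt.times, gt.positions)
                assert abs(x_tr - x_gt) < kymo.px_um  # < 1 px

    def test_pure_noise_yields_no_tracks(self):
        kymo = syn.render_kymograph([], 100.0, 60.0, noise_sd=10.0, bg=100.0,
                                    seed=3)
        assert tp.trace_tracks(kymo) == []

    def test_stationary_band_is_not_a_motile_track(self):
        site = syn.SvpSite("a", centroid_um=50.0, extent_um=1.5,
                           mean_intensity=400.0)
        kymo = syn.render_kymograph([], 100.0, 60.0, noise_sd=0.0,
                                    sites=[site])
        assert tp.trace_tracks(kymo) == []

    def test_uncalibrated_input_rejected(self):
        with pytest.raises(ValueError):
            tp.trace_tracks(np.zeros((10, 10)))

    def test_mean_position_error_below_one_pixel(self, wt_small_run):
        # against ground truth on realistic renders, matched tracks stay on path
        axon_id, tracks, kymo, traced = wt_small_run[0]
        errs = []
        for tr in traced:
            best = None
            for g in tracks:
                lo = max(tr.times[0], g.times[0])
                hi = min(tr.times[-1], g.times[-1])
                if hi <= lo:
                    continue
                ts = np.linspace(lo, hi, 20)
                d = np.abs(np.interp(ts, tr.times, tr.positions)
                           - np.interp(ts, g.times, g.positions)).mean()
                best = d if best is None else min(best, d)
            if best is not None and best < 2.0:
                errs.append(best)
        assert errs and np.mean(errs) < kymo.px_um


class TestMotileIntensity:
    def test_background_subtracted_peak(self):
        tr = syn.Track("a", [(2.0, 10.0), (22.0, 90.0)], intensity=500.0)
        kymo = syn.render_kymograph([tr], 100.0, 30.0, noise_sd=0.0, bg=100.0)
        assert tp.motile_intensity(kymo, tr) == pytest.approx(500.0, rel=0.02)

    def test_background_location_reads_near_zero(self):
        kymo = syn.render_kymograph([], 100.0, 30.0, noise_sd=0.0, bg=100.0)
        ghost = syn.Track("a", [(2.0, 10.0), (22.0, 90.0)])
        assert tp.motile_intensity(kymo, ghost) == pytest.approx(0.0, abs=1e-9)

    def test_intensity_scale_recovered_between_genotypes(self):
        from axonsynkit.config import PRESETS
        means = {}
        for g in ("WT", "C92X"):
            axons = syn.gen_svp_tracks(PRESETS[g], 30, 120.0, 100.0, seed=21)
            vals = [t.intensity for trs in axons.values() for t in trs]
            means[g] = np.mean(vals)
        assert means["C92X"] / means["WT"] == pytest.approx(0.7, rel=0.1)

    def test_outside_grid_rejected(self):
        kymo = syn.render_kymograph([], 100.0, 30.0)
        bad = syn.Track("a", [(2.0, 150.0), (22.0, 200.0)])
        with pytest.raises(ValueError):
            tp.motile_intensity(kymo, bad)


class TestRecoveryMonotonicity:
    def test_measured_flux_increases_with_generated_flux(self):
        from axonsynkit.config import PRESETS
        measured = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for flux_in in (2.0, 5.0, 8.0):
                p = PRESETS["WT"].replace(antero_flux=flux_in)
                axons = syn.gen_svp_tracks(p, 6, 300.0, 100.0, seed=31)
                vals = []
                for k, trs in enumerate(axons.values()):
                    kymo = syn.render_kymograph(trs, 100.0, 300.0,
                                                noise_sd=10.0, seed=k)
                    vals.append(tp.flux(tp.trace_tracks(kymo),
                                        "anterograde", 300.0))
                measured.append(np.mean(vals))
        assert measured[0] < measured[1] < measured[2]
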