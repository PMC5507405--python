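"""Trajectory classification, windowing, and the statistical test battery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermapattern.tracks import (
    CondensateROI,
    Track,
    classify_tracks,
    group_compare,
    join_probability,
    ks_uniform,
    segment_windows,
    track_summaries,
    tracks_from_frame,
    rois_from_frame,
    analyze_tracks,
)
from dermapattern.synthetic import TrackGenConfig, gen_tracks

ROI = CondensateROI(0, (0.0, 0.0), 20.0)


def make_track(tid, points):
    t, x, y = zip(*points)
    return Track(tid, np.array(t), np.array(x), np.array(y))


# ---------------------------------------------------------------------------
# classification


def test_track_ending_inside_roi_is_condensate():
    tr = make_track(1, [(0, 100, 0), (60, 50, 0), (120, 2, 0)])
    out = classify_tracks([tr], [ROI])[0]
    assert out.cls == "condensate"
    assert out.condensate_id == 0


def test_track_never_inside_is_intercondensate():
    tr = make_track(1, [(0, 100, 0), (60, 90, 0), (120, 95, 0)])
    out = classify_tracks([tr], [ROI])[0]
    assert out.cls == "intercondensate"
    assert out.entry_time is None


def test_entry_time_truncates_samples():
    tr = make_track(
        1, [(0, 100, 0), (300, 50, 0), (600, 30, 0), (900, 10, 0), (1200, 5, 0), (1500, 1, 0)]
    )
    out = classify_tracks([tr], [ROI])[0]
    assert out.entry_time == 900  # first time inside and inside thereafter
    assert out.t[-1] == 900  # later samples dropped


def test_reentry_uses_last_exit():
    # inside at 300, out again at 600, finally in from 900 on
    tr = make_track(
        1, [(0, 100, 0), (300, 10, 0), (600, 50, 0), (900, 10, 0), (1200, 5, 0)]
    )
    out = classify_tracks([tr], [ROI])[0]
    assert out.entry_time == 900


def test_classify_requires_rois():
    with pytest.raises(ValueError):
        classify_tracks([make_track(1, [(0, 0, 0), (1, 1, 1)])], [])


def test_track_validation():
    with pytest.raises(ValueError):
        Track(1, np.array([0.0]), np.array([0.0]), np.array([0.0]))
    with pytest.raises(ValueError):
        Track(1, np.array([0.0, 0.0]), np.zeros(2), np.zeros(2))


# ---------------------------------------------------------------------------
# windows


def classified(points, rois=(ROI,)):
    return classify_tracks([make_track(1, points)], list(rois))[0]


def test_straight_path_toward_center():
    # walks straight toward the ROI centre from (200, 0): angle 0, persistence 1
    pts = [(i * 60, 200 - 10 * i, 0) for i in range(7)]  # 0..360 min
    tr = classified(pts)
    recs = segment_windows(tr, [ROI])
    assert len(recs) == 1
    assert recs[0].euclid_angle == pytest.approx(0.0, abs=1e-9)
    assert recs[0].persistence == pytest.approx(1.0)
    assert recs[0].euclid_dist == pytest.approx(60.0)


def test_out_and_back_path_has_zero_euclid_and_flagged_angle():
    pts = [(0, 100, 0), (90, 110, 0), (180, 100, 0), (270, 110, 0), (360, 100, 0)]
    tr = classified(pts)
    recs = segment_windows(tr, [ROI])
    assert recs[0].euclid_dist == pytest.approx(0.0)
    assert recs[0].persistence == pytest.approx(0.0)
    assert not recs[0].angle_defined
    assert math.isnan(recs[0].euclid_angle)


def test_right_angle_path_pythagoras():
    pts = [(0, 100, 0), (180, 103, 0), (360, 103, 4)]
    tr = classified(pts)
    recs = segment_windows(tr, [ROI])
    assert recs[0].accum_dist == pytest.approx(7.0)
    assert recs[0].euclid_dist == pytest.approx(5.0)
    assert recs[0].persistence == pytest.approx(5.0 / 7.0)


def test_windows_counted_backward_and_partials_discarded():
    # 900 min of history: two full 360-min windows, the trailing 180 discarded
    pts = [(i * 60, 300 + i, 0) for i in range(16)]  # 0..900
    tr = classified(pts)
    recs = segment_windows(tr, [ROI])
    assert [r.window_label for r in recs] == ["0-6 h", "6-12 h"]


def test_angle_symmetry_under_reflection():
    """Reflecting all coordinates through the ROI centre leaves angles unchanged."""
    rng = np.random.default_rng(3)
    pts = [(i * 60.0, *rng.normal(50, 20, 2)) for i in range(13)]
    tr = classified(pts)
    ref = classified([(t, -x, -y) for t, x, y in pts])
    a = [r.euclid_angle for r in segment_windows(tr, [ROI]) if r.angle_defined]
    b = [r.euclid_angle for r in segment_windows(ref, [ROI]) if r.angle_defined]
    assert a == pytest.approx(b)


@settings(max_examples=200, deadline=None)
@given(
    steps=st.lists(
        st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=2, max_size=30
    )
)
def test_persistence_is_bounded_on_arbitrary_walks(steps):
    """0 <= persistence <= 1 and accumulated >= Euclidean, by construction."""
    xs = np.cumsum([s[0] for s in steps]) + 100
    ys = np.cumsum([s[1] for s in steps]) + 100
    t = np.arange(len(xs)) * 30.0
    tr = Track(1, t, xs, ys, cls="intercondensate")
    for rec in segment_windows(tr, [ROI], window_min=360.0):
        assert rec.accum_dist >= rec.euclid_dist - 1e-9
        assert rec.euclid_dist >= 0
        assert 0.0 <= rec.persistence <= 1.0
    summ = track_summaries(tr)
    assert summ.accumulated_velocity >= summ.euclidean_velocity - 1e-12
    assert summ.euclidean_velocity >= 0
    assert 0.0 <= summ.persistence <= 1.0


# ---------------------------------------------------------------------------
# summaries


def test_straight_track_summary():
    pts = [(i * 60, 100 - 6 * i, 0) for i in range(11)]  # 600 min, 60 um straight
    tr = classified(pts)
    s = track_summaries(tr)
    assert s.accumulated_velocity == pytest.approx(0.1)
    assert s.euclidean_velocity == pytest.approx(0.1)
    assert s.persistence == pytest.approx(1.0)


def test_closed_loop_has_zero_euclidean_velocity():
    pts = [(0, 100, 0), (60, 110, 0), (120, 110, 10), (180, 100, 10), (240, 100, 0)]
    s = track_summaries(classified(pts))
    assert s.euclidean_velocity == 0.0
    assert s.persistence == 0.0


# ---------------------------------------------------------------------------
# join probability


def test_join_probability_inner_bin_certain():
    rois = [CondensateROI(0, (0, 0), 20)]
    tracks = []
    for i in range(6):  # start and stay inside
        tracks.append(make_track(i, [(0, 1 + i * 0.5, 0), (500, 2, 0), (1000, 1, 0)]))
    for i in range(6, 12):  # far away forever
        tracks.append(make_track(i, [(0, 400 + i, 0), (500, 410, 0), (1000, 420, 0)]))
    cls = classify_tracks(tracks, rois)
    curve = join_probability(cls, rois, np.array([0, 20, 100, 500]))
    assert curve.probability.iloc[0] == 1.0
    assert curve.probability.iloc[2] == 0.0
    assert not curve.low_n.iloc[0]


def test_join_probability_flags_low_n_and_rejects_empty():
    rois = [CondensateROI(0, (0, 0), 20)]
    tracks = [make_track(0, [(0, 50, 0), (500, 60, 0)])]
    curve = join_probability(classify_tracks(tracks, rois), rois, np.array([0, 100]))
    assert curve.low_n.iloc[0]
    with pytest.raises(ValueError):
        join_probability([], rois, np.array([0, 100]))


def test_diffusive_capture_probability_decreases_with_distance():
    """With no directional bias, the chance of joining falls off with the
    initial distance to the centre (brute-force generator run)."""
    tdf, rdf, _ = gen_tracks(TrackGenConfig(seed=9, bias=0.0, n_cells=3000))
    cls = classify_tracks(tracks_from_frame(tdf), rois_from_frame(rdf))
    curve = join_probability(cls, rois_from_frame(rdf), np.array([0, 15, 30, 50, 80, 120]))
    p = curve.probability.to_numpy()
    assert p[0] > 0.5
    assert all(b <= a + 0.02 for a, b in zip(p, p[1:]))


# ---------------------------------------------------------------------------
# statistics


def brute_force_ks_uniform_d(angles):
    """Sup-difference between the empirical CDF and x/180, by enumeration."""
    angles = np.sort(np.asarray(angles, dtype=float))
    n = len(angles)
    d = 0.0
    for i, a in enumerate(angles):
        u = a / 180.0
        d = max(d, abs((i + 1) / n - u), abs(i / n - u))
    return d


def test_ks_uniform_five_point_sample_matches_enumeration():
    angles = np.array([0.0, 45.0, 90.0, 135.0, 180.0])
    expected = brute_force_ks_uniform_d(angles)  # = 0.2
    res = ks_uniform(angles)
    assert res.statistic == pytest.approx(expected)
    assert expected == pytest.approx(0.2)


def test_ks_uniform_large_uniform_sample_is_tight():
    rng = np.random.default_rng(12)
    res = ks_uniform(rng.uniform(0, 180, 10_000))
    assert res.statistic < 0.03  # DKW-style bound at n = 10,000
    assert res.p_value > 0.05


def test_ks_uniform_point_mass_at_zero():
    res = ks_uniform(np.zeros(10))
    assert res.statistic == pytest.approx(1.0)
    assert res.p_value < 1e-6


def test_ks_uniform_input_validation():
    with pytest.raises(ValueError):
        ks_uniform(np.array([0.0, 10.0, 200.0, 20.0, 30.0]))
    with pytest.raises(ValueError):
        ks_uniform(np.array([1.0, 2.0]))


def test_group_compare_identical_groups_not_significant():
    rng = np.random.default_rng(1)
    g = rng.normal(size=50)
    res = group_compare({"a": g, "b": g.copy()})
    mwu = [r for r in res if r.test == "mann_whitney_bonferroni"][0]
    assert mwu.p_value > 0.5


def test_group_compare_complete_separation():
    res = group_compare({"lo": np.arange(1, 21), "hi": np.arange(101, 121)})
    mwu = [r for r in res if r.test == "mann_whitney_bonferroni"][0]
    assert mwu.statistic == 0.0
    assert mwu.p_corrected < 1e-6


def test_group_compare_bonferroni_multiplier_counts_pairs():
    rng = np.random.default_rng(2)
    groups = {k: rng.normal(size=10) for k in "abc"}
    res = group_compare(groups)
    mwus = [r for r in res if r.test == "mann_whitney_bonferroni"]
    assert len(mwus) == 3
    assert all(r.n_comparisons == 3 for r in mwus)
    assert all(r.p_corrected == min(1.0, r.p_value * 3) for r in mwus)


def test_kruskal_type_one_error_rate():
    """Three groups drawn from one distribution reject at ~alpha."""
    rng = np.random.default_rng(5)
    rejections = 0
    n_resamples = 1000
    for _ in range(n_resamples):
        groups = {k: rng.normal(size=12) for k in "abc"}
        kw = group_compare(groups)[0]
        rejections += kw.p_value < 0.05
    assert rejections / n_resamples == pytest.approx(0.05, abs=0.02)


def test_constant_groups_flagged_undefined():
    res = group_compare({"a": np.ones(5), "b": np.ones(5)})
    assert math.isnan(res[0].statistic)


# ---------------------------------------------------------------------------
# pipeline smoke


def test_pipeline_recovers_ground_truth_classes():
    tdf, rdf, truth = gen_tracks(TrackGenConfig(seed=0))
    trs = tracks_from_frame(tdf)
    rois = rois_from_frame(rdf)
    wins, summ = analyze_tracks(trs, rois)
    merged = summ.merge(truth, left_on="track_id", right_on="track_id")
    assert (merged["cls"] == merged["true_class"]).all()
    assert set(wins.window_label) <= {"0-6 h", "6-12 h", "12-18 h"}
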