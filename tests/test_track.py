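"""LAP linking and gap closing: brute-force oracle equivalence, gating
soundness, partition property and lane-penalty behaviour."""

import itertools

import numpy as np
import pytest

from confinetrack import LinkingParams, Track, close_gaps, link_frames, track_movie
from confinetrack.segment import Detection
from confinetrack.track import _gap_cost_matrix, _solve_lap, pair_cost


def det(frame, x, y, label=1):
    return Detection(frame=frame, label=label, x_px=x, y_px=y, area_px2=40)


def brute_force_total(dets_a, dets_b, params):
    """Minimum of Σ link costs + b·(#unmatched) over all gated matchings."""
    costs = {}
    for i, a in enumerate(dets_a):
        for j, b in enumerate(dets_b):
            if np.hypot(b.x_px - a.x_px, b.y_px - a.y_px) <= params.max_link_dist:
                costs[(i, j)] = pair_cost(a.x_px, a.y_px, b.x_px, b.y_px, params)
    if not costs:
        return 0.0, []
    bval = params.alternative_cost_factor * max(costs.values())
    if bval <= 0:
        bval = params.alternative_cost_factor
    n, m = len(dets_a), len(dets_b)
    best, best_links = np.inf, None

    def rec(i, used_b, acc, links):
        nonlocal best, best_links
        if i == n:
            total = acc + bval * ((n - len(links)) + (m - len(links)))
            if total < best - 1e-12:
                best, best_links = total, sorted(links)
            return
        rec(i + 1, used_b, acc, links)          # a_i unmatched
        for j in range(m):
            if (i, j) in costs and j not in used_b:
                rec(i + 1, used_b | {j}, acc + costs[(i, j)], links + [(i, j)])

    rec(0, set(), 0.0, [])
    return best, best_links


def test_close_pair_linked():
    links, un_a, un_b, _ = link_frames([det(0, 10, 10)], [det(1, 15, 10)])
    assert links == [(0, 0)] and not un_a and not un_b


def test_pair_beyond_gate_unmatched():
    """120 px apart with a 100 px linking gate: both stay unmatched."""
    links, un_a, un_b, _ = link_frames([det(0, 0, 0)], [det(1, 120, 0)])
    assert links == [] and un_a == [0] and un_b == [0]


def test_y_penalty_prevents_lane_swap():
    """x offsets favour swapping lanes, but the y penalty (w=15) keeps
    links within lanes; equals the enumerated minimum."""
    a = [det(0, 0, 0), det(0, 4, 3)]
    b = [det(1, 5, 3), det(1, 9, 0)]
    params = LinkingParams()
    links, _, _, total = link_frames(a, b, params)
    expect_total, expect_links = brute_force_total(a, b, params)
    assert total == pytest.approx(expect_total)
    assert links == expect_links == [(0, 1), (1, 0)]  # same-lane
    # without the penalty the cross-lane swap is cheaper in x
    iso = LinkingParams(y_penalty_weight=0.0)
    links_iso, _, _, _ = link_frames(a, b, iso)
    assert links_iso == brute_force_total(a, b, iso)[1] == [(0, 0), (1, 1)]


@pytest.mark.parametrize("mode", ["anisotropic", "trackmate"])
def test_link_frames_matches_brute_force(mode):
    rng = np.random.default_rng(17)
    params = LinkingParams(max_link_dist=60.0, penalty_mode=mode)
    for _ in range(40):
        n, m = rng.integers(0, 6, size=2)
        a = [det(0, *rng.uniform(0, 100, 2)) for _ in range(n)]
        b = [det(1, *rng.uniform(0, 100, 2)) for _ in range(m)]
        _, _, _, total = link_frames(a, b, params)
        expect, _ = brute_force_total(a, b, params)
        assert total == pytest.approx(expect)


def test_gating_soundness_random_instances():
    rng = np.random.default_rng(23)
    params = LinkingParams(max_link_dist=40.0)
    for _ in range(25):
        a = [det(0, *rng.uniform(0, 120, 2)) for _ in range(5)]
        b = [det(1, *rng.uniform(0, 120, 2)) for _ in range(5)]
        links, _, _, _ = link_frames(a, b, params)
        for i, j in links:
            assert np.hypot(b[j].x_px - a[i].x_px,
                            b[j].y_px - a[i].y_px) <= 40.0


def seg(track_id, frames, xs, y=10.0):
    return Track(track_id=track_id, frames=frames, x=xs,
                 y=[y] * len(frames), det_labels=[])


def test_gap_within_bounds_joined():
    """End at frame 5, start at frame 8, 10 px apart: gap 2 <= 15 and
    distance 10 <= 150, so the segments join into one track."""
    a = seg(0, [3, 4, 5], [80, 90, 100])
    b = seg(1, [8, 9], [110, 120])
    out = close_gaps([a, b])
    assert len(out) == 1
    assert out[0].frames.tolist() == [3, 4, 5, 8, 9]


def test_gap_beyond_frame_bound_not_joined():
    a = seg(0, [3, 4, 5], [80, 90, 100])
    b = seg(1, [22, 23], [110, 120])  # gap 16 > 15
    assert len(close_gaps([a, b])) == 2


def test_gap_beyond_distance_bound_not_joined():
    a = seg(0, [3, 4, 5], [80, 90, 100])
    b = seg(1, [7, 8], [260, 270])  # 160 px > 150
    assert len(close_gaps([a, b])) == 2


def test_conflicting_joins_match_brute_force():
    """Two segment starts compete for one end; the LAP picks the
    enumerated minimum-cost non-conflicting join set."""
    params = LinkingParams()
    segs = [seg(0, [0, 1, 2], [0, 5, 10]),
            seg(1, [5, 6], [20, 25]),
            seg(2, [6, 7], [14, 18])]
    cost = _gap_cost_matrix(segs, params)
    links, _, _, total = _solve_lap(cost, params.alternative_cost_factor)
    # brute force over all non-conflicting join subsets
    cands = [(i, j) for i in range(3) for j in range(3)
             if np.isfinite(cost[i, j])]
    bval = params.alternative_cost_factor * max(
        cost[i, j] for i, j in cands)
    best = np.inf
    best_set = None
    for r in range(len(cands) + 1):
        for subset in itertools.combinations(cands, r):
            ends = [i for i, _ in subset]
            starts = [j for _, j in subset]
            if len(set(ends)) < len(ends) or len(set(starts)) < len(starts):
                continue
            tot = sum(cost[i, j] for i, j in subset) + bval * (6 - 2 * len(subset))
            if tot < best - 1e-12:
                best, best_set = tot, sorted(subset)
    assert total == pytest.approx(best)
    assert sorted(links) == best_set
    merged = close_gaps(segs, params)
    assert len(merged) == 3 - len(best_set)


def test_track_movie_spans_dropout():
    """A 3-frame detection dropout mid-movie still yields one track."""
    frames = []
    for f in range(20):
        if 8 <= f <= 10:
            frames.append([])
        else:
            frames.append([det(f, 10.0 + 5 * f, 12.0)])
    tracks = track_movie(frames)
    assert len(tracks) == 1
    assert len(tracks[0]) == 17
    assert 8 not in tracks[0].frames and 11 in tracks[0].frames


def test_track_movie_empty_input():
    assert track_movie([]) == []
    assert track_movie([[], [], []]) == []


def test_partition_property_random_detections():
    """Every detection lands in exactly one track, none duplicated."""
    rng = np.random.default_rng(31)
    frames = []
    for f in range(12):
        n = rng.integers(0, 5)
        frames.append([det(f, *rng.uniform(0, 200, 2), label=k + 1)
                       for k in range(n)])
    tracks = track_movie(frames)
    seen = [lbl for tr in tracks for lbl in tr.det_labels]
    expect = [(f, d.label) for f, dets in enumerate(frames) for d in dets]
    assert sorted(seen) == sorted(expect)
    assert len(seen) == len(set(seen))


def test_extreme_y_penalty_kills_cross_lane_links():
    a = [det(0, 0, 0), det(0, 0, 10)]
    b = [det(1, 30, 10), det(1, 60, 0)]  # crossing would be x-cheaper
    params = LinkingParams(y_penalty_weight=1e6)
    links, _, _, _ = link_frames(a, b, params)
    for i, j in links:
        assert a[i].y_px == b[j].y_px  # only same-lane links survive


def test_min_track_length_flagging(small_straight):
    from confinetrack import segment_movie
    _, stack, _ = small_straight
    tracks = track_movie(segment_movie(stack), min_track_length=25)
    assert all(tr.flagged_short for tr in tracks)  # 20-frame movie
    tracks = track_movie(segment_movie(stack), min_track_length=5)
    assert not any(tr.flagged_short for tr in tracks)


def test_linking_params_validation():
    with pytest.raises(ValueError):
        LinkingParams(max_link_dist=0)
    with pytest.raises(ValueError):
        LinkingParams(penalty_mode="other")
    with pytest.raises(ValueError):
        LinkingParams(alternative_cost_factor=1.0)
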