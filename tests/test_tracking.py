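import itertools
from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roostradar import Box, Detection, Track, link_detections, track_peak
from roostradar.tracking import _intersection_area

T0 = datetime(2014, 3, 1, 9, 0, tzinfo=timezone.utc)


def det(t_idx, x0, y0, x1, y1, birds=0.0, cls="clear"):
    return Detection(
        timestamp=T0 + timedelta(minutes=12 * t_idx),
        box=Box(x0, y0, x1, y1),
        birds=birds,
        cls=cls,
    )


def brute_force_links(prev_group, new_group, metric=_intersection_area):
    """Exhaustive one-to-one matching oracle.

    Enumerates every possible assignment of new detections to distinct
    previous detections (or to "new track"), keeps only assignments
    consistent with the greedy rule — every matched pair must overlap, and
    no unmatched pair may dominate a matched one — and picks the assignment
    maximizing total overlap with centroid distance as tie-break.
    """
    n, p = len(new_group), len(prev_group)
    best, best_key = None, None
    options = list(range(p)) + [None]
    for assign in itertools.product(options, repeat=n):
        used = [a for a in assign if a is not None]
        if len(used) != len(set(used)):
            continue
        if any(
            a is not None and metric(new_group[i].box, prev_group[a].box) == 0
            for i, a in enumerate(assign)
        ):
            continue
        total = sum(
            metric(new_group[i].box, prev_group[a].box)
            for i, a in enumerate(assign)
            if a is not None
        )
        dist = sum(
            (new_group[i].centroid[0] - prev_group[a].centroid[0]) ** 2
            + (new_group[i].centroid[1] - prev_group[a].centroid[1]) ** 2
            for i, a in enumerate(assign)
            if a is not None
        )
        key = (total, -dist)
        if best_key is None or key > best_key:
            best, best_key = assign, key
    return best


class TestLinking:
    def test_single_detection_single_scan(self):
        tracks = link_detections([[det(0, 0, 0, 2, 2, birds=42)]])
        assert len(tracks) == 1
        assert track_peak(tracks[0]) == 42

    def test_concentric_growth_is_one_track(self):
        scans = [
            [det(0, -1, -1, 1, 1, birds=100)],
            [det(1, -2, -2, 2, 2, birds=500)],
            [det(2, -3, -3, 3, 3, birds=300)],
        ]
        tracks = link_detections(scans)
        assert len(tracks) == 1
        assert tracks[0].peak_count == 500

    def test_no_overlap_starts_new_track(self):
        scans = [
            [det(0, 0, 0, 2, 2)],
            [det(1, 10, 10, 12, 12)],
        ]
        tracks = link_detections(scans)
        assert len(tracks) == 2

    def test_equal_overlap_tie_goes_to_nearest_centroid(self):
        # two previous boxes overlap the new box with identical area; their
        # centroids are ~4.8 km and ~3.2 km from the new centroid; the
        # nearer one must win
        prev_far = det(0, -8, -1, -4, 1)       # centroid (-6, 0)
        prev_near = det(0, 1.5, -1, 2.5, 1)    # centroid (2, 0)
        new = det(1, -4.5, -1, 2.0, 1)         # centroid (-1.25, 0)
        a1 = _intersection_area(new.box, prev_far.box)
        a2 = _intersection_area(new.box, prev_near.box)
        assert a1 == pytest.approx(a2)
        tracks = link_detections([[prev_far, prev_near], [new]])
        by_len = {len(t.detections): t for t in tracks}
        assert by_len[2].detections[0] is prev_near
        oracle = brute_force_links([prev_far, prev_near], [new])
        assert oracle == (1,)

    def test_greedy_one_to_one_losers_start_new_tracks(self):
        # two new boxes both overlap one predecessor; the larger overlap
        # claims it and the other starts a fresh track
        prev = det(0, 0, 0, 4, 4)
        big = det(1, 0, 0, 3.5, 4)      # overlap 14
        small = det(1, 3, 0, 6, 4)      # overlap 4
        tracks = link_detections([[prev], [big, small]])
        assert len(tracks) == 2
        two = next(t for t in tracks if len(t.detections) == 2)
        assert two.detections[1] is big
        oracle = brute_force_links([prev], [big, small])
        assert oracle[0] == 0 and oracle[1] is None

    def test_matches_brute_force_on_crossing_boxes(self):
        prev = [det(0, 0, 0, 4, 4), det(0, 3, 3, 7, 7)]
        new = [det(1, 1, 1, 5, 5), det(1, 4, 4, 8, 8)]
        tracks = link_detections([prev, new])
        got = []
        for ni, d in enumerate(new):
            t = next(t for t in tracks if d in t.detections)
            first = t.detections[0]
            got.append(prev.index(first) if first in prev else None)
        assert tuple(got) == brute_force_links(prev, new)

    def test_gap_breaks_track(self):
        scans = [
            [det(0, 0, 0, 2, 2)],
            [],                       # scan with no detections
            [det(2, 0, 0, 2, 2)],     # same place, but one scan later
        ]
        tracks = link_detections(scans)
        assert len(tracks) == 2

    def test_mixed_days_rejected(self):
        d1 = det(0, 0, 0, 2, 2)
        d2 = Detection(
            timestamp=T0 + timedelta(days=1), box=Box(0, 0, 2, 2)
        )
        with pytest.raises(ValueError, match="multiple days"):
            link_detections([[d1], [d2]])

    def test_every_detection_in_exactly_one_track(self):
        scans = [
            [det(0, 0, 0, 2, 2), det(0, 5, 5, 7, 7)],
            [det(1, 0.5, 0.5, 2.5, 2.5), det(1, 5.5, 5.5, 7.5, 7.5)],
            [det(2, 1, 1, 3, 3), det(2, 20, 20, 22, 22)],
        ]
        tracks = link_detections(scans)
        all_dets = [d for group in scans for d in group]
        assigned = [d for t in tracks for d in t.detections]
        assert len(assigned) == len(all_dets)
        assert {id(d) for d in assigned} == {id(d) for d in all_dets}

    @given(perm=st.permutations(range(3)))
    @settings(max_examples=6, derandomize=True)
    def test_permutation_invariance_within_scan(self, perm):
        prev = [det(0, 0, 0, 4, 4), det(0, 10, 0, 14, 4), det(0, 20, 0, 24, 4)]
        new = [det(1, 1, 1, 5, 5), det(1, 11, 1, 15, 5), det(1, 21, 1, 25, 5)]
        shuffled = [new[i] for i in perm]
        tracks = link_detections([prev, shuffled])
        pairs = {
            (id(t.detections[0]), id(t.detections[1]))
            for t in tracks
            if len(t.detections) == 2
        }
        expected = {(id(p), id(n)) for p, n in zip(prev, new)}
        assert pairs == expected


class TestTrackProperties:
    def test_peak_is_max(self):
        scans = [
            [det(0, 0, 0, 2, 2, birds=100)],
            [det(1, 0, 0, 2.5, 2.5, birds=500)],
            [det(2, 0, 0, 3, 3, birds=300)],
        ]
        (track,) = link_detections(scans)
        assert track_peak(track) == 500

    def test_contamination_flags(self):
        scans = [
            [det(0, 0, 0, 2, 2, cls="clear")],
            [det(1, 0, 0, 2.5, 2.5, cls="rain")],
        ]
        (track,) = link_detections(scans)
        assert track.contaminated and track.rain_contaminated
        scans = [[det(0, 0, 0, 2, 2, cls="clutter")]]
        (track,) = link_detections(scans)
        assert track.contaminated and not track.rain_contaminated

    def test_empty_track_peak_rejected(self):
        with pytest.raises(ValueError):
            track_peak(Track(track_id=0, detections=[]))

    def test_generator_scene_tracks_match_manifest(self, single_roost_scene, qc_open):
        from roostradar import run_pipeline

        series, manifest, ann = single_roost_scene
        _, tracks_by_date, _ = run_pipeline(series, ann, qc=qc_open)
        (d,) = tracks_by_date
        tracks = tracks_by_date[d]
        assert len(tracks) == len(manifest.roosts)
        peak_truth = max(rec.expected_birds for rec in manifest.scans)
        assert tracks[0].peak_count == pytest.approx(peak_truth, rel=0.02)
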