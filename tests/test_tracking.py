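"""Frame linking, gap closing, track filters and crossing flags."""

import itertools

import numpy as np
import pytest

from smtrack.detection import Spot
from smtrack.tracking import (LinkParams, Track, close_gaps, filter_tracks,
                              flag_crossings, link_frames)


def mk_spot(frame, x, y, inten=1.0, channel="mrna"):
    return Spot(frame=frame, x=x, y=y, amplitude=1.0, sigma_x=1.3,
                sigma_y=1.3, background=0.0, integrated_intensity=inten,
                channel=channel)


def mk_track(tid, channel, coords, start=0):
    """coords: list of (x, y); frames start..start+len-1."""
    spots = [(start + i, mk_spot(start + i, x, y, channel=channel))
             for i, (x, y) in enumerate(coords)]
    return Track(id=tid, channel=channel, spots=spots)


class TestLinkFrames:
    def test_stationary_spot_single_track(self):
        spots = [mk_spot(f, 10.0, 10.0) for f in range(8)]
        tracks = link_frames(spots, LinkParams())
        assert len(tracks) == 1
        assert tracks[0].n_frames == 8

    def test_parallel_lines_no_swaps(self):
        params = LinkParams(max_disp_px=2.0)
        spots = []
        for f in range(10):
            spots.append(mk_spot(f, 5.0 + 0.5 * f, 5.0))
            spots.append(mk_spot(f, 5.0 + 0.5 * f, 5.0 + 10.0))  # 5x gate
        tracks = link_frames(spots, params)
        assert len(tracks) == 2
        for t in tracks:
            ys = {s.y for _, s in t.spots}
            assert len(ys) == 1   # no identity swap

    def test_matches_brute_force_assignment(self, rng):
        """Per frame-pair cost equals the exhaustive-permutation optimum."""
        n, n_frames, gate = 5, 10, 4.0
        base = rng.uniform(10, 40, size=(n, 2))
        steps = rng.uniform(-1.0, 1.0, size=(n_frames, n, 2))
        pos = base[None] + np.cumsum(steps, axis=0) * 0.5
        spots = [mk_spot(f, *pos[f, i]) for f in range(n_frames)
                 for i in range(n)]
        tracks = link_frames(spots, LinkParams(max_disp_px=gate))
        assert len(tracks) == n
        got_cost = 0.0
        for t in tracks:
            xy = np.array([[s.x, s.y] for _, s in t.spots])
            got_cost += float(np.sum(np.diff(xy, axis=0) ** 2))
        best_cost = 0.0
        for f in range(n_frames - 1):
            d2 = np.sum((pos[f][:, None] - pos[f + 1][None]) ** 2, axis=2)
            best_cost += min(sum(d2[i, p[i]] for i in range(n))
                             for p in itertools.permutations(range(n)))
        assert got_cost == pytest.approx(best_cost)

    def test_gating_starts_new_track(self):
        spots = [mk_spot(0, 10.0, 10.0), mk_spot(1, 30.0, 30.0)]
        tracks = link_frames(spots, LinkParams(max_disp_px=3.0))
        assert len(tracks) == 2


class TestCloseGaps:
    def test_single_missed_frame_joined(self):
        t1 = mk_track(0, "mrna", [(5.0, 5.0)] * 3, start=0)
        t2 = mk_track(1, "mrna", [(5.1, 5.0)] * 3, start=4)  # gap of 1
        out = close_gaps([t1, t2], LinkParams(max_gap_frames=1))
        assert len(out) == 1
        assert out[0].n_frames == 6

    def test_gap_zero_is_identity(self):
        t1 = mk_track(0, "mrna", [(5.0, 5.0)] * 3, start=0)
        t2 = mk_track(1, "mrna", [(5.0, 5.0)] * 3, start=5)
        out = close_gaps([t1, t2], LinkParams(max_gap_frames=0))
        assert len(out) == 2

    def test_never_merges_overlapping(self):
        t1 = mk_track(0, "mrna", [(5.0, 5.0)] * 4, start=0)
        t2 = mk_track(1, "mrna", [(5.0, 5.0)] * 4, start=2)
        out = close_gaps([t1, t2], LinkParams(max_gap_frames=3))
        assert len(out) == 2

    def test_dropped_detections_recovered(self, rng):
        """With a few % missed detections, gap closing restores one track
        per ground-truth molecule."""
        n_mol, n_frames = 20, 60
        base = rng.uniform(10, 200, size=(n_mol, 2))
        # enforce separation so tracks are unambiguous
        base = np.array([[20.0 + 24 * (i % 5), 20.0 + 24 * (i // 5)]
                         for i in range(n_mol)], dtype=float)
        spots = []
        for f in range(n_frames):
            for i in range(n_mol):
                if rng.random() < 0.03 and 0 < f < n_frames - 1:
                    continue   # missed detection
                jitter = rng.normal(0, 0.2, 2)
                spots.append(mk_spot(f, base[i, 0] + jitter[0],
                                     base[i, 1] + jitter[1]))
        params = LinkParams(max_disp_px=3.0, max_gap_frames=2)
        fragments = link_frames(spots, params)
        closed = close_gaps(fragments, params)
        assert len(closed) == n_mol


class TestFilterTracks:
    @pytest.mark.parametrize("n_frames,kept", [(24, False), (25, True)])
    def test_mrna_length_boundary(self, n_frames, kept):
        t = mk_track(0, "mrna", [(5.0, 5.0)] * n_frames)
        filter_tracks([t], LinkParams.steady_state(min_duration_s=0.0),
                      "steady_state", 2.0)
        assert t.kept is kept
        if not kept:
            assert t.status == "discarded:too_short"

    @pytest.mark.parametrize("n_frames,kept", [(3, False), (4, True)])
    def test_protein_length_boundary(self, n_frames, kept):
        t = mk_track(0, "protein", [(5.0, 5.0)] * n_frames)
        filter_tracks([t], LinkParams.steady_state(), "steady_state", 2.0)
        assert t.kept is kept

    def test_two_minute_rule_on_mrna(self):
        short = mk_track(0, "mrna", [(5.0, 5.0)] * 50)   # 100 s at 2 s
        long = mk_track(1, "mrna", [(5.0, 5.0)] * 60)    # 120 s
        filter_tracks([short, long], LinkParams.steady_state(),
                      "steady_state", 2.0)
        assert short.status == "discarded:too_brief"
        assert long.kept

    def test_idempotent(self):
        tracks = [mk_track(0, "mrna", [(5.0, 5.0)] * 10),
                  mk_track(1, "mrna", [(5.0, 5.0)] * 80)]
        params = LinkParams.steady_state()
        once = filter_tracks(tracks, params, "steady_state", 2.0)
        snap = [(t.status, t.reason) for t in once]
        twice = filter_tracks(once, params, "steady_state", 2.0)
        assert [(t.status, t.reason) for t in twice] == snap

    def test_runoff_mode_five_frames(self):
        t4 = mk_track(0, "mrna", [(5.0, 5.0)] * 4)
        t5 = mk_track(1, "mrna", [(5.0, 5.0)] * 13)  # 130 s at 10 s
        filter_tracks([t4, t5], LinkParams.runoff_uv(), "runoff_uv", 10.0)
        assert not t4.kept
        assert t5.kept


class TestFlagCrossings:
    def test_distant_tracks_unflagged(self):
        a = mk_track(0, "mrna", [(5.0, 5.0)] * 10)
        b = mk_track(1, "mrna", [(50.0, 50.0)] * 10)
        flag_crossings([a, b], 2.6)
        assert a.kept and b.kept

    def test_crossing_pair_both_flagged(self):
        a = mk_track(0, "mrna", [(5.0 + f, 10.0) for f in range(10)])
        b = mk_track(1, "mrna", [(14.0 - f, 10.0) for f in range(10)])
        flag_crossings([a, b], 2.6)
        assert a.status == "discarded:crossing"
        assert b.status == "discarded:crossing"

    def test_only_contacting_pair_flagged(self):
        """Pairwise-distance oracle: exactly the contacting pair flagged."""
        a = mk_track(0, "mrna", [(5.0, 5.0)] * 10)
        b = mk_track(1, "mrna", [(6.0, 5.0)] * 10)     # touches a
        c = mk_track(2, "mrna", [(40.0, 40.0)] * 10)   # far away
        flag_crossings([a, b, c], 2.6)
        assert not a.kept and not b.kept
        assert c.kept


class TestConservation:
    def test_every_spot_in_exactly_one_track(self, rng):
        spots = [mk_spot(f, float(x), float(y))
                 for f in range(6)
                 for x, y in rng.uniform(5, 60, size=(8, 2))]
        tracks = link_frames(spots, LinkParams(max_disp_px=3.0))
        seen = []
        for t in tracks:
            for _, s in t.spots:
                seen.append(id(s))
        assert len(seen) == len(spots)
        assert len(set(seen)) == len(spots)

    def test_order_permutation_same_track_set(self, rng):
        spots = [mk_spot(f, float(x), 10.0)
                 for f in range(5) for x in (10.0, 20.0, 30.0)]
        tracks_a = link_frames(spots, LinkParams())
        perm = list(spots)
        rng.shuffle(perm)
        tracks_b = link_frames(perm, LinkParams())

        def canon(tracks):
            return sorted(tuple((f, round(s.x, 6), round(s.y, 6))
                                for f, s in t.spots) for t in tracks)
        assert canon(tracks_a) == canon(tracks_b)
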