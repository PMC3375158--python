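"""Detection, linking, track summaries and skeleton colocalization."""

import numpy as np
import pytest

from sgquant.synth._geometry import stamp_gaussian
from sgquant.tracking import (
    detect_puncta,
    link_tracks,
    mt_colocalization,
    summarize_track,
)
from sgquant.types import Detection, Track


def _frame(spots, shape=(64, 64), amplitude=100.0, background=10.0):
    img = np.full(shape, background)
    for r, c in spots:
        stamp_gaussian(img, (r, c), 1.3, amplitude)
    return img


def _track(positions, px=100.0, dt=1.0):
    dets = [
        Detection(frame_index=i, position=tuple(p), intensity=1.0)
        for i, p in enumerate(positions)
    ]
    return Track(track_id=1, detections=dets, pixel_size_nm=px, frame_interval_s=dt)


class TestDetectPuncta:
    def test_blank_frame_yields_nothing(self):
        assert detect_puncta(np.full((32, 32), 10.0), 1.3, 15.0) == []

    def test_single_spot_localized_to_half_pixel(self):
        truth = (20.3, 31.7)
        dets = detect_puncta(_frame([truth]), 1.3, 15.0)
        assert len(dets) == 1
        assert np.hypot(*(np.array(dets[0].position) - truth)) < 0.5

    def test_two_spots_ten_pixels_apart_both_found(self):
        truths = [(20.0, 20.0), (20.0, 30.0)]
        dets = detect_puncta(_frame(truths), 1.3, 15.0)
        assert len(dets) == 2
        got = sorted(d.position for d in dets)
        for g, t in zip(got, sorted(truths)):
            assert np.hypot(*(np.array(g) - t)) < 0.5

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_puncta(np.zeros((8, 8)), 0.0, 1.0)


class TestLinkTracks:
    def test_single_moving_detection_forms_one_full_track(self):
        frames = [[Detection(0, (10.0 + f, 10.0), 1.0)] for f in range(5)]
        tracks = link_tracks(frames, 3.0, pixel_size_nm=100, frame_interval_s=1)
        assert len(tracks) == 1
        assert len(tracks[0].detections) == 5

    def test_parallel_tracks_recovered_without_crossover(self):
        frames = []
        for f in range(6):
            frames.append(
                [
                    Detection(f, (10.0, 5.0 + 2.0 * f), 1.0),
                    Detection(f, (30.0, 5.0 + 2.0 * f), 1.0),
                ]
            )
        tracks = link_tracks(frames, 4.0, pixel_size_nm=100, frame_interval_s=1)
        assert len(tracks) == 2
        rows = sorted({d.position[0] for t in tracks for d in t.detections})
        assert rows == [10.0, 30.0]
        assert all(len(t.detections) == 6 for t in tracks)

    def test_conflicting_nearest_neighbour_stays_unlinked(self):
        # two previous detections compete for one current detection: the
        # mutual-NN rule links only the true mutual pair, as would the
        # brute-force optimal assignment on this 2x2 case
        frames = [
            [Detection(0, (0.0, 0.0), 1.0), Detection(0, (0.0, 4.0), 1.0)],
            [Detection(1, (0.0, 2.5), 1.0)],
        ]
        tracks = link_tracks(frames, 10.0, pixel_size_nm=100, frame_interval_s=1)
        assert len(tracks) == 1
        cols = [d.position[1] for d in tracks[0].detections]
        assert cols == [4.0, 2.5]  # (0,4) is the mutual nearest neighbour

    def test_links_longer_than_max_disp_forbidden(self):
        frames = [
            [Detection(0, (10.0, 10.0), 1.0)],
            [Detection(1, (10.0, 20.0), 1.0)],
        ]
        assert link_tracks(frames, 5.0, pixel_size_nm=100, frame_interval_s=1) == []

    def test_linking_is_invariant_to_detection_order(self):
        rng = np.random.default_rng(5)
        frames = []
        base = rng.uniform(10, 50, size=(4, 2))
        for f in range(5):
            dets = [
                Detection(f, tuple(base[i] + [0.0, 1.5 * f]), 1.0)
                for i in range(len(base))
            ]
            frames.append(dets)
        shuffled = [list(reversed(dets)) for dets in frames]
        t1 = link_tracks(frames, 4.0, pixel_size_nm=100, frame_interval_s=1)
        t2 = link_tracks(shuffled, 4.0, pixel_size_nm=100, frame_interval_s=1)
        sig1 = sorted(tuple(map(tuple, t.positions_px)) for t in t1)
        sig2 = sorted(tuple(map(tuple, t.positions_px)) for t in t2)
        assert sig1 == sig2


class TestSummarizeTrack:
    def test_stationary_track_not_directed(self):
        s = summarize_track(_track([(5.0, 5.0)] * 5))
        assert s.mean_velocity_um_s == 0.0
        assert s.straightness == 0.0
        assert not s.directed

    def test_collinear_track_hand_arithmetic(self):
        # 5 collinear detections 1 px apart, 100 nm/px, 1 s interval
        s = summarize_track(_track([(10.0, 10.0 + i) for i in range(5)]))
        assert s.mean_velocity_um_s == pytest.approx(0.1)
        assert s.straightness == pytest.approx(1.0)
        assert s.path_length_um == pytest.approx(0.4)
        assert s.directed

    def test_three_detections_never_directed(self):
        s = summarize_track(_track([(0.0, 0.0), (0.0, 1.0), (0.0, 2.0)]))
        assert s.straightness == pytest.approx(1.0)
        assert not s.directed  # fewer than 4 detections

    def test_velocity_calibration_equivariance(self):
        pos = [(10.0, 10.0 + 2 * i) for i in range(5)]
        base = summarize_track(_track(pos, px=100.0, dt=1.0))
        double_px = summarize_track(_track(pos, px=200.0, dt=1.0))
        double_dt = summarize_track(_track(pos, px=100.0, dt=2.0))
        assert double_px.mean_velocity_um_s == pytest.approx(2 * base.mean_velocity_um_s)
        assert double_dt.mean_velocity_um_s == pytest.approx(base.mean_velocity_um_s / 2)

    def test_net_displacement_variant(self):
        pos = [(0.0, 0.0), (0.0, 2.0), (0.0, 0.0), (0.0, 2.0), (0.0, 4.0)]
        path = summarize_track(_track(pos))
        net = summarize_track(_track(pos), use_net_displacement=True)
        assert net.mean_velocity_um_s < path.mean_velocity_um_s
        assert net.mean_velocity_um_s == pytest.approx(0.4 * 0.1 / 0.4)


class TestColocalization:
    def test_track_on_filament_fully_colocalizes(self):
        skeleton = np.zeros((40, 40), dtype=bool)
        skeleton[20, :] = True
        track = _track([(20.0, 5.0 + i) for i in range(5)])
        assert mt_colocalization(track, skeleton, 2.0) == 1.0

    def test_parallel_track_at_5px_offset_does_not(self):
        skeleton = np.zeros((40, 40), dtype=bool)
        skeleton[20, :] = True
        track = _track([(25.0, 5.0 + i) for i in range(5)])
        assert mt_colocalization(track, skeleton, 2.0) == 0.0

    def test_empty_skeleton_gives_zero(self):
        track = _track([(5.0, 5.0), (5.0, 6.0)])
        assert mt_colocalization(track, np.zeros((10, 10), dtype=bool), 2.0) == 0.0

    def test_on_skeleton_tracks_separate_from_off_skeleton(self):
        """Generated on-filament directed tracks colocalize far more than
        free directed tracks (mean separation >= 0.5)."""
        from sgquant.synth import TrackSetParams, generate_track_set

        p = TrackSetParams(
            n_tracks=30, fraction_directed=1.0, on_skeleton_fraction=0.5,
            localization_noise_nm=0.0, seed=13,
        )
        ts, skeleton, truth = generate_track_set(p)
        fracs = {"on": [], "off": []}
        for t, row in zip(ts.tracks, truth.itertuples()):
            track = _track(t.true_positions_px)
            key = "on" if row.on_skeleton else "off"
            fracs[key].append(mt_colocalization(track, skeleton, 2.0))
        assert fracs["on"] and fracs["off"]
        assert np.mean(fracs["on"]) - np.mean(fracs["off"]) >= 0.5


class TestTrackType:
    def test_gapped_frames_rejected(self):
        dets = [Detection(0, (0, 0), 1.0), Detection(2, (0, 1), 1.0)]
        with pytest.raises(ValueError, match="consecutive"):
            Track(1, dets, 100.0, 1.0)

    def test_short_tracks_rejected(self):
        with pytest.raises(ValueError):
            Track(1, [Detection(0, (0, 0), 1.0)], 100.0, 1.0)
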