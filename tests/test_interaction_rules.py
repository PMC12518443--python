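"""The movement/position/interaction rule set: published defaults,
boundary semantics, missing-data conventions, oracle equivalence."""

from dataclasses import replace

import numpy as np
import pytest

from tableside import (
    InteractionParams,
    Keypoint,
    PoseDetection,
    Region,
    RegionSet,
    UsageError,
    classify_interaction,
    classify_pose_position,
    classify_pose_still,
    classify_subpose_position,
    classify_subpose_still,
    keypoint_displacement,
)
from tableside.interaction_rules import (
    CATEGORY_INTERACTING,
    CATEGORY_POSITIONED_BUT_MOVING,
    CATEGORY_WRONG_POSITION,
)
from tableside.pose_io import COCO_KEYPOINT_NAMES

from conftest import random_pose, random_region_set, random_track, stream_from_tracks
from rule_oracle import oracle_pose_by_table, oracle_pose_still


def make_pose(frame, positions, confidences=None, track_id=0):
    """Pose with given {name: (x, y)}; other keypoints undetected."""
    confidences = confidences or {}
    kps = []
    for name in COCO_KEYPOINT_NAMES:
        if name in positions:
            x, y = positions[name]
            kps.append(Keypoint(name, x, y, confidences.get(name, 0.9)))
        else:
            kps.append(Keypoint.undetected(name))
    return PoseDetection(frame, tuple(kps), 0.9, track_id)


def square_regions(size=1000.0):
    sq = ((0.0, 0.0), (size, 0.0), (size, size), (0.0, size))
    return RegionSet(wrists=Region("wrists", sq), shoulders=Region("shoulders", sq),
                     head=Region("head", sq))


class TestDefaultParams:
    def test_published_defaults_field_by_field(self):
        p = InteractionParams()
        assert p.f_motion == 5
        assert p.min_still_subposes == 1
        assert [s.name for s in p.movement_subposes] == ["shoulders", "head"]
        for spec in p.movement_subposes:
            assert spec.min_still_keypoints == 1
            assert spec.displacement_threshold == 17.5
            assert spec.confidence_threshold == 0.3
        assert p.movement_subposes[0].keypoints == ("left_shoulder", "right_shoulder")
        assert p.movement_subposes[1].keypoints == (
            "nose", "left_eye", "right_eye", "left_ear", "right_ear")
        assert p.min_positioned_subposes == 2
        wrists, shoulders, head = p.position_subposes
        assert (wrists.region_name, wrists.min_inside_keypoints,
                wrists.confidence_threshold) == ("wrists", 1, 0.3)
        assert wrists.keypoints == ("left_wrist", "right_wrist")
        assert (shoulders.region_name, shoulders.min_inside_keypoints,
                shoulders.confidence_threshold) == ("shoulders", 1, 0.3)
        assert (head.region_name, head.min_inside_keypoints,
                head.confidence_threshold) == ("head", 2, 0.15)

    def test_toml_overrides_merge_with_defaults(self, tmp_path):
        cfg = tmp_path / "params.toml"
        cfg.write_text('f_motion = 10\n[movement.shoulders]\ntau_m = 25.0\n')
        p = InteractionParams.from_toml(cfg)
        assert p.f_motion == 10
        assert p.movement_subposes[0].displacement_threshold == 25.0
        assert p.movement_subposes[1].displacement_threshold == 17.5  # untouched


class TestDisplacement:
    def test_three_four_five_triangle(self):
        a = make_pose(0, {"nose": (100.0, 100.0)})
        b = make_pose(5, {"nose": (103.0, 104.0)})
        track = {0: a, 5: b}
        assert keypoint_displacement(track, 5, "nose", 5) == pytest.approx(5.0)

    def test_identical_positions_give_zero(self):
        a = make_pose(0, {"nose": (100.0, 100.0)})
        b = make_pose(5, {"nose": (100.0, 100.0)})
        assert keypoint_displacement({0: a, 5: b}, 5, "nose", 5) == 0.0

    def test_track_younger_than_span_is_undefined(self):
        b = make_pose(3, {"nose": (100.0, 100.0)})
        track = {2: make_pose(2, {"nose": (0.0, 0.0)}), 3: b}
        assert keypoint_displacement(track, 3, "nose", 5) is None

    def test_undetected_endpoint_is_undefined(self):
        a = make_pose(0, {})  # nose undetected at t-5
        b = make_pose(5, {"nose": (100.0, 100.0)})
        assert keypoint_displacement({0: a, 5: b}, 5, "nose", 5) is None

    def test_frame_not_in_track_errors(self):
        with pytest.raises(UsageError):
            keypoint_displacement({}, 5, "nose", 5)


class TestMovementRule:
    def track_with_shoulder_motion(self, d_left, d_right, conf=0.9):
        p0 = make_pose(0, {"left_shoulder": (100.0, 100.0), "right_shoulder": (200.0, 100.0)})
        p5 = make_pose(5, {"left_shoulder": (100.0 + d_left, 100.0),
                           "right_shoulder": (200.0 + d_right, 100.0)},
                       confidences={"left_shoulder": conf, "right_shoulder": conf})
        return {0: p0, 5: p5}

    def test_static_confident_shoulders_are_still(self):
        track = self.track_with_shoulder_motion(0.0, 0.0)
        spec = InteractionParams().movement_subposes[0]
        assert classify_subpose_still(track[5], track, spec, 5)

    def test_low_confidence_keypoints_assumed_still_despite_motion(self):
        track = self.track_with_shoulder_motion(500.0, 500.0, conf=0.1)
        spec = InteractionParams().movement_subposes[0]
        assert classify_subpose_still(track[5], track, spec, 5)

    def test_one_keypoint_below_threshold_suffices(self):
        track = self.track_with_shoulder_motion(30.0, 5.0)
        spec = InteractionParams().movement_subposes[0]
        assert classify_subpose_still(track[5], track, spec, 5)

    def test_displacement_exactly_at_threshold_is_not_below(self):
        track = self.track_with_shoulder_motion(17.5, 17.5)
        spec = InteractionParams().movement_subposes[0]
        assert not classify_subpose_still(track[5], track, spec, 5)
        barely = self.track_with_shoulder_motion(17.5 - 1e-9, 17.5)
        assert classify_subpose_still(barely[5], barely, spec, 5)

    def test_confidence_exactly_at_gate_counts_as_reliable(self):
        track = self.track_with_shoulder_motion(30.0, 30.0, conf=0.3)
        spec = InteractionParams().movement_subposes[0]
        assert not classify_subpose_still(track[5], track, spec, 5)

    def test_fully_undetected_pose_is_still(self):
        pose = make_pose(5, {})
        still, verdicts = classify_pose_still(pose, {5: pose})
        assert still and verdicts == {"shoulders": True, "head": True}

    def test_all_subposes_moving_confidently_is_not_still(self):
        pos0 = {n: (100.0 + 30 * i, 100.0) for i, n in enumerate(
            ("left_shoulder", "right_shoulder", "nose", "left_eye", "right_eye",
             "left_ear", "right_ear"))}
        pos5 = {n: (x + 30.0, y) for n, (x, y) in pos0.items()}
        track = {0: make_pose(0, pos0), 5: make_pose(5, pos5)}
        still, verdicts = classify_pose_still(track[5], track)
        assert not still and verdicts == {"shoulders": False, "head": False}

    def test_one_still_subpose_suffices(self):
        pos0 = {"left_shoulder": (100.0, 100.0), "right_shoulder": (200.0, 100.0),
                "nose": (150.0, 50.0)}
        pos5 = {"left_shoulder": (130.0, 100.0), "right_shoulder": (230.0, 100.0),
                "nose": (150.0, 50.0)}  # head still, shoulders moving
        track = {0: make_pose(0, pos0), 5: make_pose(5, pos5)}
        still, verdicts = classify_pose_still(track[5], track)
        assert still and verdicts == {"shoulders": False, "head": True}


class TestPositionRule:
    def test_confident_wrists_inside_are_positioned(self):
        pose = make_pose(0, {"left_wrist": (500.0, 500.0), "right_wrist": (600.0, 500.0)})
        spec = InteractionParams().position_subposes[0]
        assert classify_subpose_position(pose, square_regions(), spec)

    def test_low_confidence_wrists_not_counted(self):
        pose = make_pose(0, {"left_wrist": (500.0, 500.0), "right_wrist": (600.0, 500.0)},
                         confidences={"left_wrist": 0.2, "right_wrist": 0.2})
        spec = InteractionParams().position_subposes[0]
        assert not classify_subpose_position(pose, square_regions(), spec)

    def test_head_needs_two_of_five_at_low_gate(self):
        pose = make_pose(0, {"nose": (500.0, 500.0), "left_eye": (510.0, 490.0),
                             "left_ear": (5000.0, 5000.0), "right_ear": (5000.0, 5000.0)},
                         confidences={"nose": 0.2, "left_eye": 0.2})
        spec = InteractionParams().position_subposes[2]
        assert classify_subpose_position(pose, square_regions(), spec)

    def test_two_of_three_subposes_make_by_table(self):
        # wrists + head in-region, shoulders far outside
        pose = make_pose(0, {
            "left_wrist": (500.0, 500.0), "nose": (500.0, 400.0), "left_eye": (505.0, 395.0),
            "left_shoulder": (5000.0, 5000.0), "right_shoulder": (5000.0, 5000.0)})
        by_table, verdicts = classify_pose_position(pose, square_regions())
        assert by_table
        assert verdicts == {"wrists": True, "shoulders": False, "head": True}

    def test_single_subpose_is_not_enough(self):
        pose = make_pose(0, {"left_wrist": (500.0, 500.0)})
        by_table, verdicts = classify_pose_position(pose, square_regions())
        assert not by_table
        assert verdicts == {"wrists": True, "shoulders": False, "head": False}


class TestInteraction:
    def _tracked_stream(self, moving: bool, inside: bool):
        # all shoulder and head keypoints detected and confident, so a
        # moving pose really counts as moving (nothing "assumed still")
        base = 500.0 if inside else 5000.0
        step = 10.0 if moving else 0.0
        poses = {}
        for f in range(10):
            poses[f] = make_pose(f, {
                "left_shoulder": (base + step * f, 400.0),
                "right_shoulder": (base + 100 + step * f, 400.0),
                "nose": (base + 50 + step * f, 300.0),
                "left_eye": (base + 55 + step * f, 295.0),
                "right_eye": (base + 45 + step * f, 295.0),
                "left_ear": (base + 62 + step * f, 298.0),
                "right_ear": (base + 38 + step * f, 298.0),
                "left_wrist": (base + step * f, 500.0),
            })
        return stream_from_tracks({0: poses})

    def test_still_by_table_interacts(self):
        records = classify_interaction(self._tracked_stream(False, True), square_regions())
        late = [r for r in records if r.frame >= 5]
        assert all(r.interacting and r.category == CATEGORY_INTERACTING for r in late)

    def test_moving_by_table_is_positioned_but_moving(self):
        records = classify_interaction(self._tracked_stream(True, True), square_regions())
        late = [r for r in records if r.frame >= 5]
        assert all(not r.interacting and r.category == CATEGORY_POSITIONED_BUT_MOVING
                   for r in late)

    def test_still_away_is_wrong_position(self):
        records = classify_interaction(self._tracked_stream(False, False), square_regions())
        assert all(r.still and not r.by_table and r.category == CATEGORY_WRONG_POSITION
                   for r in records)

    def test_untracked_stream_is_rejected_with_instruction(self):
        pose = make_pose(0, {"nose": (1.0, 1.0)}, track_id=None)
        from tableside import PoseStream
        stream = PoseStream((pose,), n_frames=1)
        with pytest.raises(UsageError, match="build_tracklets"):
            classify_interaction(stream, square_regions())

    def test_every_detection_gets_exactly_one_record(self):
        rng = np.random.default_rng(12)
        tracks = {tid: random_track(rng, tid) for tid in range(5)}
        stream = stream_from_tracks(tracks)
        records = classify_interaction(stream, random_region_set(rng))
        assert len(records) == len(stream)
        keys = {(r.frame, r.track_id) for r in records}
        assert keys == {(d.frame, d.track_id) for d in stream}


class TestOracleEquivalence:
    def test_random_tracklets_agree_with_brute_force(self, default_params):
        rng = np.random.default_rng(99)
        regions = random_region_set(rng)
        for tid in range(60):
            track = random_track(rng, tid, step_px=float(rng.uniform(0, 25)))
            for frame, pose in track.items():
                assert classify_pose_still(pose, track, default_params)[0] == \
                    oracle_pose_still(pose, track, default_params)
                assert classify_pose_position(pose, regions, default_params)[0] == \
                    oracle_pose_by_table(pose, regions, default_params)


class TestMonotonicity:
    def test_raising_tau_never_unstills(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            track = random_track(rng, 0, step_px=float(rng.uniform(0, 30)))
            lo = InteractionParams()
            hi = InteractionParams(movement_subposes=tuple(
                replace(s, displacement_threshold=s.displacement_threshold * 3)
                for s in lo.movement_subposes))
            for frame, pose in track.items():
                if classify_pose_still(pose, track, lo)[0]:
                    assert classify_pose_still(pose, track, hi)[0]

    def test_region_superset_never_unpositions(self):
        rng = np.random.default_rng(22)
        for _ in range(30):
            regions = random_region_set(rng)
            grown = RegionSet(**{
                name: Region(name, tuple(
                    (cx + (x - cx) * 2.0, cy + (y - cy) * 2.0)
                    for x, y in regions[name].vertices
                    for cx, cy in [(
                        sum(v[0] for v in regions[name].vertices) / len(regions[name].vertices),
                        sum(v[1] for v in regions[name].vertices) / len(regions[name].vertices),
                    )]
                ))
                for name in ("wrists", "shoulders", "head")
            })
            pose = random_pose(rng, 0)
            if classify_pose_position(pose, regions)[0]:
                assert classify_pose_position(pose, grown)[0]
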