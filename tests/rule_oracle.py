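"""Independent brute-force evaluator of the interaction rules.

Written literally from the rule statements, keypoint by keypoint and
subpose by subpose, sharing no code path with the package's classifier:
point-in-polygon goes through shapely (so region tests here only use
simple polygons), displacement is recomputed from raw coordinates, and
counting is done with explicit loops. Used as the equivalence oracle.
"""

from __future__ import annotations

import math

from shapely.geometry import Point, Polygon

from tableside import InteractionParams, PoseDetection, RegionSet


def oracle_subpose_still(pose, track, spec, f_motion: int) -> bool:
    n_still = 0
    for name in spec.keypoints:
        kp = pose.keypoint(name)
        # "When a keypoint is not detected, or detected with a confidence
        # below a threshold, it is assumed to be still."
        if (not kp.detected) or kp.confidence < spec.confidence_threshold:
            n_still += 1
            continue
        prev_pose = track.get(pose.frame - f_motion)
        if prev_pose is None:
            n_still += 1
            continue
        prev_kp = prev_pose.keypoint(name)
        if not prev_kp.detected:
            n_still += 1
            continue
        displacement = math.sqrt((kp.x - prev_kp.x) ** 2 + (kp.y - prev_kp.y) ** 2)
        if displacement < spec.displacement_threshold:
            n_still += 1
    # still if at least M_keypoint of its keypoints yield displacement below tau
    return n_still >= spec.min_still_keypoints


def oracle_pose_still(pose, track, params: InteractionParams) -> bool:
    n = 0
    for spec in params.movement_subposes:
        if oracle_subpose_still(pose, track, spec, params.f_motion):
            n += 1
    # a pose is still if at least M_subpose of its subposes are
    return n >= params.min_still_subposes


def oracle_subpose_positioned(pose, regions: RegionSet, spec) -> bool:
    polygon = Polygon([(x, y) for x, y in regions[spec.region_name].vertices])
    n_inside = 0
    for name in spec.keypoints:
        kp = pose.keypoint(name)
        # keypoints below the confidence threshold are not counted in any region
        if not kp.detected or kp.confidence < spec.confidence_threshold:
            continue
        if polygon.covers(Point(kp.x, kp.y)):  # boundary-inclusive
            n_inside += 1
    # by the table if at least P_keypoint keypoints fall within the region
    return n_inside >= spec.min_inside_keypoints


def oracle_pose_by_table(pose, regions: RegionSet, params: InteractionParams) -> bool:
    n = 0
    for spec in params.position_subposes:
        if oracle_subpose_positioned(pose, regions, spec):
            n += 1
    return n >= params.min_positioned_subposes


def oracle_interacting(pose, track, regions, params) -> bool:
    # standing still in the correct position signals table interaction
    return oracle_pose_still(pose, track, params) and \
        oracle_pose_by_table(pose, regions, params)
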