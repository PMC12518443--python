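"""Rebuild track identities from raw, untracked pose detections.

The movement rule needs frame-to-frame correspondence. When the pose
stream carries no identities, a geometric tracker associates detections
across frames by object keypoint similarity (OKS), confident detections
first, and discards tracklets that never span two consecutive frames.
"""

from dataclasses import replace

from tableside import NoiseModel, PoseStream, build_tracklets, make_fixture, simulate

scripts, regions, _, n_frames = make_fixture("spectators", seed=0)
result = simulate(scripts, regions, NoiseModel.noiseless(), n_frames)

untracked = PoseStream(
    tuple(replace(d, track_id=None) for d in result.clean_stream), n_frames)
tracked = build_tracklets(untracked)

n_tracks = len({d.track_id for d in tracked})
print(f"detections in:  {len(untracked)}  (no identities)")
print(f"detections out: {len(tracked)}  in {n_tracks} tracklets")
print()
print(f"The scene scripts {len(scripts)} actors; on noise-free data the")
print("tracker recovers exactly one tracklet per actor, so every")
print("detection keeps a consistent identity for the displacement rule.")
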