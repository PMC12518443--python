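"""Simulate a busy operating-table scene and measure interaction.

Three actors: two staff at the table (one walks away mid-recording) and a
circulator pacing the room. The interaction rule marks a pose as
interacting with the table when it is both still and inside the annotated
wrist/shoulder/head regions; F is the share of all pose detections that
interact.
"""

from tableside import classify_interaction, fraction, make_fixture, simulate

scripts, regions, noise, n_frames = make_fixture("busy_table", seed=1)
result = simulate(scripts, regions, noise, n_frames)

records = classify_interaction(result.stream, regions)
f_table = fraction(records, "interacting")
f_moving = fraction(records, "moving")
f_truth = fraction(result.ground_truth)

print(f"pose detections        |P| = {len(records)}")
print(f"table interaction      F = {f_table:.4f}")
print(f"movement               F = {f_moving:.4f}")
print(f"ground truth (no noise) F = {f_truth:.4f}")
print()
print("F is the mean of the binary interaction indicator over all pose")
print("detections: here personnel spent about"
      f" {100 * f_table:.1f}% of detected pose-time interacting with the")
print("table, and the noisy measurement sits within a point of the")
print("noise-free ground truth.")
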