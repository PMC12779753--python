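"""Segment one synthetic trial into its four movement phases.

Wrist speed is computed frame-to-frame, smoothed over five frames, and
split into still/moving periods by 2-cluster k-means; the run pattern
still-moving-still-moving gives the reaction time and the reaching,
grip, and back-movement phases.
"""

import numpy as np

from graspkin import sample_ground_truth, segment_trial, simulate_trial

gt = sample_ground_truth(np.random.default_rng(3), "precision")
trial = simulate_trial(gt, noise_sd_mm=1.0, seed=3)
seg = segment_trial(trial.positions("wrist"), frame_rate_hz=60.0, seed=0)

print(f"parse ok: {seg.parse_ok}")
print(f"reaction time: {1000 * seg.reaction_time_s:.0f} ms "
      f"(generated: {1000 * gt.reaction_latency_s:.0f} ms)")
for phase in ("reaching", "grip", "back"):
    start, end = seg.phase_interval(phase)
    print(f"{phase:>9}: frames [{start}, {end})  "
          f"duration {1000 * (end - start) / 60:.0f} ms")
print(f"ground-truth boundaries: {gt.phase_boundary_frames}")
# recovered boundaries sit within a frame or two of the generated ones
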