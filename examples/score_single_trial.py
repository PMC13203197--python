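"""Score one resident–intruder trial from raw traces to the aggression index.

Simulates a single moderately aggressive individual at a reduced scale
(120 s at 10 fps instead of the full 1800 s at 30 fps), extracts behavior
bouts from the classifier confidence trace, computes kinematic features
from the pose track, and prints the per-trial summary and its index value.
"""

from crabtai import PipelineConfig, compute_tai, extract_all_bouts, summarize_trial
from crabtai.synthetic import SimParams, generate_profiles, simulate_trial

params = SimParams(n=1, rng_seed=42).scaled_to(120.0, fps=10.0)
config = PipelineConfig(t_total=120.0, fps=10.0)

profile = generate_profiles(params)[0]
print(f"latent aggressiveness a = {profile.a:.3f}")

pose, trace = simulate_trial(profile, params)
bouts = extract_all_bouts(trace, config)
for behavior, blist in bouts.items():
    print(f"{behavior:>14}: {len(blist):3d} bouts, "
          f"{sum(b.duration_s for b in blist):6.1f} s total")

summary = summarize_trial(trace, pose, config)
print(f"first attack at {summary.t_first:.1f} s")
print(f"movement X1 = {summary.rel_movement:.1f} carapace widths, "
      f"freezing X2 = {summary.freezing_s:.1f} s")
print(f"TAI = {compute_tai(summary, config.tai_weights):.4f}")
# The index combines the weighted fraction of the trial spent in each
# behavior with a reward for attacking early; 0 means no aggression at all.
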