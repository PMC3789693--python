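"""Segment one array's CGH log ratios and call copy-number categories.

Simulates a small paired cohort, runs circular binary segmentation on the
first sample, merges statistically indistinguishable levels, and categorizes
each segment against MAD-multiple thresholds (>5×MAD amplification,
>1.1×MAD gain, mirrored for losses).
"""

from cgsig import SimulationConfig, call_cnv, cbs_segment, merge_levels, simulate_cohort

sim = simulate_cohort(SimulationConfig(seed=11, n_samples=5, n_paired=3,
                                       n_chromosomes=1, markers_per_chromosome=300))
profile = sim.marker_profiles[0]

segmented = merge_levels(cbs_segment(profile, alpha=0.01, n_perm=500, seed=11), profile)
calls = call_cnv(segmented, profile)

print(f"sample {profile.sample_id}: {len(profile)} markers -> {len(segmented.segments)} segments")
print(f"array MAD = {calls[0].mad:.4f}  (gain/loss beyond ±{1.1*calls[0].mad:.3f}, "
      f"amplification/homozygous deletion beyond ±{5*calls[0].mad:.3f})")
for call in calls:
    s = call.segment
    print(f"  chr{s.chromosome}:{s.start}-{s.end}  n={s.n_markers:3d}  "
          f"mean={s.seg_mean:+.3f}  {call.category}")
# Each line is one constant-copy-number region; seg_mean is the average log2
# tumor/normal ratio of its markers, and the category is the MAD-threshold call.
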