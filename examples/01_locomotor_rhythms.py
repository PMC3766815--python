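"""Classify circadian rhythmicity of simulated DAM recordings.

Simulates a mixed cohort (half the flies carry a planted 24-h rhythm, half
are arrhythmic), slices the constant-darkness block, and scores each fly's
rhythm index (RI) from the correlogram.  A fly is rhythmic when RI > 0.2;
the period is the circadian correlogram peak.
"""

from circafly import analyze_rhythm, ri_histogram, slice_dd
from circafly.rhythm import results_frame
from circafly.synthetic import ActivitySimSpec, simulate_activity

spec = ActivitySimSpec(n_flies=16, fraction_rhythmic=0.5, seed=42)
series, truth = simulate_activity(spec)

results = [analyze_rhythm(slice_dd(s)) for s in series]
frame = results_frame(results).set_index("fly_id")
frame["planted_rhythmic"] = truth["rhythmic"]
print(frame[["ri", "period_h", "rhythmic", "planted_rhythmic"]].round(3))

called = frame["rhythmic"].sum()
print(f"\n{called}/{len(frame)} flies called rhythmic "
      f"({truth['rhythmic'].sum()} planted).")
print("Rhythmic calls should match the planted flags, with periods near "
      "24 h;\narrhythmic flies sit well below the 0.2 RI threshold.")
print("\nRI relative-frequency histogram (bimodal for a mixed cohort):")
print(ri_histogram(results).round(3))
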