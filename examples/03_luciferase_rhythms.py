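"""Detrend bioluminescence traces, fit the cosinor, compare group levels.

Two simulated groups of 16 flies each carry the same transcriptional
rhythm, but the second group emits at 70% of the first group's level.
The linear emission decay is removed per fly, the oscillation is fit with
a grid-search cosinor, and overall levels are compared with a bootstrap CI.
"""

import numpy as np

from circafly import assess_alive, compare_group_levels, cosinor_fit, detrend_trace
from circafly.synthetic import LuciferaseSimSpec, simulate_luciferase

ctrl, _ = simulate_luciferase(LuciferaseSimSpec(seed=1), id_prefix="ctrl")
dis, _ = simulate_luciferase(LuciferaseSimSpec(level_scale=0.7, seed=2),
                             id_prefix="dis")

fits = [cosinor_fit(detrend_trace(assess_alive(t))).fit for t in ctrl]
print("control cosinor fits (planted: period 24 h, rel. amplitude 0.30, "
      "acrophase 14 h):")
print(f"  period    {np.mean([f.period_h for f in fits]):6.2f} h")
print(f"  rel. amp  {np.mean([f.rel_amplitude for f in fits]):6.3f}")
print(f"  acrophase {np.mean([f.acrophase_h for f in fits]):6.2f} h")

cmp = compare_group_levels(ctrl, dis, seed=3)
print(f"\nemission reduction: {100 * cmp.fractional_reduction:.1f}% "
      f"(95% CI {100 * cmp.ci_low:.1f}-{100 * cmp.ci_high:.1f}%, "
      f"n = {cmp.n_a}/{cmp.n_b})")
print("The rhythm parameters match between groups while overall emission "
      "drops ~30%,\nthe dissociation expected when reporter output falls "
      "without clock impairment.")
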