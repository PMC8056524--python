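"""Power curves and treatment-effect sweeps for one trial scenario.

Shows how achieved power grows with per-arm n for the intermediate-burden
secondary-prevention design, and how the required n collapses for larger
treatment effects.
"""

import numpy as np

from amytrial import effect_size_sweep, power_curve, required_n_per_arm

mean_pct, sd_pct = 2.34, 0.72  # DVR cortical, intermediate burden

res = required_n_per_arm(mean_pct, sd_pct, reduction_fraction=0.20)
print(f"20% reduction: n per arm = {res.n_per_arm} "
      f"(power {res.achieved_power:.3f}; at n-1: {res.power_at_n_minus_1:.3f})")

ns, powers = power_curve(mean_pct, sd_pct, 0.20, np.arange(5, 61, 5))
print("\n  n  power")
for n, p in zip(ns, powers):
    print(f"{n:4d}  {p:.3f}" + ("  <- crosses 80%" if p >= 0.80 and powers[max(0, list(ns).index(n) - 1)] < 0.80 else ""))

print("\nRequired n per arm by treatment effect:")
for reduction, r in effect_size_sweep(mean_pct, sd_pct).items():
    print(f"  {int(100 * reduction):3d}% reduction -> n = {r.n_per_arm}")

print(
    "\nPower rises steeply with n around the minimal design, and a doubling\n"
    "of the treatment effect cuts the required sample roughly fourfold."
)
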