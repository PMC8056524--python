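"""Full synthetic-cohort analysis: simulate, fit, classify, power.

Generates the default 237-subject longitudinal cohort, fits random-slope
mixed models per metric, classifies accumulators against test-retest cutoffs
and prints the resulting group rates and per-arm sample sizes.
"""

from amytrial import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig())

print("Group annualized % change (fitted):")
for g in bundle["group_summaries"]:
    if g.population == "all" and g.roi == "cortical" and g.stratum != "whole":
        print(
            f"  {g.metric:4s} {g.stratum:18s} n={g.n:3d} "
            f"mean={g.mean_pct:5.2f} sd={g.sd_pct:4.2f} effect={g.effect_size:4.2f}"
        )

print("\nAccumulators (cortical composite):")
acc = bundle["accumulators"]
for metric in ("SUVR", "DVR"):
    row = acc[(acc["metric"] == metric) & (acc["roi"] == "cortical") & (acc["stratum"] == "all")]
    print(f"  {metric}: {int(row['n_accumulators'].iloc[0])} of {int(row['n'].iloc[0])}")
print(f"  accumulator by DVR but not SUVR: {len(bundle['discordant_dvr_not_suvr'])} subjects")

print("\nPer-arm sample sizes (whole population, cortical):")
sz = bundle["sample_sizes"]
sub = sz[(sz["population"] == "all") & (sz["roi"] == "cortical")]
print(sub[["scenario", "metric", "mean_pct", "sd_pct", "n_per_arm"]].to_string(index=False))

print(
    "\nIntermediate-burden subjects accumulate fastest (inverted-U), so the\n"
    "early-secondary scenario needs by far the fewest subjects per arm."
)
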