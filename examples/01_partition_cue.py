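"""Partition straw-derived C and compute microbial use efficiency of straw-C.

Simulates the default incubation (4 treatments x 2 timepoints, 3 labeled +
3 unlabeled replicates), partitions the CO2 and biomass pools with the
two-pool delta-13C mixing model, and compares treatments by one-way ANOVA
with a compact letter display.
"""

import numpy as np

from strawcue.isotope import partition_experiment, partition_replicates, treatment_anova
from strawcue.synthetic import ExperimentDesign, default_truth, generate_isotope_samples

design = ExperimentDesign(seed=1)
truth = default_truth(design)  # 1 permil delta-noise, 5% pool CV

samples = generate_isotope_samples(design, truth)
summary = partition_experiment(samples, seed=1)

print("Per-treatment straw-C use efficiency (mean over n=3, 95% t-interval):")
print(
    summary[
        ["treatment", "timepoint_days", "f_co2", "f_mbc", "cue", "ci_low", "ci_high"]
    ].to_string(index=False, float_format="%.3f")
)

reps = partition_replicates(samples)
day7 = reps[reps["timepoint_days"] == 7]
anova = treatment_anova({t: g["cue"].to_numpy() for t, g in day7.groupby("treatment")})
print(f"\nDay-7 ANOVA: F = {anova.f_statistic:.1f}, p = {anova.p_value:.2g}")
print("Letters (treatments sharing no letter differ at p < 0.05):")
for trt, letter in sorted(anova.letters.items()):
    mean = day7[day7["treatment"] == trt]["cue"].mean()
    print(f"  {trt:>4}: CUE = {mean:.3f}  {letter}")
print(
    "\nCUE is the fraction of decomposed straw-C retained in microbial biomass;"
    "\nthe cellulose-dominant amendment (CM) should carry the top letter at day 7."
)
truth_cm = truth.true_cue("CM", 7)
print(f"Generator ground truth for CM at day 7: {truth_cm:.3f}")
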