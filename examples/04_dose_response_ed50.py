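"""Hill dose-response fits and the ED50 field-effect comparison.

Simulates the full study design — doses 0-13 Gy, 20 mice per dose split
between a 0 T and a 1.5 T arm, with the 1.5 T arm's ED50 reduced by 3% —
then runs the analysis chain: 3-SD dichotomization at 5 months (4-month
fallback), percent-abnormal per dose group, per-arm Hill fits, and the
extra sum-of-squares F-test on the ED50 difference.
"""

from vivorate import cohort_stats as cs

config = cs.CohortConfig(seed=2024, field_multiplier=0.97)
records, truth = cs.simulate_cohort(config)
cutoffs = cs.cutoffs_from_config(config)

print("abnormality cutoffs (mean +/- 3 SD of controls):")
for c in cutoffs.values():
    print(f"  {c.metric:12s} {c.value:8.3f} ({c.direction})")

comp = cs.ed50_comparison_from_cohort(records, cutoffs, metric="rr_bpm")
print(f"\ntrue ED50s    : 0 T {truth.ed50_by_field[0.0]:.2f} Gy, "
      f"1.5 T {truth.ed50_by_field[1.5]:.2f} Gy")
print(f"fitted ED50s  : 0 T {comp.ed50_0t:.2f} Gy, 1.5 T {comp.ed50_15t:.2f} Gy")
print(f"fitted ratio  : {comp.ed50_15t / comp.ed50_0t:.3f} (truth 0.970)")
print(f"F({comp.df_num},{comp.df_den}) = {comp.f_stat:.2f}, p = {comp.p_value:.4f}")
# With 10 animals per dose per arm a 3% ED50 shift is at the edge of
# detectability; across many simulated cohorts the fitted ratio is
# unbiased while single cohorts scatter around it.
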