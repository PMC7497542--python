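"""Full model-informed EEG analysis on a reduced synthetic cohort.

Simulates a cohort, fits each subject's hybrid-model parameters, derives
trial-wise RPEs from the *fitted* parameters, generates synthetic EEG,
and tests which components' single-trial amplitudes track |RPE| in which
condition.  At full scale (29 subjects) the dissociation emerges: FRN and
theta couple to RPEs in both conditions, P3 only under the predictable
internal model.  This demo runs 10 subjects for speed.
"""

from twostep_eeg.pipeline import dissociation_summary, run_synthetic_study

result = run_synthetic_study(n_subjects=10, n_blocks=2, seed=5)

print("per-component 2x2 ANOVA on RPE-coupling slopes "
      "(rpe_sign x condition):")
for comp in ("frn", "p3", "theta", "delta"):
    av = result.coupling[comp]["anova"].set_index("effect")
    t = result.coupling[comp]["t_tests"].set_index("scope")
    print(f"  {comp:6s} condition effect: "
          f"F = {av.loc['condition', 'F']:6.2f}, "
          f"p = {av.loc['condition', 'p']:.3f} | "
          f"slope predictable = "
          f"{t.loc['condition:predictable', 'mean_slope']:+.3f}, "
          f"random = {t.loc['condition:random', 'mean_slope']:+.3f}")

summary = dissociation_summary(result)
print("\nP3 condition x expectancy interaction: "
      f"p = {summary['p3_condition_x_expectancy_p']:.4f}")
print("FRN condition x expectancy interaction: "
      f"p = {summary['frn_condition_x_expectancy_p']:.4f}")
print("\npattern checks (True = as expected under the generator's "
      "ground truth):")
for k, v in summary["pattern"].items():
    print(f"  {k}: {v}")
print("\n(small-n demo; group-level significance stabilizes at the "
      "full 29-subject scale)")
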