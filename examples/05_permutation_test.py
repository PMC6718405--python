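"""Group-level label-permutation test of the recognition decoder.

Each permutation shuffles the labels within subject, recomputes every
subject's leave-one-out AUROC and averages; the p-value is the fraction
of permuted group means reaching the actual one.  Desk scale here:
4 subjects, B = 30 (use B = 1000 for a recording-faithful run).
"""
from prestim import permutation_test_group, simulate_experiment
from prestim.preprocess import average_prestim, detrend_blocks

tasks = {}
for i, session in enumerate(simulate_experiment(4, seed=5, with_pupil=False)):
    X = average_prestim(detrend_blocks(session.epochs))
    real = session.trials["is_real"].to_numpy()
    yes = (session.trials["recognition_report"] == "yes").to_numpy()
    tasks[f"subject{i}"] = (X[real], yes[real].astype(int))

null = permutation_test_group(tasks, B=30, seed=6)
print(f"group mean AUROC: {null.actual_score:.3f}")
print(f"permutation p-value: {null.p_value:.4f} "
      f"(smoothed {null.p_value_smoothed:.4f}, B = {null.B})")
# With the default planted effects the actual group mean exceeds every
# permuted mean, so the raw exceedance fraction is 0; the smoothed
# (k+1)/(B+1) estimate bounds it away from zero.
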