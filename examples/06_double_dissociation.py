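"""The behavioral double dissociation at desk scale.

Trials are split into high/low predicted-probability groups per model
(general: P(recognition) > 0.5; specific: the objective category is the
strict argmax of the predicted category probabilities) and SDT metrics
are compared between groups.  The general process should move criterion
c, the specific process sensitivity d'.  8 subjects here; the acceptance
suite runs 20 experiments of 24 subjects.
"""
from prestim import (
    dissociation_table,
    simulate_experiment,
    subject_decision_variables,
    subject_dissociation,
)
from prestim.preprocess import average_prestim, detrend_blocks

results = []
for session in simulate_experiment(8, seed=7, with_pupil=False):
    X = average_prestim(detrend_blocks(session.epochs))
    dv = subject_decision_variables(X, session.trials)
    results.append(subject_dissociation(dv))

res = dissociation_table(results)
print(res.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
for metric in ("criterion", "d_prime"):
    for model in ("general", "specific"):
        t = res.tests[(model, metric)]
        print(f"{model:9s} {metric:9s} hi-vs-lo p = {t.p_value:.4g}")
# Expect a low p for (general, criterion) and (specific, d_prime) and
# unremarkable p-values for the two crossed contrasts.
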