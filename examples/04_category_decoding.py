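"""Decode the forthcoming stimulus category, separately for recognized
and unrecognized trials.

The specific-process hypothesis predicts above-chance category decoding
from pre-stimulus states in recognized trials only: a valid spontaneous
category prediction makes recognition more likely, so recognized trials
are enriched for states matching the upcoming category.
"""
from prestim import loo_cv_decode, simulate_session
from prestim.preprocess import average_prestim, detrend_blocks

session = simulate_session(seed=4)
X = average_prestim(detrend_blocks(session.epochs))
trials = session.trials
real = trials["is_real"].to_numpy()
yes = (trials["recognition_report"] == "yes").to_numpy()
objective = trials["objective_category"].astype(str).to_numpy()

for label, sel in (("recognized", real & yes), ("unrecognized", real & ~yes)):
    res = loo_cv_decode(X[sel], objective[sel])
    print(f"category decoding AUROC, {label} real trials "
          f"(n={int(sel.sum())}): {res.auroc:.3f}")
# Above-chance decoding in recognized but not unrecognized trials is the
# signature of the specific process: category information in spontaneous
# activity matters only when it turns out to be valid.
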