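"""Decode forthcoming recognition from pre-stimulus brain states.

L2 logistic regression (C = 1) with leave-one-out cross-validation on
real-image trials, plus the activation-pattern transform A = Sigma beta
that turns decoder weights back into an interpretable sensor pattern.
"""
import numpy as np

from prestim import activation_pattern, loo_cv_decode, simulate_session
from prestim.preprocess import average_prestim, detrend_blocks

session = simulate_session(seed=3)
X = average_prestim(detrend_blocks(session.epochs))
real = session.trials["is_real"].to_numpy()
yes = (session.trials["recognition_report"] == "yes").to_numpy()

res = loo_cv_decode(X[real], yes[real].astype(int), pos_label=1)
print(f"recognition decoding AUROC (real trials, LOO-CV): {res.auroc:.3f}")

pattern = activation_pattern(res.decoder, X[real])
w = session.w_g / np.linalg.norm(session.w_g)
a = pattern.A[0] / np.linalg.norm(pattern.A[0])
print(f"cosine(activation pattern, planted arousal pattern): {abs(a @ w):.3f}")
# AUROC well above 0.5 shows pre-stimulus states predict the upcoming
# report; the activation pattern recovers the planted sensor expression
# of the general process, which raw decoder weights need not.
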