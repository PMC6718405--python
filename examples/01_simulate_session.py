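"""Generate one synthetic recognition-threshold session and inspect it.

The session has the published design: 4 categories x (5 real + 1
scrambled) images x 15 repetitions = 360 trials in 10 blocks, with
behavior driven by a general arousal-like latent and a category-
preference latent.
"""
from prestim import simulate_session

session = simulate_session(seed=1)
trials = session.trials

real = trials["is_real"]
yes = trials["recognition_report"] == "yes"
print(f"trials: {len(trials)} ({int(real.sum())} real, {int((~real).sum())} scrambled)")
print(f"unique real images: {trials.loc[real, 'image_id'].nunique()}")
print(f"recognition rate:  real {yes[real].mean():.3f}, scrambled {yes[~real].mean():.3f}")
rec_real = real & yes
acc = (trials.loc[rec_real, "category_report"].astype(str)
       == trials.loc[rec_real, "objective_category"].astype(str)).mean()
print(f"categorization accuracy in recognized real trials: {100 * acc:.1f}%")
print(f"epochs array: {session.epochs.values.shape} (trial x sensor x time)")
# Real recognition sits near the 50% threshold, scrambled recognition is
# much rarer, and recognized categorization is far above the 25% chance
# level - the operating point the decoding analyses assume.
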