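"""Build a balanced reach-to-grasp session ledger.

The reference design: 7 participants x 4 runs x 15 blocks (5 per
condition) x 3 trials, targets on for 2.5 s, inter-trial intervals drawn
from a truncated exponential (2.5-10.5 s offset-to-onset, mean 4.5 s).
"""

from graspkin import SessionSpec, build_session

spec = SessionSpec()
ledger = build_session(spec, seed=1)

print(f"total trials: {len(ledger)}")
print("trials per condition per participant:")
print(ledger.groupby(["participant", "trial_type"]).size().unstack().head())
gaps = ledger.groupby(["participant", "run"])["onset"].diff().dropna()
print(f"onset-to-onset interval: {gaps.mean():.2f} s mean "
      f"(range {gaps.min():.2f}-{gaps.max():.2f} s)")
# 1260 trials in all, 60 per condition per participant; onset-to-onset
# gaps average ~7 s (the 2.5 s target plus the ~4.5 s mean jitter).
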