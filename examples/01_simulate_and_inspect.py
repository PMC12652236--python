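"""Generate a synthetic oddball session and inspect its planted structure.

One frequent ("standard") and one rare ("deviant") screen position, 2 s
stimuli with 5 s intervals; the evoked-response gain adapts with repeated
presentations at a position, so deviants and early trials respond strongly.
"""

import numpy as np

from novelfp import SessionConfig, generate_oddball_session

cfg = SessionConfig(fs_lfp=2000.0, seed=42)  # 2 kHz keeps the file small
session = generate_oddball_session(cfg)

log = session.log
gains = session.truth.gains
std = log.conditions == "standard"
print(f"trials: {len(log)} ({(~std).sum()} deviant), "
      f"stimulus {log.offsets[0]-log.onsets[0]:.0f} s, "
      f"interval {log.onsets[1]-log.offsets[0]:.0f} s")
print(f"planted gains -- deviant: {gains[~std].mean():.2f}, "
      f"first 10 trials: {gains[:10].mean():.2f}, "
      f"late standards: {gains[std & (np.arange(len(log)) > 60)].mean():.2f}")
print(f"LFP: {session.recording.n_samples} samples at {session.recording.fs:.0f} Hz, "
      f"sd {session.recording.voltage.std():.0f} uV")
# deviant and early-trial responses are large; repeated standards adapt to ~1
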