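"""Calibration of the significance conventions on effect-free sessions.

Sessions with no planted novelty (all gains equal) are pushed through the
full pipeline; the rate at which nPC1(Deviant) exceeds 2 checks the
convention that nPC1 > 2 means p < 0.05.  A small run for illustration —
the full 400-session version lives in scripts/acceptance.py.
"""

import numpy as np

from novelfp.experiments import null_calibration

out = null_calibration(n_sessions=25, seed=9)
print(f"null sessions: {out['n_sessions']}")
print(f"fraction with nPC1(Deviant) > 2: {out['fraction_npc1_gt2']:.2f}  (expect <= 0.05)")
print(f"fraction with permutation p < 0.05: {out['fraction_p_lt_05']:.2f}  (nominal 0.05; "
      "mildly inflated because the axis is fit with the trial labels)")
print(f"largest null nPC1: {out['npc1_deviant'].max():.2f}")
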