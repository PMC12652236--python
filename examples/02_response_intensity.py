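"""Response intensity (PC1/nPC1) and the within-session permutation test.

The 80-580 ms response window of every trial is downsampled to 400 Hz
(200 points), a principal axis is fit on balanced standard/deviant subsets
(100 resamples), all trials are projected, and the deviant group is tested
against the standard pool by shuffling trial identities 10,000 times.
"""

from novelfp import (
    SessionConfig,
    extract_response_matrix,
    fit_balanced_pc1,
    generate_oddball_session,
    project_scores,
    session_permutation_test,
)

session = generate_oddball_session(SessionConfig(fs_lfp=2000.0, seed=7))
matrix = extract_response_matrix(session.recording, session.log)
print(f"response matrix: {matrix.data.shape[0]} trials x {matrix.data.shape[1]} samples, "
      f"{int(matrix.artifact_mask.sum())} artifact trials removed")

model = fit_balanced_pc1(matrix, session.log, seed=1)
scores = project_scores(matrix, model, session.log)
for group in ("Deviant", "First10", "1After"):
    print(f"nPC1({group}) = {scores.npc1(group):6.2f}", end="")
    res = session_permutation_test(scores, group, seed=2)
    print(f"   permutation p = {res.p_value:.4g}")
# nPC1 > 2 marks a session-level novelty effect; 1After behaves like a
# plain standard, so its nPC1 should sit near 0
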