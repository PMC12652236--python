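# novelfp

Analysis of **spatial-novelty coding in cortical LFP** during visual
oddball experiments with head and eye tracking — plus a synthetic-session
generator with planted ground truth, so the whole chain is testable
without access to recordings.

The scientific question the pipeline serves: when a visual stimulus
appears at a rare screen position, does cortex respond more strongly than
to the frequent position — and is that novelty response keyed to the
*allocentric* position on the screen (invariant to where the animal is
looking) or to the *retinal* position (so any never-before-used viewing
angle would look novel)?  The package is written for systems
neuroscientists analysing freely viewing animals (the motivating
preparation is the reptilian dorsal visual cortex) whose head and eye
positions are tracked with keypoint estimators.

## The statistic at its core

Per trial the 80–580 ms post-onset LFP window is downsampled to 400 Hz
(200 points) and trials with |V| > 900 µV are discarded.  Response
intensity is the projection onto a first principal axis fit on
class-balanced subsets — all 20 deviant trials plus 20 random standards,
repeated 100× and averaged — so the abundant standards cannot dominate the
decomposition.  Group scores are normalised by the standard distribution:

    nPC1_X = (mPC1_X − mPC1_Standard) / sPC1_Standard

with nPC1 > 2 the session-level significance convention.  Inference is by
permutation: within a session, trial identities are shuffled 10,000 times;
across sessions, session labels are.  Around this sit the gaze geometry
(head bearing from two keypoints; eye angle ψ_k = arccos(k/r_socket) from
an ellipse fit to the pupil outline, rotated by the visual-streak angle ρ;
viewing angle θ + φ_x; the ±15° left/right split and the ≥ 5° first-view
rule) and the movement control (sliding-window activity magnitudes of
movement-locked vs stimulus-locked LFP).

## Worked example

```python
from novelfp import (SessionConfig, generate_oddball_session,
                     extract_response_matrix, fit_balanced_pc1,
                     project_scores, session_permutation_test)

session = generate_oddball_session(SessionConfig(fs_lfp=2000.0, seed=7))
matrix  = extract_response_matrix(session.recording, session.log)
model   = fit_balanced_pc1(matrix, session.log, seed=1)
scores  = project_scores(matrix, model, session.log)
for group in ("Deviant", "First10", "1After"):
    res = session_permutation_test(scores, group, seed=2)
    print(group, round(scores.npc1(group), 2), res.p_value)
```

prints

```
Deviant 8.84 9.999000099990002e-05
First10 4.11 9.999000099990002e-05
1After 0.13 0.5424
```

i.e. the deviant position and the unadapted first ten trials evoke
responses far above the standard distribution (nPC1 ≫ 2, permutation
p < 10⁻⁴, the smallest level 10,000 shuffles can report), while the first
standard after a deviant behaves like any standard — novelty here is
position-specific, not a global reset.  The `examples/` directory has one
narrative script per capability (simulation, response intensity, gaze
geometry, spatial control, movement comparison, null calibration); each
prints its numbers with a line on what they mean.  A thin CLI
(`novelfp simulate / analyze / group`) covers shell use on session
directories.

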