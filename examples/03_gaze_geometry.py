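"""Head, eye and viewing angles from tracked keypoints.

Head direction comes from the two-point bearing on the top camera; eye
direction from an ellipse fit to the pupil outline and the arccos model of
a spherical eye in its socket, rotated into visual-streak coordinates.
The left/right split, first-view flags and movement speeds drive the
gaze-invariance analyses.
"""

import numpy as np

from novelfp import SessionConfig, build_gaze_table, generate_oddball_session
from novelfp.permutation import pearson_correlation

session = generate_oddball_session(SessionConfig(fs_lfp=2000.0, n_trials=60, seed=5))
table = build_gaze_table(session.head, session.log, session.eye, session.annotation)
df = table.df

print(f"head angle range: [{df['theta'].min():.1f}, {df['theta'].max():.1f}] deg "
      f"(0 = session mean)")
print(f"angle groups: {(df['angle_group']=='left').sum()} left, "
      f"{(df['angle_group']=='right').sum()} right "
      f"(|theta| > 15 deg, strict)")
print(f"first-view trials (>= 5 deg from all previous): {int(df['is_first_view'].sum())}")
ok = df[["theta", "phi_x"]].dropna()
r, p = pearson_correlation(ok["theta"], ok["phi_x"])
print(f"head-eye correlation: r = {r:.2f} (p = {p:.2g})")
print(f"mean head speed 80-480 ms post-onset: {np.nanmean(df['head_speed']):.1f} px/s")
# viewing angle = theta + phi_x; near-zero head-eye correlation means the
# eyes do not counter-rotate to cancel head turns
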