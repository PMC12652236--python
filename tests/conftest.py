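import numpy as np
import pandas as pd
import pytest

from novelfp.experiments import fast_session_config
from novelfp.response import extract_response_matrix, fit_balanced_pc1, project_scores
from novelfp.session_io import TrialLog
from novelfp.synthetic import generate_oddball_session


def make_log(conditions, period_s=7.0, stim_s=2.0, start_s=5.0):
    """Trial log with the given condition sequence and regular timing."""
    n = len(conditions)
    onsets = start_s + period_s * np.arange(n)
    return TrialLog(
        pd.DataFrame(
            {
                "trial_index": np.arange(n),
                "onset_s": onsets,
                "offset_s": onsets + stim_s,
                "condition": conditions,
                "pos_col": [0 if c == "deviant" else 1 for c in conditions],
                "pos_row": [0 if c == "deviant" else 1 for c in conditions],
            }
        )
    )


@pytest.fixture(scope="session")
def planted_session():
    """One default planted-novelty session at the reduced LFP rate."""
    cfg = fast_session_config(seed=1234)
    return generate_oddball_session(cfg)


@pytest.fixture(scope="session")
def planted_scores(planted_session):
    s = planted_session
    matrix = extract_response_matrix(s.recording, s.log)
    model = fit_balanced_pc1(matrix, s.log, seed=99)
    table = project_scores(matrix, model, s.log)
    return s, matrix, model, table
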