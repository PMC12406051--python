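import numpy as np
import pandas as pd
import pytest

from itemsl.design import EventTable, build_trialwise_design


def make_events(onsets, durations=2.0, conditions=None, session=0, **extra):
    onsets = np.asarray(onsets, float)
    durations = np.broadcast_to(np.asarray(durations, float), onsets.shape)
    if conditions is None:
        conditions = ["A"] * len(onsets)
    df = pd.DataFrame(
        {"session": session, "onset": onsets, "duration": durations, "condition": conditions}
    )
    for k, v in extra.items():
        df[k] = v
    return EventTable(df, modulators=list(extra.keys()))


@pytest.fixture
def short_isi_design():
    """12 trials, 2 s stimuli, ~2 s gaps: heavily overlapping regressors."""
    rng = np.random.default_rng(0)
    onsets = np.cumsum(np.concatenate([[0.0], 2.0 + rng.uniform(0, 4, 11)]))
    conds = list("ABABABABABAB")
    events = make_events(onsets, 2.0, conds)
    n_scans = int(np.ceil((onsets[-1] + 2 + 32) / 2.0))
    return events, build_trialwise_design(events, n_scans, 2.0)
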