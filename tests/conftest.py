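import numpy as np
import pytest

import myoreg as mr


@pytest.fixture(scope="session")
def bank():
    return mr.design_filter_bank(mr.FilterSpec(), 2000.0)


@pytest.fixture(scope="session")
def dircon_schedule():
    return mr.build_schedule(mr.DIRCON)


@pytest.fixture(scope="session")
def mapcon_schedule():
    return mr.build_schedule(mr.MAPCON)


@pytest.fixture(scope="session")
def noisefree_session(dircon_schedule, bank):
    """Direct-control calibration with a deterministic envelope: no effort
    jitter, no per-channel wander, no interference; carrier noise remains."""
    spec = mr.SessionSpec(seed=1, effort_jitter_rel=0.0, channel_wander_rel=0.0)
    mixing = mr.make_mixing(16, seed=1, interference_amp=0.0)
    raw, traj, mix = mr.make_session(dircon_schedule, 16, seed=1, spec=spec, mixing=mixing)
    sigma = mr.process_batch(raw, bank)
    return raw, traj, mix, sigma


@pytest.fixture(scope="session")
def jittered_session(dircon_schedule, bank):
    """Direct-control calibration at the default study conditions."""
    spec = mr.SessionSpec(seed=1)
    raw, traj, mix = mr.make_session(dircon_schedule, 16, seed=1, spec=spec)
    sigma = mr.process_batch(raw, bank)
    return raw, traj, mix, sigma


def held_segment_frames(schedule, fs=100.0, trim_s=1.0):
    """Frame indices inside every segment after edge trimming."""
    idx = []
    for _, start_s, dur_s in schedule.segments:
        i0 = int(round((start_s + trim_s) * fs))
        i1 = int(round((start_s + dur_s - trim_s) * fs))
        idx.append(np.arange(i0, i1))
    return np.concatenate(idx)
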