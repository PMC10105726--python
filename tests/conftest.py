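import numpy as np
import pandas as pd
import pytest

from rewardops.config import CohortConfig, DRLMParams, PhotoParams, REVParams
from rewardops.io import EventLog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def drlm_params():
    return DRLMParams()


@pytest.fixture
def rev_params():
    return REVParams()


@pytest.fixture
def photo_params():
    return PhotoParams()


def make_log(rows, session_type="DRLM", group="CON", mouse_id="toy01", test_index=1):
    return EventLog(
        mouse_id=mouse_id,
        group=group,
        session_type=session_type,
        test_index=test_index,
        events=pd.DataFrame(rows, columns=["event", "time_s"]),
    )


@pytest.fixture
def toy_drlm_log():
    """Two-trial DRLM log: DS at t=100 responded at t=103; DS at t=160
    without a response; two ITI feeder responses in between."""
    rows = [
        ("ds_on", 100.0),
        ("feeder", 103.0),
        ("pellet", 103.5),
        ("ds_off", 104.0),
        ("feeder", 120.0),
        ("feeder", 140.0),
        ("ds_on", 160.0),
        ("ds_off", 190.0),
    ]
    return make_log(rows)


def small_cohort_config(seed=0, n_per_group=2, raw_rate=100.0, n_trials=20,
                        n_drlm=1, n_rev=1):
    """Scaled-down cohort for fast end-to-end tests (raw rate 100 Hz still
    exceeds twice the 20-Hz analysis rate)."""
    cfg = CohortConfig(
        n_per_group=n_per_group, seed=seed, n_drlm_tests=n_drlm, n_rev_tests=n_rev
    )
    cfg.drlm.n_trials = n_trials
    cfg.photo.raw_rate_hz = raw_rate
    cfg.photo.tail_s = 10.0
    return cfg
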