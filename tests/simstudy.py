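"""Shared helper for the end-to-end calibration studies: generate a scaled
cohort, run events -> trace synthesis -> segmentation -> z-scoring ->
aggregation -> mixed ANOVA, and return the group-effect p-values.

Scaled study conditions (chosen once): raw trace rate 100 Hz (still five
times the 20-Hz analysis rate), 20-trial DRLM sessions, one test day, no
REV sessions.  The analysed quantity is the DS-on phase activity of
responded trials 11-20, the contrast the analysis is most sensitive to.
"""

import copy

import pandas as pd

from rewardops.config import CohortConfig
from rewardops.photometry import activity_long, aggregate, session_phase_activity
from rewardops.simulate import Cohort, generate_cohort
from rewardops.stats import AnovaSpec, mixed_anova


def study_config(seed: int, n_per_group: int, null: bool) -> CohortConfig:
    cfg = CohortConfig(
        n_per_group=n_per_group, seed=seed, n_drlm_tests=1, n_rev_tests=0
    )
    cfg.drlm.n_trials = 20
    cfg.photo.raw_rate_hz = 100.0
    cfg.photo.tail_s = 10.0
    if null:
        # zero group effect: CSS inherits every CON parameter
        cfg.drlm.p_response["CSS"] = cfg.drlm.p_response["CON"]
        cfg.drlm.iti_rate_hz["CSS"] = cfg.drlm.iti_rate_hz["CON"]
        cfg.drlm.latency_median_s["CSS"] = copy.deepcopy(
            cfg.drlm.latency_median_s["CON"]
        )
        cfg.photo.amp["CSS"] = dict(cfg.photo.amp["CON"])
    return cfg


def dson_group_pvalues(seed: int, n_per_group: int, null: bool):
    """(p_group, p_group_x_interval) for the trials 11-20 DS-on analysis of
    one simulated cohort; None when too few complete subjects."""
    cfg = study_config(seed, n_per_group, null)
    cohort = generate_cohort(cfg, photometry=True)
    frames = []
    for log in cohort.logs:
        df, _ = session_phase_activity(log, cohort.traces[Cohort.trace_key(log)])
        if not df.empty:
            frames.append(df)
    per_trial = pd.concat(frames, ignore_index=True)
    agg = aggregate(per_trial, "ds_on", window=(11, 20), responded_only=True)
    if agg.empty:
        return None
    long = activity_long(agg, "ds_on")
    spec = AnovaSpec(
        dv="z", subject="mouse_id", between="group", within=("interval",)
    )
    try:
        table = mixed_anova(long, spec).set_index("effect")
    except ValueError:
        return None
    return float(table.loc["group", "p"]), float(table.loc["group:interval", "p"])
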