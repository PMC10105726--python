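"""Extract per-trial, per-phase z-scored calcium activity for one session.

A DRLM session and its raw trace are generated, the trace is down-sampled
to 20 Hz, and each responded trial's DS-on phase (DS onset to feeder
response) is z-scored against its own 10-s pre-onset baseline and
time-normalized onto 10 equal intervals.
"""

from rewardops import CohortConfig, Cohort, generate_cohort, session_phase_activity
from rewardops.photometry import aggregate

cfg = CohortConfig(n_per_group=1, seed=7, n_rev_tests=0, n_drlm_tests=1)
cfg.photo.raw_rate_hz = 100.0  # scaled-down raw rate for a quick demo
cohort = generate_cohort(cfg)

log = next(l for l in cohort.logs if l.group == "CON")
per_trial, qc = session_phase_activity(log, cohort.traces[Cohort.trace_key(log)])

agg = aggregate(per_trial, "ds_on", window=(1, 20), responded_only=True)
bins = agg[[f"bin_{i}" for i in range(1, 11)]].iloc[0]
print(f"mouse {log.mouse_id}: {int(agg['n_trials'].iloc[0])} responded trials 1-20")
print("DS-on phase, 10 time-normalized interval means of z:")
print("  " + "  ".join(f"{b:5.2f}" for b in bins))
print()
print("The transient evoked at DS onset makes early intervals strongly")
print("positive (several baseline SDs); activity decays toward baseline by")
print("the feeder response.  Trials excluded by QC:", qc.degenerate_baseline)
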