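"""Trial reconstruction and behavioural statistics for DRLM and REV sessions.

DRLM (discriminative reward learning-memory): a tone discriminative stimulus
(DS, max 30 s) signals that a feeder response delivers a sucrose pellet;
feeder responses during the variable inter-trial intervals (ITIs) are counted
but without consequence.  The per-test measures are the number of pellets
obtained (DS trials with a response), the median DS response latency (30 s
imputed for no-response trials), the median ITI response interval
(ITI duration / feeder responses in that ITI) and the discriminative learning
ratio (median ITI interval / median DS latency), all over the first 20 trials
of each test.

REV (reward-to-effort valuation): nose-pokes at an operant stimulus are
reinforced on a progressive-ratio schedule (1, 5, 9, 13, ... in blocks of
five trials).  Completing a ratio triggers a 1-s tone DS plus pellet
delivery; the measures are total operant responses, pellets earned, final
ratio attained, median pellet retrieval latency and median post-reinforcement
pause, plus per-block operant and post-operant phase durations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventLog, MalformedLogError

__all__ = [
    "TrialRecordDRLM",
    "TrialRecordREV",
    "MetricsDRLM",
    "MetricsREV",
    "segment_drlm",
    "segment_rev",
    "select_trials",
    "drlm_metrics",
    "rev_metrics",
    "required_ratio",
    "drlm_metrics_table",
    "rev_metrics_table",
]

logger = logging.getLogger(__name__)

DS_MAX_S = 30.0
ITI_MAX_S = 80.0


@dataclass
class TrialRecordDRLM:
    """One reconstructed DRLM trial with its preceding ITI."""

    index: int  # 1-based
    ds_onset_s: float
    ds_offset_s: float
    responded: bool
    #: response - onset; imputed to 30 s when not responded
    latency_s: float
    iti_start_s: float
    iti_end_s: float
    iti_responses: int
    #: feeder-response times within the preceding ITI
    iti_response_times_s: tuple[float, ...] = ()
    #: time of the responding feeder event (None when not responded)
    feeder_time_s: float | None = None

    @property
    def iti_duration_s(self) -> float:
        return self.iti_end_s - self.iti_start_s


@dataclass
class TrialRecordREV:
    """One reconstructed progressive-ratio trial."""

    index: int  # 1-based
    required_ratio: int
    operant_times_s: tuple[float, ...]
    completed: bool
    ds_onset_s: float | None = None  # at ratio completion
    feeder_time_s: float | None = None


@dataclass
class MetricsDRLM:
    pellets: int
    median_latency_s: float
    median_iti_interval_s: float
    learning_ratio: float
    n_trials: int
    #: alternative learning-ratio mode: median of per-trial interval/latency
    learning_ratio_per_trial: float = math.nan
    iti_interval_imputed: bool = False


@dataclass
class MetricsREV:
    total_operant: int
    pellets_earned: int
    final_ratio: int
    retrieval_latency_s: float
    post_reinforcement_pause_s: float
    #: per-PR-block median phase durations (required ratio -> seconds)
    operant_phase_s: dict[int, float] = field(default_factory=dict)
    post_operant_phase_s: dict[int, float] = field(default_factory=dict)


def required_ratio(trial_index: int, base: int = 1, step: int = 4, block: int = 5) -> int:
    """Responses required for trial ``trial_index`` of the progressive-ratio
    schedule: 1 for trials 1-5, 5 for 6-10, 9 for 11-15, 13 for 16-20, ...

    Equals ``step * floor((index - 1) / block) + base``.
    """
    if trial_index < 1:
        raise ValueError(f"trial_index must be >= 1, got {trial_index}")
    return step * ((trial_index - 1) // block) + base


def segment_drlm(log: EventLog, ds_max_s: float = DS_MAX_S) -> list[TrialRecordDRLM]:
    """Reconstruct DRLM trials from an event log.

    A trial is responded iff a feeder event falls in ``[ds_on, ds_on + 30)``;
    the first such event defines the latency.  The ITI preceding trial *k*
    runs from the previous trial's DS offset (session start for trial 1) to
    trial *k*'s DS onset; feeder responses within it are counted.
    """
    log.validate()
    ev = log.events
    ons = ev.loc[ev["event"] == "ds_on", "time_s"].to_numpy()
    offs = ev.loc[ev["event"] == "ds_off", "time_s"].to_numpy()
    feeders = ev.loc[ev["event"] == "feeder", "time_s"].to_numpy()
    if len(offs) != len(ons):
        raise MalformedLogError(
            f"{len(ons)} DS onsets but {len(offs)} DS offsets"
        )
    if np.any(offs <= ons):
        raise MalformedLogError("DS offset precedes its onset")
    if len(ons) > 1 and np.any(ons[1:] < offs[:-1]):
        raise MalformedLogError("overlapping DS windows")

    trials: list[TrialRecordDRLM] = []
    prev_off = 0.0
    for k, (on, off) in enumerate(zip(ons, offs), start=1):
        in_window = feeders[(feeders >= on) & (feeders < on + ds_max_s)]
        responded = in_window.size > 0
        if responded:
            feeder_t = float(in_window[0])
            latency = feeder_t - on
        else:
            feeder_t = None
            latency = ds_max_s
        iti_mask = (feeders >= prev_off) & (feeders < on)
        iti_times = tuple(float(t) for t in feeders[iti_mask])
        trials.append(
            TrialRecordDRLM(
                index=k,
                ds_onset_s=float(on),
                ds_offset_s=float(off),
                responded=responded,
                latency_s=float(latency),
                iti_start_s=float(prev_off),
                iti_end_s=float(on),
                iti_responses=len(iti_times),
                iti_response_times_s=iti_times,
                feeder_time_s=feeder_t,
            )
        )
        prev_off = float(off)
    return trials


def segment_rev(
    log: EventLog, base: int = 1, step: int = 4, block: int = 5
) -> list[TrialRecordREV]:
    """Partition REV operant events into progressive-ratio trials.

    Pellet deliveries delimit completed trials; trailing operant responses
    without a delivery form one incomplete final trial.
    """
    log.validate()
    ev = log.events
    operants = ev.loc[ev["event"] == "operant", "time_s"].to_numpy()
    pellets = ev.loc[ev["event"] == "pellet", "time_s"].to_numpy()
    ds_ons = ev.loc[ev["event"] == "ds_on", "time_s"].to_numpy()
    feeders = ev.loc[ev["event"] == "feeder", "time_s"].to_numpy()

    trials: list[TrialRecordREV] = []
    for k, p in enumerate(pellets, start=1):
        need = required_ratio(k, base, step, block)
        # operant responses belonging to trial k: those after the previous
        # trial's completion and at/before this pellet delivery
        lo = 0.0 if not trials else (trials[-1].feeder_time_s or trials[-1].ds_onset_s or 0.0)
        pokes = operants[(operants > lo) & (operants <= p)]
        if pokes.size < need:
            raise MalformedLogError(
                f"pellet {k} delivered after {pokes.size} operant responses; "
                f"schedule requires {need}"
            )
        ds_candidates = ds_ons[(ds_ons >= pokes[-1]) & (ds_ons <= p)]
        ds_onset = float(ds_candidates[0]) if ds_candidates.size else float(pokes[-1])
        later_feeders = feeders[feeders >= p]
        feeder_t = float(later_feeders[0]) if later_feeders.size else None
        trials.append(
            TrialRecordREV(
                index=k,
                required_ratio=need,
                operant_times_s=tuple(float(t) for t in pokes),
                completed=True,
                ds_onset_s=ds_onset,
                feeder_time_s=feeder_t,
            )
        )
    # trailing incomplete trial
    lo = 0.0 if not trials else (trials[-1].feeder_time_s or trials[-1].ds_onset_s)
    trailing = operants[operants > lo] if trials else operants
    if trailing.size:
        k = len(trials) + 1
        trials.append(
            TrialRecordREV(
                index=k,
                required_ratio=required_ratio(k, base, step, block),
                operant_times_s=tuple(float(t) for t in trailing),
                completed=False,
            )
        )
    return trials


def select_trials(
    trials: list,
    first_k: int | None = None,
    window: tuple[int, int] | None = None,
    responded_only: bool = False,
) -> list:
    """Order-preserving trial filters; composes range and response filters.

    ``first_k`` keeps trials 1..k; ``window`` keeps the inclusive 1-based
    index range; ``responded_only`` keeps DRLM trials with a feeder response
    (REV: completed trials).  An empty result is legal.
    """
    out = trials
    if first_k is not None:
        out = [t for t in out if t.index <= first_k]
    if window is not None:
        lo, hi = window
        out = [t for t in out if lo <= t.index <= hi]
    if responded_only:
        out = [
            t
            for t in out
            if (t.responded if hasattr(t, "responded") else t.completed)
        ]
    return out


def _median(values) -> float:
    return float(np.median(np.asarray(values, dtype=float))) if len(values) else math.nan


def drlm_metrics(trials: list[TrialRecordDRLM]) -> MetricsDRLM:
    """Per-test DRLM statistics over a trial subset.

    The median latency is taken over all trials in the subset, with the 30-s
    imputation for non-responded trials.  Per-ITI response intervals
    (duration / responses) are defined only for ITIs with at least one
    response; if no ITI has any response the interval is imputed to the
    maximum ITI duration (80 s) and a warning is logged.
    """
    if not trials:
        raise ValueError("drlm_metrics requires a non-empty trial subset")
    pellets = sum(t.responded for t in trials)
    med_latency = _median([t.latency_s for t in trials])
    intervals = [
        t.iti_duration_s / t.iti_responses for t in trials if t.iti_responses > 0
    ]
    imputed = False
    if intervals:
        med_interval = _median(intervals)
    else:
        med_interval = ITI_MAX_S
        imputed = True
        logger.warning(
            "no ITI with a feeder response in subset; imputing the %.0f-s "
            "maximum ITI duration as the median ITI interval",
            ITI_MAX_S,
        )
    per_trial = [
        (t.iti_duration_s / t.iti_responses) / t.latency_s
        for t in trials
        if t.iti_responses > 0 and t.latency_s > 0
    ]
    return MetricsDRLM(
        pellets=int(pellets),
        median_latency_s=med_latency,
        median_iti_interval_s=med_interval,
        learning_ratio=med_interval / med_latency,
        learning_ratio_per_trial=_median(per_trial),
        n_trials=len(trials),
        iti_interval_imputed=imputed,
    )


def rev_metrics(
    trials: list[TrialRecordREV], pr_block: int | None = None
) -> MetricsREV:
    """Per-test REV statistics.

    ``pr_block`` (a required-ratio value, e.g. 5) restricts the per-block
    phase-duration medians to that block; blocks never reached yield NaN.
    """
    completed = [t for t in trials if t.completed]
    total_operant = sum(len(t.operant_times_s) for t in trials)
    final_ratio = max((t.required_ratio for t in completed), default=0)
    retrieval = _median(
        [t.feeder_time_s - t.ds_onset_s for t in completed if t.feeder_time_s is not None]
    )
    pauses = []
    for t, nxt in zip(trials[:-1], trials[1:]):
        if t.completed and t.feeder_time_s is not None and nxt.operant_times_s:
            pauses.append(nxt.operant_times_s[0] - t.feeder_time_s)
    ratios = sorted({t.required_ratio for t in completed})
    if pr_block is not None:
        ratios = [pr_block]
    op_phase: dict[int, float] = {}
    post_phase: dict[int, float] = {}
    for r in ratios:
        block = [t for t in completed if t.required_ratio == r]
        op_phase[r] = _median(
            [t.operant_times_s[-1] - t.operant_times_s[0] for t in block]
        )
        post_phase[r] = _median(
            [
                t.feeder_time_s - t.ds_onset_s
                for t in block
                if t.feeder_time_s is not None
            ]
        )
    return MetricsREV(
        total_operant=int(total_operant),
        pellets_earned=len(completed),
        final_ratio=int(final_ratio),
        retrieval_latency_s=retrieval,
        post_reinforcement_pause_s=_median(pauses),
        operant_phase_s=op_phase,
        post_operant_phase_s=post_phase,
    )


def drlm_metrics_table(
    logs: list[EventLog], first_k: int | None = 20
) -> pd.DataFrame:
    """Tidy per-mouse, per-test DRLM metrics (one row per mouse x test)."""
    rows = []
    for log in logs:
        if log.session_type != "DRLM":
            continue
        trials = select_trials(segment_drlm(log), first_k=first_k)
        m = drlm_metrics(trials)
        rows.append(
            {
                "mouse_id": log.mouse_id,
                "group": log.group,
                "test": log.test_index,
                "pellets": m.pellets,
                "median_latency_s": m.median_latency_s,
                "median_iti_interval_s": m.median_iti_interval_s,
                "learning_ratio": m.learning_ratio,
                "learning_ratio_per_trial": m.learning_ratio_per_trial,
                "n_trials": m.n_trials,
            }
        )
    return pd.DataFrame(rows)


def rev_metrics_table(logs: list[EventLog], pr_block: int = 5) -> pd.DataFrame:
    """Tidy per-mouse, per-test REV metrics (one row per mouse x test)."""
    rows = []
    for log in logs:
        if log.session_type != "REV":
            continue
        m = rev_metrics(segment_rev(log), pr_block=pr_block)
        rows.append(
            {
                "mouse_id": log.mouse_id,
                "group": log.group,
                "test": log.test_index,
                "total_operant": m.total_operant,
                "pellets_earned": m.pellets_earned,
                "final_ratio": m.final_ratio,
                "retrieval_latency_s": m.retrieval_latency_s,
                "post_reinforcement_pause_s": m.post_reinforcement_pause_s,
                f"operant_phase_pr{pr_block}_s": m.operant_phase_s.get(pr_block, math.nan),
                f"post_operant_phase_pr{pr_block}_s": m.post_operant_phase_s.get(
                    pr_block, math.nan
                ),
            }
        )
    return pd.DataFrame(rows)
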