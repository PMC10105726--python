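"""Event-locked analysis of fibre-photometry traces.

The raw demodulated signal (970 Hz) is down-sampled to 20 Hz by window
averaging, then each trial is normalized against its own pre-onset baseline:
z(t) = (F(t) - F0) / SD0, where F0 and SD0 are the mean and standard
deviation of the 10 s immediately before phase onset (DS onset in the DRLM
test; the first operant response in the REV test).  Variable-length phases
(DS-on, operant, post-operant) are time-normalized onto 10 equal intervals;
fixed 5-s phases (post-DS feeder, ITI feeder, post-feeder) are binned into
10 x 0.5-s intervals.  Per-trial bin values are averaged per mouse, test and
group for the mixed-design statistics.

Degenerate trials (baseline window before trace start, SD0 = 0, phase
shorter than the minimum for time normalization) are excluded and counted
in a QC report rather than propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import TrialRecordDRLM, TrialRecordREV, segment_drlm, segment_rev
from .io import EventLog, PhotometryTrace

__all__ = [
    "BaselineStats",
    "PhaseActivity",
    "DegenerateBaselineError",
    "downsample",
    "baseline_stats",
    "zscore",
    "time_normalize",
    "bin_fixed",
    "phase_windows",
    "trial_phase_activity",
    "session_phase_activity",
    "aggregate",
    "N_BINS",
    "BASELINE_S",
    "FIXED_PHASE_S",
    "TIME_NORMALIZED_PHASES",
    "FIXED_PHASES",
]

logger = logging.getLogger(__name__)

N_BINS = 10
BASELINE_S = 10.0
FIXED_PHASE_S = 5.0
FIXED_BIN_S = 0.5
#: shortest phase that still puts >= 1 sample (at 20 Hz) into each of the
#: 10 time-normalized sub-windows
MIN_PHASE_S = 0.5

TIME_NORMALIZED_PHASES = frozenset({"ds_on", "operant", "post_operant"})
FIXED_PHASES = frozenset({"post_ds_feeder", "iti_feeder", "post_feeder"})


class DegenerateBaselineError(ValueError):
    """Baseline window has zero variance; the z-score is undefined."""


@dataclass
class BaselineStats:
    """Mean and SD of the 10-s pre-onset baseline window (population SD)."""

    F0: float
    SD0: float
    n: int


def downsample(trace: PhotometryTrace, target_hz: float = 20.0) -> PhotometryTrace:
    """Window-mean resampling onto a uniform ``target_hz`` grid.

    Each output sample is the mean of the raw samples whose timestamps fall
    in its half-open 1/target_hz window; output timestamps sit at window
    starts.  The 970 -> 20 Hz factor is non-integer (48.5), so this is a
    deterministic, mean-preserving alternative to phase-locked decimation.
    A trace already at the target rate is returned unchanged.
    """
    if abs(trace.rate_hz - target_hz) < 1e-9:
        return trace
    if trace.rate_hz < 2 * target_hz:
        raise ValueError(
            f"raw rate {trace.rate_hz} Hz is below the Nyquist rate of the "
            f"{target_hz}-Hz target"
        )
    # raw sample i (time t0 + i/rate) falls in output window floor(t * target)
    rel = np.arange(trace.F.size) / trace.rate_hz
    idx = np.floor(rel * target_hz + 1e-12).astype(np.int64)
    n_out = int(idx[-1]) + 1
    sums = np.bincount(idx, weights=trace.F, minlength=n_out)
    counts = np.bincount(idx, minlength=n_out)
    # drop a trailing partially-filled window
    full = int(np.floor(trace.F.size / trace.rate_hz * target_hz))
    n_out = min(n_out, full) if full > 0 else n_out
    with np.errstate(invalid="ignore"):
        F = sums[:n_out] / counts[:n_out]
    return PhotometryTrace(F=F, rate_hz=target_hz, t0=trace.t0)


def _window_slice(trace: PhotometryTrace, start: float, end: float) -> slice:
    """Index slice of samples with timestamps in the half-open [start, end)."""
    i0 = int(np.ceil((start - trace.t0) * trace.rate_hz - 1e-9))
    i1 = int(np.ceil((end - trace.t0) * trace.rate_hz - 1e-9))
    return slice(max(i0, 0), max(min(i1, trace.F.size), 0))


def baseline_stats(trace: PhotometryTrace, anchor_s: float) -> BaselineStats:
    """F0 and SD0 over the 10 s immediately before ``anchor_s``.

    Raises ValueError when the window extends before the trace start (such
    trials are marked invalid by callers).  SD0 is the population SD.
    """
    start = anchor_s - BASELINE_S
    if start < trace.t0 - 1e-9:
        raise ValueError(
            f"baseline window [{start:.2f}, {anchor_s:.2f}) precedes trace start"
        )
    sl = _window_slice(trace, start, anchor_s)
    seg = trace.F[sl]
    if seg.size == 0:
        raise ValueError("baseline window contains no samples")
    return BaselineStats(F0=float(seg.mean()), SD0=float(seg.std(ddof=0)), n=seg.size)


def zscore(
    trace: PhotometryTrace, window: tuple[float, float], stats: BaselineStats
) -> tuple[np.ndarray, np.ndarray]:
    """z(t) = (F(t) - F0)/SD0 for samples in the half-open ``window``.

    Returns (times, z).  A zero-SD baseline raises
    :class:`DegenerateBaselineError`; callers exclude the trial and log it.
    """
    if stats.SD0 <= 0:
        raise DegenerateBaselineError("baseline SD is zero; z-score undefined")
    sl = _window_slice(trace, *window)
    t = trace.t0 + np.arange(sl.start, sl.stop) / trace.rate_hz
    return t, (trace.F[sl] - stats.F0) / stats.SD0


def time_normalize(
    t: np.ndarray,
    z: np.ndarray,
    window: tuple[float, float],
    n_intervals: int = N_BINS,
) -> np.ndarray:
    """Mean z in each of ``n_intervals`` equal-duration sub-windows of a
    variable-length phase (time normalization onto one standard size).

    Empty sub-windows are filled by linear interpolation between the
    neighbouring non-empty bins (no extrapolation: edge gaps copy the
    nearest non-empty bin).  Phases shorter than 0.5 s are rejected.
    """
    start, end = window
    dur = end - start
    if dur < MIN_PHASE_S:
        raise ValueError(f"phase duration {dur:.3f} s below minimum {MIN_PHASE_S} s")
    if len(t) == 0:
        raise ValueError("no samples in phase window")
    idx = np.floor((np.asarray(t) - start) / dur * n_intervals).astype(np.int64)
    idx = np.clip(idx, 0, n_intervals - 1)
    sums = np.bincount(idx, weights=z, minlength=n_intervals)
    counts = np.bincount(idx, minlength=n_intervals)
    bins = np.full(n_intervals, np.nan)
    nz = counts > 0
    bins[nz] = sums[nz] / counts[nz]
    if not nz.all():
        filled = np.flatnonzero(nz)
        bins = np.interp(np.arange(n_intervals), filled, bins[filled])
    return bins


def bin_fixed(
    t: np.ndarray,
    z: np.ndarray,
    onset_s: float,
    width_s: float = FIXED_BIN_S,
    duration_s: float = FIXED_PHASE_S,
) -> np.ndarray:
    """Mean z in consecutive fixed-width bins covering
    [onset, onset + duration); every bin must contain samples."""
    n = int(round(duration_s / width_s))
    t = np.asarray(t)
    mask = (t >= onset_s - 1e-9) & (t < onset_s + duration_s - 1e-9)
    if not mask.any():
        raise ValueError("no samples in fixed phase window")
    idx = np.floor((t[mask] - onset_s) / width_s + 1e-9).astype(np.int64)
    idx = np.clip(idx, 0, n - 1)
    counts = np.bincount(idx, minlength=n)
    if (counts == 0).any():
        raise ValueError("fixed phase window truncated: empty bin")
    return np.bincount(idx, weights=np.asarray(z)[mask], minlength=n) / counts


def phase_windows(trial: TrialRecordDRLM | TrialRecordREV) -> dict[str, tuple[float, float]]:
    """Half-open phase windows for one trial.

    DRLM responded trial: baseline [onset-10, onset), ds_on [onset, feeder),
    post_ds_feeder [feeder, feeder+5), and iti_feeder [f, f+5) anchored at
    the first feeder response of the *following* ITI (normalized against
    this trial's pre-DS baseline).  Non-responded trials carry the baseline
    only.  REV completed trial: baseline [poke1-10, poke1), operant
    [poke1, last poke), post_operant [DS onset, feeder), post_feeder
    [feeder, feeder+5).
    """
    wins: dict[str, tuple[float, float]] = {}
    if isinstance(trial, TrialRecordDRLM):
        on = trial.ds_onset_s
        wins["baseline"] = (on - BASELINE_S, on)
        if trial.responded and trial.feeder_time_s is not None:
            f = trial.feeder_time_s
            wins["ds_on"] = (on, f)
            wins["post_ds_feeder"] = (f, f + FIXED_PHASE_S)
    elif isinstance(trial, TrialRecordREV):
        if not trial.operant_times_s:
            return wins
        p1 = trial.operant_times_s[0]
        wins["baseline"] = (p1 - BASELINE_S, p1)
        if trial.completed:
            last = trial.operant_times_s[-1]
            if last > p1:
                wins["operant"] = (p1, last)
            if trial.ds_onset_s is not None and trial.feeder_time_s is not None:
                wins["post_operant"] = (trial.ds_onset_s, trial.feeder_time_s)
                wins["post_feeder"] = (
                    trial.feeder_time_s,
                    trial.feeder_time_s + FIXED_PHASE_S,
                )
    else:
        raise TypeError(f"unsupported trial record {type(trial)!r}")
    return wins


def _iti_feeder_onset(
    trial: TrialRecordDRLM, next_trial: TrialRecordDRLM | None
) -> float | None:
    """Onset of the ITI feeder phase following ``trial``: the first feeder
    response of the next ITI after the 5-s post-DS feeder window."""
    if next_trial is None:
        return None
    guard = (
        trial.feeder_time_s + FIXED_PHASE_S
        if trial.feeder_time_s is not None
        else trial.ds_offset_s
    )
    for ft in next_trial.iti_response_times_s:
        if ft >= guard:
            return ft
    return None


@dataclass
class PhaseActivity:
    """Per-trial z-scored interval means for one phase."""

    trial_index: int
    phase: str
    bins: np.ndarray  # 10 interval means of z
    binning: str  # "time_normalized" | "fixed_0p5s"
    phase_mean: float  # non-binned mean z over the phase
    valid: bool = True


@dataclass
class PhaseQC:
    """Exclusion accounting for one session's phase extraction."""

    n_trials: int = 0
    short_baseline: int = 0
    degenerate_baseline: int = 0
    short_phase: dict[str, int] = field(default_factory=dict)
    truncated_phase: dict[str, int] = field(default_factory=dict)

    def add_phase_failure(self, phase: str, kind: str) -> None:
        d = self.short_phase if kind == "short" else self.truncated_phase
        d[phase] = d.get(phase, 0) + 1


def trial_phase_activity(
    trace20: PhotometryTrace,
    trial: TrialRecordDRLM | TrialRecordREV,
    iti_onset_s: float | None = None,
    qc: PhaseQC | None = None,
) -> list[PhaseActivity]:
    """z-score one trial against its baseline and bin every defined phase."""
    qc = qc if qc is not None else PhaseQC()
    wins = phase_windows(trial)
    if "baseline" not in wins:
        return []
    anchor = wins["baseline"][1]
    try:
        stats = baseline_stats(trace20, anchor)
    except ValueError:
        qc.short_baseline += 1
        return []
    if stats.SD0 <= 0:
        qc.degenerate_baseline += 1
        logger.warning("trial %d: zero-SD baseline, excluded", trial.index)
        return []
    if iti_onset_s is not None:
        wins["iti_feeder"] = (iti_onset_s, iti_onset_s + FIXED_PHASE_S)
    out = []
    for phase, win in wins.items():
        if phase == "baseline":
            continue
        try:
            t, z = zscore(trace20, win, stats)
            if phase in TIME_NORMALIZED_PHASES:
                bins = time_normalize(t, z, win)
                binning = "time_normalized"
            else:
                bins = bin_fixed(t, z, win[0])
                binning = "fixed_0p5s"
        except ValueError as err:
            qc.add_phase_failure(
                phase, "short" if "duration" in str(err) else "truncated"
            )
            continue
        out.append(
            PhaseActivity(
                trial_index=trial.index,
                phase=phase,
                bins=bins,
                binning=binning,
                phase_mean=float(z.mean()) if len(z) else float("nan"),
            )
        )
    return out


def session_phase_activity(
    log: EventLog,
    raw_trace: PhotometryTrace,
    target_hz: float = 20.0,
) -> tuple[pd.DataFrame, PhaseQC]:
    """Down-sample one session's raw trace and extract per-trial phase bins.

    Returns a tidy frame (mouse_id, group, session_type, test, trial,
    responded/completed flag, phase, binning, phase_mean, bin_1..bin_10)
    plus the exclusion QC report.
    """
    trace20 = downsample(raw_trace, target_hz)
    qc = PhaseQC()
    rows = []
    if log.session_type == "DRLM":
        trials = segment_drlm(log)
        nxt = trials[1:] + [None]
        for trial, next_trial in zip(trials, nxt):
            qc.n_trials += 1
            iti_onset = (
                _iti_feeder_onset(trial, next_trial) if trial.responded else None
            )
            acts = trial_phase_activity(trace20, trial, iti_onset, qc)
            rows += [
                _activity_row(log, trial.index, trial.responded, a) for a in acts
            ]
    elif log.session_type == "REV":
        trials = segment_rev(log)
        for trial in trials:
            qc.n_trials += 1
            acts = trial_phase_activity(trace20, trial, None, qc)
            for a in acts:
                row = _activity_row(log, trial.index, trial.completed, a)
                row["required_ratio"] = trial.required_ratio
                rows.append(row)
    else:
        raise ValueError(f"unknown session type {log.session_type!r}")
    return pd.DataFrame(rows), qc


def _activity_row(log: EventLog, index: int, flag: bool, a: PhaseActivity) -> dict:
    row = {
        "mouse_id": log.mouse_id,
        "group": log.group,
        "session_type": log.session_type,
        "test": log.test_index,
        "trial": index,
        "responded": bool(flag),
        "phase": a.phase,
        "binning": a.binning,
        "phase_mean": a.phase_mean,
    }
    for b in range(N_BINS):
        row[f"bin_{b + 1}"] = a.bins[b]
    return row


def aggregate(
    per_trial: pd.DataFrame,
    phase: str,
    window: tuple[int, int] | None = None,
    responded_only: bool = True,
    pr_block: int | None = None,
    tests: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Mean per-trial bins per mouse x test for one phase.

    ``window`` restricts trial indices (inclusive); ``pr_block`` restricts
    REV trials to one required ratio; mice with no qualifying trials simply
    have no row (unbalanced data propagate to the stats stage).  The output
    is tidy: mouse_id, group, test, n_trials, phase_mean and bin_1..bin_10,
    where phase_mean is the non-time-normalized grand mean over trials.
    """
    df = per_trial[per_trial["phase"] == phase]
    if window is not None:
        df = df[(df["trial"] >= window[0]) & (df["trial"] <= window[1])]
    if responded_only:
        df = df[df["responded"]]
    if pr_block is not None:
        df = df[df["required_ratio"] == pr_block]
    if tests is not None:
        df = df[df["test"].isin(tests)]
    if df.empty:
        return pd.DataFrame()
    bin_cols = [f"bin_{b + 1}" for b in range(N_BINS)]
    agg = (
        df.groupby(["mouse_id", "group", "test"], as_index=False)
        .agg(
            n_trials=("trial", "size"),
            phase_mean=("phase_mean", "mean"),
            **{c: (c, "mean") for c in bin_cols},
        )
    )
    return agg


def activity_long(agg: pd.DataFrame, phase: str) -> pd.DataFrame:
    """Melt an aggregate table to tidy long form (one row per bin) for the
    mixed-design ANOVA: mouse_id, group, test, phase, interval, z."""
    bin_cols = [c for c in agg.columns if c.startswith("bin_")]
    long = agg.melt(
        id_vars=["mouse_id", "group", "test"],
        value_vars=bin_cols,
        var_name="interval",
        value_name="z",
    )
    long["interval"] = long["interval"].str.removeprefix("bin_").astype(int)
    long.insert(3, "phase", phase)
    return long
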