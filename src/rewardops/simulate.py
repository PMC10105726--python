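"""Synthetic CON/CSS cohort generator.

Produces behavioural event streams for DRLM and REV sessions and matching
raw fibre-photometry traces with the statistical structure the analysis
pipeline assumes, so that every downstream stage can be exercised and
validated without any recorded data.

The behavioural model: DS trials are responded with a per-mouse,
per-group probability; DS response latencies follow a log-normal
distribution truncated at the 30-s maximum DS duration (medians configured
per group and test day); ITI feeder responses arrive as a Poisson process;
ITI durations are uniform on [20, 80] s (mean 50 s).  REV sessions run the
progressive-ratio schedule with log-normal inter-poke intervals, retrieval
latencies and post-reinforcement pauses, and a per-ratio quitting hazard.

The photometry forward model: each labelled behavioural event adds a
double-exponential calcium-transient kernel scaled by a group- and
phase-specific amplitude onto a constant baseline with optional linear
drift and additive white Gaussian noise, sampled at the raw demodulated
rate (970 Hz by default).  The analysis pipeline must not depend on these
kernel details; they exist only to give the z-scoring and binning stages a
signal with known ground truth.

All randomness flows from a single cohort seed through named per-mouse,
per-session substreams, so identical configurations yield byte-identical
cohorts regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr, ndtri

from . import behavior
from .config import CohortConfig, ConfigError, DRLMParams, PhotoParams, REVParams
from .io import EventLog, PhotometryTrace

__all__ = [
    "generate_iti_schedule",
    "generate_drlm_session",
    "generate_rev_session",
    "synthesize_photometry",
    "transient_kernel",
    "generate_cohort",
    "Cohort",
    "MouseEffects",
    "session_rng",
]

_SESSION_CODE = {"DRLM": 1, "REV": 2, "DRLM_trace": 3, "REV_trace": 4, "mouse": 5}


def session_rng(
    seed: int, group_index: int, mouse_index: int, kind: str, test_index: int = 0
) -> np.random.Generator:
    """Deterministic per-mouse-session RNG substream."""
    ss = np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF,
        spawn_key=(group_index, mouse_index, _SESSION_CODE[kind], test_index),
    )
    return np.random.default_rng(ss)


def generate_iti_schedule(
    params: DRLMParams, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Draw inter-trial-interval durations (seconds).

    The schedule is a variable-interval schedule with mean 50 s and range
    20-80 s; durations are uniform on [iti_min_s, iti_max_s], which matches
    the stated mean and range with the fewest assumptions.  A degenerate
    range (min == max) yields constant intervals.
    """
    params.validate()
    if abs((params.iti_min_s + params.iti_max_s) / 2.0 - params.iti_mean_s) > 1e-9:
        raise ConfigError(
            "uniform ITI schedule requires iti_mean_s at the centre of "
            f"[{params.iti_min_s}, {params.iti_max_s}]"
        )
    if n is None:
        n = params.n_trials
    return rng.uniform(params.iti_min_s, params.iti_max_s, size=n)


def _truncated_lognormal(
    rng: np.random.Generator, median: float, sigma: float, upper: float, size: int
) -> np.ndarray:
    """Log-normal(ln median, sigma) truncated to (0, upper] via inverse CDF."""
    if median > upper:
        raise ConfigError(f"latency median {median} exceeds truncation bound {upper}")
    if sigma == 0.0:
        return np.full(size, float(median))
    mu = math.log(median)
    cap = ndtr((math.log(upper) - mu) / sigma)
    u = rng.uniform(0.0, cap, size=size)
    return np.exp(mu + sigma * ndtri(u))


def generate_drlm_session(
    params: DRLMParams,
    group: str,
    test_index: int,
    rng: np.random.Generator,
    mouse_id: str = "m01",
    p_response: float | None = None,
    latency_median: float | None = None,
) -> EventLog:
    """Simulate one DRLM session as a timestamped event log.

    Responded trials place a feeder response at onset + latency, a pellet
    delivery shortly after, and DS offset one second after the response
    (capped at the 30-s maximum DS duration); non-responded trials run the
    full 30 s.  ITI feeder responses are a Poisson process that skips the
    5-s post-reward retrieval window.
    """
    params.validate()
    if group not in params.p_response:
        raise ConfigError(f"unknown group label {group!r}")
    p = params.p_response[group] if p_response is None else p_response
    med = (
        params.latency_median(group, test_index)
        if latency_median is None
        else latency_median
    )
    rate = params.iti_rate_hz[group]

    itis = generate_iti_schedule(params, rng)
    # responding declines within the session; the per-session marginal
    # stays at n_trials * p
    half = (params.n_trials + 1) // 2
    d = params.response_decline
    p_early = min(p * (1 + d), 1.0)
    p_late = np.clip(2 * p - p_early, 0.0, 1.0)  # redistribute any clipped mass
    p_k = np.where(np.arange(params.n_trials) < half, p_early, p_late)
    responded = rng.uniform(size=params.n_trials) < p_k
    latencies = _truncated_lognormal(
        rng, med, params.latency_sigma, params.ds_max_s, params.n_trials
    )

    events: list[tuple[str, float]] = []
    truth_rows = []
    prev_off = 0.0
    prev_guard = 0.0  # end of the previous trial's 5-s retrieval window
    for k in range(params.n_trials):
        iti_start = prev_off
        on = prev_off + itis[k]
        # trial body
        if responded[k]:
            lat = float(latencies[k])
            feeder = on + lat
            off = min(on + params.ds_max_s, feeder + 1.0)
            events += [
                ("ds_on", on),
                ("feeder", feeder),
                ("pellet", feeder + params.pellet_delay_s),
                ("ds_off", off),
            ]
            iti_guard = feeder + 5.0  # post-reward retrieval window
        else:
            lat = params.ds_max_s
            feeder = None
            off = on + params.ds_max_s
            events += [("ds_on", on), ("ds_off", off)]
            iti_guard = off
        # feeder responses in the ITI preceding this trial (skipping the
        # previous trial's retrieval window)
        lo = max(iti_start, prev_guard)
        hi = on
        if rate > 0 and hi > lo:
            n_ev = rng.poisson(rate * (hi - lo))
            times = np.sort(rng.uniform(lo, hi, size=n_ev))
            events += [("feeder", float(x)) for x in times]
        truth_rows.append(
            {
                "index": k + 1,
                "ds_onset_s": on,
                "responded": bool(responded[k]),
                "latency_s": lat,
                "iti_start_s": iti_start,
                "iti_end_s": on,
            }
        )
        prev_off = off
        prev_guard = iti_guard

    ev = pd.DataFrame(events, columns=["event", "time_s"]).sort_values(
        "time_s", kind="mergesort"
    )
    ev = _enforce_strict_order(ev)
    log = EventLog(
        mouse_id=mouse_id,
        group=group,
        session_type="DRLM",
        test_index=test_index,
        events=ev,
        truth=pd.DataFrame(truth_rows),
    )
    log.validate()
    return log


def generate_rev_session(
    params: REVParams,
    group: str,
    rng: np.random.Generator,
    test_index: int = 1,
    mouse_id: str = "m01",
) -> EventLog:
    """Simulate one progressive-ratio REV session.

    Operant responses accumulate until the block's required ratio is met,
    which triggers a 1-s tone DS and pellet delivery, followed by retrieval,
    a 5-s timeout and a post-reinforcement pause.  The session ends at the
    time limit or when the per-ratio quitting hazard fires (evaluated before
    each trial); a truncated trial remains incomplete in the log.
    """
    params.validate()
    if group not in params.operant_ipi_s:
        raise ConfigError(f"unknown group label {group!r}")
    ipi_med = params.operant_ipi_s[group]
    retr_med = params.retrieval_latency_s[group]
    pause_med = params.pause_s[group]
    hazard = params.quit_hazard[group]

    def logn(median: float, sigma: float) -> float:
        return float(median * math.exp(sigma * rng.standard_normal()))

    events: list[tuple[str, float]] = []
    t = params.start_delay_s + logn(pause_med, params.pause_sigma)
    k = 0
    while True:
        k += 1
        need = behavior.required_ratio(k, params.pr_base, params.pr_step, params.block_size)
        if rng.uniform() < min(1.0, hazard * need):
            break  # mouse disengages before starting this trial
        poke_t = t
        truncated = False
        for j in range(need):
            if poke_t > params.session_max_s:
                truncated = True
                break
            events.append(("operant", poke_t))
            if j < need - 1:
                poke_t += logn(ipi_med, params.ipi_sigma)
        if truncated:
            break
        last = poke_t
        ds_on = last + 1e-4  # tone DS elicited by the final response
        retrieval = max(logn(retr_med, params.retrieval_sigma), 0.6)
        feeder = ds_on + retrieval
        events += [
            ("ds_on", ds_on),
            ("pellet", ds_on + 0.5),
            ("ds_off", ds_on + 1.0),
            ("feeder", feeder),
        ]
        if feeder > params.session_max_s:
            break
        t = feeder + max(logn(pause_med, params.pause_sigma), params.timeout_s)
        if t > params.session_max_s:
            break

    ev = pd.DataFrame(events, columns=["event", "time_s"]).sort_values(
        "time_s", kind="mergesort"
    )
    ev = _enforce_strict_order(ev)
    log = EventLog(
        mouse_id=mouse_id,
        group=group,
        session_type="REV",
        test_index=test_index,
        events=ev,
    )
    log.validate()
    return log


def _enforce_strict_order(ev: pd.DataFrame) -> pd.DataFrame:
    """Nudge coincident timestamps apart (continuous draws collide with
    probability zero, but constructed fixtures may not)."""
    t = ev["time_s"].to_numpy(float).copy()
    for i in range(1, t.size):
        if t[i] <= t[i - 1]:
            t[i] = np.nextafter(t[i - 1], np.inf)
    ev = ev.copy()
    ev["time_s"] = t
    return ev


def transient_kernel(
    t: np.ndarray, rise_s: float = 0.1, decay_s: float = 1.0
) -> np.ndarray:
    """Difference-of-exponentials calcium-transient kernel, peak-normalized
    to 1 so that amplitudes are peak heights; zero for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-t / decay_s) - np.exp(-t / rise_s), 0.0)
    t_peak = rise_s * decay_s / (decay_s - rise_s) * math.log(decay_s / rise_s)
    peak = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    return out / peak


def _event_amplitudes(log: EventLog, amp: dict[str, float]) -> list[tuple[float, float]]:
    """(time, amplitude) pairs for every transient-evoking event in a log."""
    out: list[tuple[float, float]] = []
    if log.session_type == "DRLM":
        trials = behavior.segment_drlm(log)
        for tr in trials:
            a = amp["ds_on_early"] if tr.index <= 10 else amp["ds_on_late"]
            out.append((tr.ds_onset_s, a))
            if tr.feeder_time_s is not None:
                out.append((tr.feeder_time_s, amp["post_ds_feeder"]))
            for ft in tr.iti_response_times_s:
                out.append((ft, amp["iti_feeder"]))
    elif log.session_type == "REV":
        trials = behavior.segment_rev(log)
        for tr in trials:
            for pt in tr.operant_times_s:
                out.append((pt, amp["operant"]))
            if tr.completed and tr.ds_onset_s is not None:
                out.append((tr.ds_onset_s, amp["post_operant"]))
            if tr.feeder_time_s is not None:
                out.append((tr.feeder_time_s, amp["post_feeder"]))
    else:
        raise ConfigError(f"unknown session type {log.session_type!r}")
    return out


def synthesize_photometry(
    log: EventLog,
    params: PhotoParams,
    rng: np.random.Generator,
    amp_scale: float = 1.0,
    duration_s: float | None = None,
) -> PhotometryTrace:
    """Forward-model a raw fluorescence trace for one session.

    trace = baseline + drift * t + sum over events of amp * kernel(t - t_ev)
    + N(0, noise_sd), sampled at ``params.raw_rate_hz`` from session time
    zero.  Event amplitudes come from the group's amplitude map;
    ``amp_scale`` applies a per-mouse multiplicative random effect.
    """
    params.validate()
    amp = params.amp[log.group]
    if duration_s is None:
        duration_s = log.duration_s + params.tail_s
    n = int(math.ceil(duration_s * params.raw_rate_hz))
    dt = 1.0 / params.raw_rate_hz
    F = np.full(n, params.baseline_level, dtype=float)
    if params.drift_per_s:
        F += params.drift_per_s * np.arange(n) * dt
    if params.noise_sd > 0:
        F += params.noise_sd * rng.standard_normal(n)
    supp = int(math.ceil(8.0 * params.kernel_decay_s * params.raw_rate_hz))
    for t_ev, a in _event_amplitudes(log, amp):
        i0 = int(math.ceil(t_ev * params.raw_rate_hz))
        i1 = min(n, i0 + supp)
        if i1 <= i0:
            continue
        rel = np.arange(i0, i1) * dt - t_ev
        F[i0:i1] += (a * amp_scale) * transient_kernel(
            rel, params.kernel_rise_s, params.kernel_decay_s
        )
    return PhotometryTrace(F=F, rate_hz=params.raw_rate_hz)


@dataclass
class MouseEffects:
    """Per-mouse random effects drawn once per cohort mouse."""

    p_logit_offset: float
    amp_scale: float


@dataclass
class Cohort:
    """A generated cohort: event logs plus (optionally) raw traces."""

    config: CohortConfig
    logs: list[EventLog]
    traces: dict[str, PhotometryTrace] = field(default_factory=dict)
    effects: dict[str, MouseEffects] = field(default_factory=dict)

    @staticmethod
    def trace_key(log: EventLog) -> str:
        return f"{log.mouse_id}/{log.session_type}{log.test_index}"


def generate_cohort(cfg: CohortConfig, photometry: bool = True) -> Cohort:
    """Generate the full CON/CSS cohort defined by ``cfg``.

    Per-mouse random effects (response probability on the logit scale,
    multiplicative transient amplitude) are drawn from dedicated substreams,
    then every mouse-session is simulated from its own substream derived
    from ``(seed, group, mouse, session, test)``.
    """
    cfg.validate()
    logs: list[EventLog] = []
    traces: dict[str, PhotometryTrace] = {}
    effects: dict[str, MouseEffects] = {}
    for gi, group in enumerate(cfg.groups):
        p_group = cfg.drlm.p_response[group]
        for mi in range(cfg.n_per_group):
            mouse_id = f"{group}{mi + 1:02d}"
            mrng = session_rng(cfg.seed, gi, mi, "mouse")
            eff = MouseEffects(
                p_logit_offset=float(
                    cfg.drlm.p_response_sigma * mrng.standard_normal()
                ),
                amp_scale=float(
                    math.exp(cfg.photo.mouse_amp_sigma * mrng.standard_normal())
                ),
            )
            effects[mouse_id] = eff
            if 0.0 < p_group < 1.0 and cfg.drlm.p_response_sigma > 0:
                p_mouse = float(expit(logit(p_group) + eff.p_logit_offset))
            else:
                p_mouse = p_group
            for test in range(1, cfg.n_drlm_tests + 1):
                log = generate_drlm_session(
                    cfg.drlm,
                    group,
                    test,
                    session_rng(cfg.seed, gi, mi, "DRLM", test),
                    mouse_id=mouse_id,
                    p_response=p_mouse,
                )
                logs.append(log)
                if photometry:
                    traces[Cohort.trace_key(log)] = synthesize_photometry(
                        log,
                        cfg.photo,
                        session_rng(cfg.seed, gi, mi, "DRLM_trace", test),
                        amp_scale=eff.amp_scale,
                    )
            for test in range(1, cfg.n_rev_tests + 1):
                log = generate_rev_session(
                    cfg.rev,
                    group,
                    session_rng(cfg.seed, gi, mi, "REV", test),
                    test_index=test,
                    mouse_id=mouse_id,
                )
                logs.append(log)
                if photometry:
                    traces[Cohort.trace_key(log)] = synthesize_photometry(
                        log,
                        cfg.photo,
                        session_rng(cfg.seed, gi, mi, "REV_trace", test),
                        amp_scale=eff.amp_scale,
                    )
    return Cohort(config=cfg, logs=logs, traces=traces, effects=effects)
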