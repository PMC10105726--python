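"""Typed configuration for synthetic CON/CSS cohorts.

The defaults encode the study conditions of the chronic-social-stress (CSS)
reward experiments these tools analyse: 40-trial discriminative
reward-learning (DRLM) sessions with a 30-s tone discriminative stimulus (DS)
and variable inter-trial intervals (mean 50 s, range 20-80 s); progressive
ratio reward-to-effort (REV) sessions with the ratio sequence 1, 5, 9, 13, ...
in blocks of five trials; and a GCaMP-like forward model for the raw
fibre-photometry trace (double-exponential transients on a noisy baseline,
demodulated-rate sampling at 970 Hz).

Group calibration follows the published behaviour: CSS mice respond on
18.4/40 DS trials per test on average versus 24.4/40 for controls, CSS DS
response latencies stay flat across test days while control latencies fall,
and group-dependent transient amplitudes reproduce the direction of the
photometry effects (lower CSS DS-on activity in late trials; higher CSS
operant/post-operant activity at PR 5).

All configuration round-trips through YAML (:func:`load_config`,
:func:`save_config`).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "DRLMParams",
    "REVParams",
    "PhotoParams",
    "CohortConfig",
    "ConfigError",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised for invalid generator or pipeline configuration."""


def _default_p_response() -> dict[str, float]:
    # responded DS trials per 40-trial test: CON 24.4, CSS 18.4
    return {"CON": 24.4 / 40.0, "CSS": 18.4 / 40.0}


def _default_latency_median() -> dict[str, dict[int, float]]:
    # seconds; control medians fall across test days (learning), CSS stays flat
    return {
        "CON": {1: 8.0, 2: 5.0, 3: 3.0},
        "CSS": {1: 8.0, 2: 8.0, 3: 8.0},
    }


def _default_iti_rate() -> dict[str, float]:
    # feeder responses / s during inter-trial intervals
    return {"CON": 0.125, "CSS": 0.10}


@dataclass
class DRLMParams:
    """Parameters of a discriminative reward learning-memory session."""

    n_trials: int = 40
    ds_max_s: float = 30.0
    iti_mean_s: float = 50.0
    iti_min_s: float = 20.0
    iti_max_s: float = 80.0
    #: per-group probability that a DS trial receives a feeder response
    p_response: dict[str, float] = field(default_factory=_default_p_response)
    #: SD of a per-mouse logit-normal random effect on p_response
    p_response_sigma: float = 0.4
    #: within-session decline of responding: trials in the first half of the
    #: session respond with p*(1+d), the second half with p*(1-d), keeping
    #: the per-session marginal at n_trials * p while concentrating
    #: responses in the analysed early trials
    response_decline: float = 0.45
    #: per-group, per-test median of the log-normal DS latency model (s)
    latency_median_s: dict[str, dict[int, float]] = field(
        default_factory=_default_latency_median
    )
    #: log-space SD of the DS latency model
    latency_sigma: float = 0.5
    #: per-group rate of feeder responses during ITIs (Hz)
    iti_rate_hz: dict[str, float] = field(default_factory=_default_iti_rate)
    #: pellet delivery delay after the triggering feeder response (s)
    pellet_delay_s: float = 0.5

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if not (self.iti_min_s <= self.iti_mean_s <= self.iti_max_s):
            raise ConfigError(
                "ITI range invalid: need iti_min_s <= iti_mean_s <= iti_max_s, got "
                f"{self.iti_min_s}, {self.iti_mean_s}, {self.iti_max_s}"
            )
        if self.ds_max_s <= 0:
            raise ConfigError("ds_max_s must be positive")
        for g, p in self.p_response.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"p_response[{g!r}] must lie in [0, 1], got {p}")
        if not 0.0 <= self.response_decline < 1.0:
            raise ConfigError("response_decline must lie in [0, 1)")
        for g, r in self.iti_rate_hz.items():
            if r < 0:
                raise ConfigError(f"iti_rate_hz[{g!r}] must be >= 0")

    def latency_median(self, group: str, test_index: int) -> float:
        """Median DS latency for *group* on test *test_index* (carries the
        last configured test forward for later tests)."""
        table = self.latency_median_s[group]
        if test_index in table:
            return table[test_index]
        return table[max(table)]


@dataclass
class REVParams:
    """Parameters of a progressive-ratio reward-to-effort session."""

    pr_base: int = 1
    pr_step: int = 4
    block_size: int = 5
    session_max_s: float = 2700.0
    timeout_s: float = 5.0
    #: per-group median inter-poke interval within a ratio run (s)
    operant_ipi_s: dict[str, float] = field(
        default_factory=lambda: {"CON": 2.0, "CSS": 4.0}
    )
    ipi_sigma: float = 0.4
    #: per-group median latency from ratio completion (DS onset) to retrieval (s)
    retrieval_latency_s: dict[str, float] = field(
        default_factory=lambda: {"CON": 1.5, "CSS": 2.5}
    )
    retrieval_sigma: float = 0.3
    #: per-group median post-reinforcement pause before the next poke (s)
    pause_s: dict[str, float] = field(default_factory=lambda: {"CON": 5.0, "CSS": 10.0})
    pause_sigma: float = 0.4
    #: per-group hazard of quitting after a completed trial, per unit of the
    #: trial's required ratio (probability = min(1, quit_hazard * ratio))
    quit_hazard: dict[str, float] = field(
        default_factory=lambda: {"CON": 0.01, "CSS": 0.03}
    )
    #: delay before the first operant response of the session (s); must leave
    #: room for the 10-s pre-trial baseline window
    start_delay_s: float = 12.0

    def validate(self) -> None:
        if self.block_size < 1 or self.pr_base < 1 or self.pr_step < 0:
            raise ConfigError("invalid progressive-ratio schedule parameters")
        if self.session_max_s <= 0:
            raise ConfigError("session_max_s must be positive")
        for g, h in self.quit_hazard.items():
            if h < 0:
                raise ConfigError(f"quit_hazard[{g!r}] must be >= 0")


def _default_amp() -> dict[str, dict[str, float]]:
    # Transient amplitudes (arbitrary fluorescence units) per group and
    # event/phase label.  ds_on_early applies to trials 1-10, ds_on_late to
    # trials 11 onwards: control DS-on activity rises within a session while
    # CSS activity stays flat, so CSS < CON in late trials.  In the REV test
    # control activity is suppressed around the operant run (negative
    # amplitudes) while CSS activity is elevated, so CSS > CON at PR 5.
    return {
        "CON": {
            "ds_on_early": 1.0,
            "ds_on_late": 2.0,
            "post_ds_feeder": 2.0,
            "iti_feeder": 0.3,
            "operant": -0.6,
            "post_operant": -0.6,
            "post_feeder": 2.0,
        },
        "CSS": {
            "ds_on_early": 1.0,
            "ds_on_late": 1.0,
            "post_ds_feeder": 2.0,
            "iti_feeder": 0.15,
            "operant": 0.6,
            "post_operant": 0.6,
            "post_feeder": 2.0,
        },
    }


@dataclass
class PhotoParams:
    """Forward model for the raw fibre-photometry trace."""

    raw_rate_hz: float = 970.0
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.0
    #: group -> event/phase label -> transient amplitude (a.u.)
    amp: dict[str, dict[str, float]] = field(default_factory=_default_amp)
    noise_sd: float = 0.5
    baseline_level: float = 10.0
    drift_per_s: float = 0.0
    #: log-space SD of a per-mouse multiplicative amplitude random effect
    mouse_amp_sigma: float = 0.2
    #: trace margin after the last event (s)
    tail_s: float = 15.0

    def validate(self, target_hz: float = 20.0) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.raw_rate_hz <= 2 * target_hz:
            raise ConfigError(
                f"raw_rate_hz={self.raw_rate_hz} must exceed twice the "
                f"{target_hz}-Hz analysis rate"
            )
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= self.kernel_rise_s:
            raise ConfigError("kernel constants need 0 < rise < decay")


@dataclass
class CohortConfig:
    """Full specification of a synthetic CON/CSS cohort."""

    n_per_group: int = 13
    groups: tuple[str, ...] = ("CON", "CSS")
    n_drlm_tests: int = 3
    n_rev_tests: int = 3
    seed: int = 0
    drlm: DRLMParams = field(default_factory=DRLMParams)
    rev: REVParams = field(default_factory=REVParams)
    photo: PhotoParams = field(default_factory=PhotoParams)

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if len(self.groups) < 1:
            raise ConfigError("at least one group label required")
        self.drlm.validate()
        self.rev.validate()
        self.photo.validate()
        for g in self.groups:
            for m in (self.drlm.p_response, self.drlm.iti_rate_hz, self.photo.amp):
                if g not in m:
                    raise ConfigError(f"group {g!r} missing from a parameter map")


def _int_keys(d: Mapping) -> dict:
    """YAML mapping keys arrive as str; restore per-test integer keys."""
    return {int(k): v for k, v in d.items()}


def config_to_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["groups"] = list(cfg.groups)
    return d


def config_from_dict(d: Mapping) -> CohortConfig:
    d = dict(d)
    drlm = dict(d.pop("drlm", {}))
    if "latency_median_s" in drlm:
        drlm["latency_median_s"] = {
            g: _int_keys(v) for g, v in drlm["latency_median_s"].items()
        }
    rev = dict(d.pop("rev", {}))
    photo = dict(d.pop("photo", {}))
    if "groups" in d:
        d["groups"] = tuple(d["groups"])
    cfg = CohortConfig(
        drlm=DRLMParams(**drlm), rev=REVParams(**rev), photo=PhotoParams(**photo), **d
    )
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> CohortConfig:
    """Read a cohort configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: CohortConfig, path: str | Path) -> None:
    """Write a cohort configuration to YAML (round-trips with load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
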