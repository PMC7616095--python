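"""Synthetic Pavlovian-conditioning sessions with known ground truth.

Generates everything the downstream analyses consume: trial event tables
(cue, reward, lick and movement bouts), spike trains of four
projection-defined dopamine populations (DMS, DLS, VLS, NAc core), and
two-channel fiber-photometry traces sharing a motion artifact.

The task emulated is a head-fixed Pavlovian paradigm: a 1-s auditory cue,
reward at a fixed 2-s delay from cue onset, 100 trials per session, and
inter-trial intervals drawn from a flat-hazard (shifted, truncated
exponential) distribution on 4-10 s with median 5.4 s.

Every generator is a pure function of (config, seed): identical seeds give
identical sessions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "POPULATIONS",
    "EVENT_KINDS",
    "TaskConfig",
    "BehaviorParams",
    "SessionEvents",
    "EventModulation",
    "PopulationTemplate",
    "DEFAULT_TEMPLATES",
    "SpikeTrain",
    "UnitGroundTruth",
    "SyntheticSession",
    "PhotometryParams",
    "PhotometryRecording",
    "PhotometryGroundTruth",
    "calibrate_iti_rate",
    "sample_iti",
    "sample_itis",
    "generate_session_events",
    "simulate_spike_train",
    "build_population_session",
    "simulate_photometry",
]

POPULATIONS = ("DMS", "DLS", "VLS", "NAcCore")
EVENT_KINDS = ("cue", "reward", "lick", "movement")


class ConfigurationError(ValueError):
    """Raised when a generator configuration is invalid."""


# ---------------------------------------------------------------------------
# configs and event types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the Pavlovian task.

    ``iti_rate_per_s`` is the rate constant of the shifted exponential ITI
    distribution before truncation.  ``None`` means "calibrate so the
    truncated median equals ``iti_median_s``" (done by root-finding).
    """

    n_trials: int = 100
    cue_duration_s: float = 1.0
    cue_reward_delay_s: float = 2.0
    iti_support_s: tuple[float, float] = (4.0, 10.0)
    iti_rate_per_s: float | None = None
    iti_median_s: float = 5.4
    session_padding_s: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        lo, hi = self.iti_support_s
        if not lo < hi:
            raise ConfigurationError("iti_support_s lower bound must be < upper")
        if self.iti_rate_per_s is not None and self.iti_rate_per_s <= 0:
            raise ConfigurationError("iti_rate_per_s must be positive")
        for name in ("cue_duration_s", "cue_reward_delay_s", "session_padding_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def effective_iti_rate(self) -> float:
        if self.iti_rate_per_s is not None:
            return self.iti_rate_per_s
        lo, hi = self.iti_support_s
        return calibrate_iti_rate(lo, hi, self.iti_median_s)


@dataclass(frozen=True)
class BehaviorParams:
    """Lick/movement bout parameters of the synthetic behavior.

    Anticipatory licking starts ``lick_latency_s`` after cue onset;
    consummatory licking starts shortly after reward.  Movement bouts are a
    Poisson process restricted to ITIs, optionally kept clear of the
    post-reward consumption window.
    """

    lick_latency_s: float = 0.5
    anticipatory_lick_s: float = 1.4
    consummatory_delay_s: float = 0.1
    consummatory_lick_s: float = 2.0
    movement_rate_per_s: float = 0.08
    movement_duration_s: float = 0.8
    movement_clear_reward_s: float = 3.0

    def __post_init__(self) -> None:
        if self.anticipatory_lick_s <= 0 or self.consummatory_lick_s <= 0:
            raise ConfigurationError("lick bout durations must be positive")
        if self.movement_duration_s <= 0:
            raise ConfigurationError("movement_duration_s must be positive")
        if self.lick_latency_s < 0 or self.consummatory_delay_s < 0:
            raise ConfigurationError("bout latencies must be non-negative")


@dataclass
class SessionEvents:
    """Event times of one behavioral session (seconds from session start)."""

    cue_onsets_s: np.ndarray
    reward_times_s: np.ndarray
    lick_bouts: list[tuple[float, float]]
    movement_bouts: list[tuple[float, float]]
    session_duration_s: float
    cue_duration_s: float = 1.0

    def validate(self) -> None:
        cues = np.asarray(self.cue_onsets_s, float)
        rewards = np.asarray(self.reward_times_s, float)
        if np.any(np.diff(cues) <= 0):
            raise ValueError("cue onsets must be strictly ascending")
        for kind in (self.lick_bouts, self.movement_bouts):
            for on, off in kind:
                if off <= on:
                    raise ValueError("bout offset must exceed onset")
                if on < 0 or off > self.session_duration_s:
                    raise ValueError("bout outside session bounds")
        if np.any(cues < 0) or np.any(rewards > self.session_duration_s):
            raise ValueError("events outside session bounds")

    def iti_segments(
        self, post_reward_excl_s: float = 0.0, pre_cue_excl_s: float = 0.0
    ) -> list[tuple[float, float]]:
        """Inter-trial segments (reward k -> cue k+1), with optional guards."""
        segs = []
        cues = np.asarray(self.cue_onsets_s, float)
        rewards = np.asarray(self.reward_times_s, float)
        for k in range(len(rewards)):
            start = rewards[k] + post_reward_excl_s
            end = (cues[k + 1] if k + 1 < len(cues) else self.session_duration_s)
            end -= pre_cue_excl_s if k + 1 < len(cues) else 0.0
            if end > start:
                segs.append((float(start), float(end)))
        return segs


# ---------------------------------------------------------------------------
# population templates and spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventModulation:
    """Multiplicative rate modulation locked to one event kind.

    ``gain == 1`` means no modulation; ``gain < 1`` a firing decrease.  For
    point events (cue, reward) the modulation lasts ``duration_s`` from
    ``latency_s`` after the event; for bouts (lick, movement) it covers the
    bout shifted by ``latency_s`` (``duration_s`` ignored when None).
    """

    gain: float = 1.0
    latency_s: float = 0.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ConfigurationError("gain must be >= 0")


@dataclass(frozen=True)
class PopulationTemplate:
    """Firing phenotype of one projection-defined dopamine population."""

    population: str
    tonic_rate_hz: float
    cue: EventModulation = EventModulation()
    reward: EventModulation = EventModulation()
    lick: EventModulation = EventModulation()
    movement: EventModulation = EventModulation()
    pause_rate_per_min: float = 0.0
    pause_duration_s: float = 0.2

    def __post_init__(self) -> None:
        if self.tonic_rate_hz < 0:
            raise ConfigurationError("tonic_rate_hz must be >= 0")

    def modulation(self, kind: str) -> EventModulation:
        return getattr(self, kind)

    def encoded_kinds(self) -> frozenset[str]:
        return frozenset(k for k in EVENT_KINDS if self.modulation(k).gain != 1.0)

    def dominant_kind(self) -> str:
        encoded = self.encoded_kinds()
        if not encoded:
            return "none"
        return max(encoded, key=lambda k: abs(math.log(self.modulation(k).gain))
                   if self.modulation(k).gain > 0 else math.inf)


# Defaults chosen to reproduce the qualitative population phenotypes:
# DMS cue-only; DLS cue + reward + lick (multiplexing); VLS reward-only and
# strongest; NAc core delayed, lick-locked, slower tonic rate, longer pauses.
DEFAULT_TEMPLATES: Mapping[str, PopulationTemplate] = {
    "DMS": PopulationTemplate(
        population="DMS", tonic_rate_hz=5.0,
        cue=EventModulation(2.2, 0.02, 0.25),
        movement=EventModulation(0.6, 0.0, None),
    ),
    "DLS": PopulationTemplate(
        population="DLS", tonic_rate_hz=5.5,
        cue=EventModulation(2.0, 0.02, 0.25),
        reward=EventModulation(2.4, 0.04, 0.2),
        lick=EventModulation(1.5, 0.0, None),
        movement=EventModulation(0.6, 0.0, None),
    ),
    "VLS": PopulationTemplate(
        population="VLS", tonic_rate_hz=5.5,
        reward=EventModulation(3.2, 0.04, 0.2),
    ),
    "NAcCore": PopulationTemplate(
        population="NAcCore", tonic_rate_hz=3.0,
        cue=EventModulation(1.7, 0.35, 0.4),
        reward=EventModulation(1.8, 0.35, 0.5),
        lick=EventModulation(1.6, 0.05, None),
        pause_rate_per_min=4.0, pause_duration_s=2.0,
    ),
}


@dataclass
class SpikeTrain:
    """Spike times of one unit (strictly ascending seconds)."""

    unit_id: str
    spike_times_s: np.ndarray
    session_id: str | None = None

    def validate(self) -> None:
        t = np.asarray(self.spike_times_s, float)
        if t.size and (np.any(np.diff(t) <= 0) or np.any(t < 0)):
            raise ValueError("spike times must be strictly increasing and >= 0")


@dataclass(frozen=True)
class UnitGroundTruth:
    population: str
    encoded: frozenset[str]
    dominant: str


@dataclass
class SyntheticSession:
    events: SessionEvents
    spike_trains: list[SpikeTrain]
    ground_truth: dict[str, UnitGroundTruth]
    seed: int | None = None


# ---------------------------------------------------------------------------
# ITI sampling
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def calibrate_iti_rate(lo: float, hi: float, median: float) -> float:
    """Rate constant of the shifted exponential whose truncation to
    [lo, hi] has the requested median, found by root-finding."""
    if not lo < median < hi:
        raise ConfigurationError("median must lie inside the support")
    span, m = hi - lo, median - lo

    def median_gap(rate: float) -> float:
        # F(m)/F(span) - 1/2 for the truncated exponential CDF
        return -math.expm1(-rate * m) / -math.expm1(-rate * span) - 0.5

    return brentq(median_gap, 1e-6, 50.0, xtol=1e-12)


def sample_itis(config: TaskConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` ITIs: lo + Exp(rate), rejecting draws above hi."""
    lo, hi = config.iti_support_s
    rate = config.effective_iti_rate
    if rate <= 0:
        raise ConfigurationError("ITI rate must be positive")
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = lo + rng.exponential(1.0 / rate, size=max(n - filled, 16))
        ok = draw[draw <= hi]
        take = min(ok.size, n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def sample_iti(config: TaskConfig, rng: np.random.Generator) -> float:
    return float(sample_itis(config, 1, rng)[0])


# ---------------------------------------------------------------------------
# session events
# ---------------------------------------------------------------------------

def generate_session_events(
    config: TaskConfig,
    behavior: BehaviorParams | None = None,
    rng: np.random.Generator | None = None,
) -> SessionEvents:
    """Lay out a full session: cue/reward pairs separated by sampled ITIs,
    anticipatory/consummatory lick bouts, and ITI movement bouts."""
    behavior = behavior or BehaviorParams()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    itis = sample_itis(config, config.n_trials - 1, rng) if config.n_trials > 1 else np.array([])
    cues = np.empty(config.n_trials)
    cues[0] = config.session_padding_s
    for k in range(1, config.n_trials):
        # ITI runs from reward delivery to the next cue onset
        cues[k] = cues[k - 1] + config.cue_reward_delay_s + itis[k - 1]
    # quantize onsets to a dyadic ~1 us grid so cue + delay is exact in
    # floating point and reward - cue equals the configured delay bit-for-bit
    cues = np.round(cues * 2.0**20) / 2.0**20
    rewards = cues + config.cue_reward_delay_s
    duration = float(rewards[-1] + behavior.consummatory_delay_s
                     + behavior.consummatory_lick_s + config.session_padding_s)

    lick_bouts: list[tuple[float, float]] = []
    for c, r in zip(cues, rewards):
        a_on = c + behavior.lick_latency_s
        a_off = a_on + behavior.anticipatory_lick_s
        lick_bouts.append((a_on, a_off))
        c_on = max(r + behavior.consummatory_delay_s, a_off)
        lick_bouts.append((c_on, c_on + behavior.consummatory_lick_s))

    movement_bouts: list[tuple[float, float]] = []
    events = SessionEvents(cues, rewards, lick_bouts, movement_bouts, duration,
                           cue_duration_s=config.cue_duration_s)
    clear = behavior.movement_clear_reward_s
    for seg_on, seg_off in events.iti_segments(post_reward_excl_s=clear):
        seg_len = seg_off - seg_on
        n_bouts = rng.poisson(behavior.movement_rate_per_s * seg_len)
        onsets = np.sort(rng.uniform(seg_on, seg_off, size=n_bouts))
        last_off = -np.inf
        for on in onsets:
            off = min(on + behavior.movement_duration_s, seg_off)
            if on >= last_off and off > on:
                movement_bouts.append((float(on), float(off)))
                last_off = off
    events.validate()
    return events


# ---------------------------------------------------------------------------
# spike simulation
# ---------------------------------------------------------------------------

def _rate_trace(
    template: PopulationTemplate,
    events: SessionEvents,
    dt: float,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Piecewise-constant intensity (Hz) on a dt grid: tonic rate times the
    product of active event gains, with optional random pauses (rate 0)."""
    n = int(round(events.session_duration_s / dt))
    rate = np.full(n, template.tonic_rate_hz)

    def apply(windows: Sequence[tuple[float, float]], gain: float) -> None:
        if gain == 1.0:
            return
        for on, off in windows:
            i = max(int(round(on / dt)), 0)
            j = min(int(round(off / dt)), n)
            if j > i:
                rate[i:j] *= gain

    for kind, times in (("cue", events.cue_onsets_s), ("reward", events.reward_times_s)):
        mod = template.modulation(kind)
        dur = mod.duration_s if mod.duration_s is not None else 0.2
        apply([(t + mod.latency_s, t + mod.latency_s + dur) for t in times], mod.gain)
    for kind, bouts in (("lick", events.lick_bouts), ("movement", events.movement_bouts)):
        mod = template.modulation(kind)
        apply([(on + mod.latency_s, off + mod.latency_s) for on, off in bouts], mod.gain)

    if template.pause_rate_per_min > 0 and rng is not None:
        n_pauses = rng.poisson(template.pause_rate_per_min / 60.0 * events.session_duration_s)
        for on in rng.uniform(0, events.session_duration_s, size=n_pauses):
            apply([(on, on + template.pause_duration_s)], 0.0)
    np.maximum(rate, 0.0, out=rate)
    return rate


def simulate_spike_train(
    template: PopulationTemplate,
    events: SessionEvents,
    rng: np.random.Generator,
    unit_id: str = "u0",
    dt: float = 0.001,
    refractory_s: float | None = None,
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes by thinning a piecewise-constant
    intensity sampled at ``dt`` (1 ms) resolution."""
    rate = _rate_trace(template, events, dt, rng)
    duration = events.session_duration_s
    rmax = float(rate.max(initial=0.0))
    if rmax <= 0:
        return SpikeTrain(unit_id, np.empty(0))
    n_cand = rng.poisson(rmax * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n_cand))
    idx = np.minimum((t / dt).astype(int), rate.size - 1)
    keep = rng.uniform(size=n_cand) < rate[idx] / rmax
    times = np.unique(t[keep])
    if refractory_s:
        kept = []
        last = -np.inf
        for s in times:
            if s - last >= refractory_s:
                kept.append(s)
                last = s
        times = np.asarray(kept)
    train = SpikeTrain(unit_id, times)
    train.validate()
    return train


def _jitter_template(
    template: PopulationTemplate,
    rng: np.random.Generator,
    gain_jitter_sd: float,
    rate_jitter_sd: float,
) -> PopulationTemplate:
    """Per-unit variability: lognormal jitter on tonic rate and on every
    non-unit gain (unit gains stay exactly 1, preserving ground truth)."""
    kwargs: dict = {"tonic_rate_hz": template.tonic_rate_hz * math.exp(rng.normal(0, rate_jitter_sd))}
    for kind in EVENT_KINDS:
        mod = template.modulation(kind)
        if mod.gain != 1.0 and mod.gain > 0:
            kwargs[kind] = replace(mod, gain=mod.gain * math.exp(rng.normal(0, gain_jitter_sd)))
    return replace(template, **kwargs)


def build_population_session(
    population: str,
    n_neurons: int,
    config: TaskConfig,
    rng: np.random.Generator | None = None,
    behavior: BehaviorParams | None = None,
    template: PopulationTemplate | None = None,
    gain_jitter_sd: float = 0.08,
    rate_jitter_sd: float = 0.12,
) -> SyntheticSession:
    """One shared session with ``n_neurons`` units simulated from the
    population template (with per-unit jitter) plus ground-truth labels."""
    if population not in POPULATIONS:
        raise ConfigurationError(f"unknown population {population!r}")
    if n_neurons < 1:
        raise ConfigurationError("n_neurons must be >= 1")
    template = template or DEFAULT_TEMPLATES[population]
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    events = generate_session_events(config, behavior, rng)

    trains: list[SpikeTrain] = []
    truth: dict[str, UnitGroundTruth] = {}
    for i in range(n_neurons):
        unit_id = f"{population}_{i:03d}"
        unit_template = _jitter_template(template, rng, gain_jitter_sd, rate_jitter_sd)
        trains.append(simulate_spike_train(unit_template, events, rng, unit_id=unit_id))
        truth[unit_id] = UnitGroundTruth(
            population=population,
            encoded=unit_template.encoded_kinds(),
            dominant=unit_template.dominant_kind(),
        )
    return SyntheticSession(events, trains, truth, seed=config.seed)


# ---------------------------------------------------------------------------
# photometry simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotometryParams:
    """Two-channel photometry generator settings (130 Hz acquisition)."""

    fs_hz: float = 130.0
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.5
    signal_scale: float = 0.08
    baseline_level: float = 1.0
    reference_level: float = 1.0
    artifact_amplitude: float = 0.02
    artifact_cutoff_hz: float = 1.0
    gain_activity: float = 0.8
    gain_reference: float = 1.0
    noise_sd: float = 0.004
    bleach_amplitude: float = 0.0
    bleach_tau_s: float = 300.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class PhotometryRecording:
    activity: np.ndarray
    reference: np.ndarray
    fs_hz: float
    events: SessionEvents | None = None


@dataclass
class PhotometryGroundTruth:
    true_signal: np.ndarray
    artifact: np.ndarray
    gains: tuple[float, float]
    noise_sd: float


def _indicator_kernel(params: PhotometryParams) -> np.ndarray:
    dt = 1.0 / params.fs_hz
    t = np.arange(0.0, 5.0 * params.kernel_decay_s, dt)
    k = (1.0 - np.exp(-t / params.kernel_rise_s)) * np.exp(-t / params.kernel_decay_s)
    s = k.sum()
    return k / s if s > 0 else k


def simulate_photometry(
    events: SessionEvents,
    template: PopulationTemplate,
    params: PhotometryParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PhotometryRecording, PhotometryGroundTruth]:
    """Activity channel = indicator-convolved population rate + shared
    artifact + noise; reference channel = artifact + noise only."""
    params = params or PhotometryParams()
    rng = rng if rng is not None else np.random.default_rng()
    dt = 1.0 / params.fs_hz
    n = int(round(events.session_duration_s * params.fs_hz))

    rate = _rate_trace(template, events, dt, rng=None)[:n]
    if rate.size < n:
        rate = np.pad(rate, (0, n - rate.size), constant_values=template.tonic_rate_hz)
    rel = rate / template.tonic_rate_hz - 1.0 if template.tonic_rate_hz > 0 else rate * 0.0
    kernel = _indicator_kernel(params)
    true_signal = params.signal_scale * np.convolve(rel, kernel)[:n]

    if params.artifact_amplitude > 0:
        white = rng.standard_normal(n)
        sos = butter(2, params.artifact_cutoff_hz, "lowpass", fs=params.fs_hz, output="sos")
        artifact = sosfiltfilt(sos, white)
        sd = artifact.std()
        artifact = artifact / sd * params.artifact_amplitude if sd > 0 else artifact
    else:
        artifact = np.zeros(n)

    bleach = (params.bleach_amplitude
              * np.exp(-np.arange(n) * dt / params.bleach_tau_s)) if params.bleach_amplitude else 0.0
    activity = (params.baseline_level + bleach + true_signal
                + params.gain_activity * artifact + rng.normal(0, params.noise_sd, n))
    reference = (params.reference_level + bleach
                 + params.gain_reference * artifact + rng.normal(0, params.noise_sd, n))
    rec = PhotometryRecording(activity, reference, params.fs_hz, events=events)
    truth = PhotometryGroundTruth(true_signal, artifact,
                                  (params.gain_activity, params.gain_reference),
                                  params.noise_sd)
    return rec, truth
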