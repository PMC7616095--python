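"""Tonic firing statistics measured in the inter-trial interval.

Covers the local coefficient of variation of inter-spike intervals (CV2;
~0 for clock-like firing, ~1 for Poisson firing) and burst/pause detection
with a robust-Gaussian-surprise (RGS) outlier test on centered log ISIs:
the central location is the mean of the inter-quartile log-ISIs, the spread
a normalized median absolute deviation, and strings of significantly
short (bursts) or long (pauses) intervals are scored by the Gaussian tail
probability of their summed deviation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .task_synth import SessionEvents, SpikeTrain

__all__ = [
    "ISISequence",
    "Burst",
    "BurstSet",
    "FiringSummary",
    "compute_cv2",
    "detect_bursts_rgs",
    "detect_pauses_rgs",
    "iti_isis",
    "iti_firing_summary",
]


@dataclass
class ISISequence:
    """Order-preserving inter-spike intervals (seconds) of one unit."""

    isis: np.ndarray
    unit_id: str | None = None

    def __post_init__(self) -> None:
        self.isis = np.asarray(self.isis, float)
        if self.isis.size and np.any(self.isis <= 0):
            raise ValueError("all inter-spike intervals must be positive")


@dataclass(frozen=True)
class Burst:
    start_index: int      # index of the first ISI in the string
    n_spikes: int
    surprise: float       # -log10 tail probability of the string


@dataclass
class BurstSet:
    bursts: list[Burst]
    alpha: float
    kind: str = "burst"   # "burst" (short-ISI) or "pause" (long-ISI)

    def __len__(self) -> int:
        return len(self.bursts)

    def spike_count(self) -> int:
        return sum(b.n_spikes for b in self.bursts)


@dataclass
class FiringSummary:
    unit_id: str
    iti_rate_hz: float
    mean_cv2: float | None
    burst_fraction: float
    pause_count: int
    median_pause_duration_s: float


def compute_cv2(isis: ISISequence | np.ndarray) -> float:
    """Mean over adjacent ISI pairs of 2|I(n+1) - I(n)| / (I(n+1) + I(n))."""
    x = isis.isis if isinstance(isis, ISISequence) else np.asarray(isis, float)
    if x.size < 2:
        raise ValueError("CV2 needs at least two inter-spike intervals")
    num = 2.0 * np.abs(np.diff(x))
    den = x[1:] + x[:-1]
    return float(np.mean(num / den))


# ---------------------------------------------------------------------------
# robust Gaussian surprise
# ---------------------------------------------------------------------------

def _rgs_center_scale(log_isis: np.ndarray) -> tuple[float, float]:
    q25, q75 = np.percentile(log_isis, [25, 75])
    central = log_isis[(log_isis >= q25) & (log_isis <= q75)]
    center = float(central.mean()) if central.size else float(log_isis.mean())
    scale = float(1.4826 * np.median(np.abs(log_isis - center)))
    return center, scale


_MAX_STRETCH = 200   # bound on the substring search around one seed


def _detect_rgs(
    isis: ISISequence | np.ndarray,
    alpha: float,
    string_alpha: float,
    kind: str,
    min_isis: int,
) -> BurstSet:
    """Shared short/long-ISI string detector.

    ``alpha`` sets the per-interval candidate cutoff (quantile of the
    central normal); ``string_alpha`` is the stricter string-level
    significance a whole string must reach.  The gap between the two
    absorbs the left-skew of log ISIs relative to the fitted Gaussian and
    the implicit multiple comparisons over candidate strings, keeping the
    false-positive rate on Poisson trains below ``alpha``.
    """
    x_raw = isis.isis if isinstance(isis, ISISequence) else np.asarray(isis, float)
    if x_raw.size < 10:
        raise ValueError("RGS needs at least 10 inter-spike intervals")
    log_isis = np.log(x_raw)
    center, scale = _rgs_center_scale(log_isis)
    if scale <= 0:
        return BurstSet([], alpha, kind)  # degenerate (all-equal) train
    # orient so that "more extreme" is positive for both kinds
    y = (center - log_isis) if kind == "burst" else (log_isis - center)

    cutoff = scale * stats.norm.isf(alpha)
    candidates = np.flatnonzero(y > cutoff)
    order = candidates[np.argsort(-y[candidates])]     # most extreme first
    threshold = -np.log10(string_alpha)

    def surprise(i: int, j: int) -> float:
        z = y[i:j].sum() / (scale * np.sqrt(j - i))
        return float(-np.log10(max(stats.norm.sf(z), 1e-300)))

    taken = np.zeros(y.size, bool)
    found: list[Burst] = []
    for c in order:
        if taken[c]:
            continue
        c = int(c)
        # maximal stretch of same-direction deviations containing the seed
        i0 = c
        while i0 > 0 and c - i0 < _MAX_STRETCH and y[i0 - 1] > 0 and not taken[i0 - 1]:
            i0 -= 1
        j0 = c + 1
        while j0 < y.size and j0 - c < _MAX_STRETCH and y[j0] > 0 and not taken[j0]:
            j0 += 1
        # the substring containing the seed with maximal joint surprise
        best_s, best_i, best_j = -1.0, c, c + 1
        for i in range(i0, c + 1):
            for j in range(c + 1, j0 + 1):
                s = surprise(i, j)
                if s > best_s:
                    best_s, best_i, best_j = s, i, j
        if best_j - best_i >= min_isis and best_s >= threshold:
            found.append(Burst(start_index=best_i, n_spikes=best_j - best_i + 1,
                               surprise=best_s))
            taken[best_i:best_j] = True
    found.sort(key=lambda b: b.start_index)
    return BurstSet(found, alpha, kind)


def detect_bursts_rgs(
    isis: ISISequence | np.ndarray,
    alpha: float = 0.05,
    string_alpha: float = 0.001,
) -> BurstSet:
    """Strings of >= 2 significantly short ISIs (>= 3 spikes)."""
    return _detect_rgs(isis, alpha, string_alpha, "burst", min_isis=2)


def detect_pauses_rgs(
    isis: ISISequence | np.ndarray,
    alpha: float = 0.05,
    string_alpha: float = 0.05,
) -> BurstSet:
    """Strings of >= 1 significantly long ISI.

    The default string threshold equals ``alpha``: the upper tail of log
    ISIs is lighter than Gaussian for Poisson-like firing, so the string
    test is already conservative on that side (no skew margin needed).
    """
    return _detect_rgs(isis, alpha, string_alpha, "pause", min_isis=1)


# ---------------------------------------------------------------------------
# ITI-restricted summaries
# ---------------------------------------------------------------------------

def iti_isis(
    train: SpikeTrain,
    events: SessionEvents,
    post_reward_excl_s: float = 3.0,
    pre_cue_excl_s: float = 1.0,
) -> tuple[ISISequence, float, int]:
    """ISIs of spikes falling in ITIs "outside of engagement" (excluding
    3 s after reward and 1 s before the next cue).  Only interval pairs
    fully inside a single segment contribute.  Returns (isis, total ITI
    duration, ITI spike count)."""
    spikes = np.asarray(train.spike_times_s, float)
    segs = events.iti_segments(post_reward_excl_s, pre_cue_excl_s)
    if not segs:
        raise ValueError("no ITI time available")
    total = sum(b - a for a, b in segs)
    isis: list[np.ndarray] = []
    n_spikes = 0
    for a, b in segs:
        seg_spikes = spikes[(spikes >= a) & (spikes < b)]
        n_spikes += seg_spikes.size
        if seg_spikes.size >= 2:
            isis.append(np.diff(seg_spikes))
    joined = np.concatenate(isis) if isis else np.empty(0)
    return ISISequence(joined, unit_id=train.unit_id), float(total), n_spikes


def iti_firing_summary(
    train: SpikeTrain,
    events: SessionEvents,
    alpha: float = 0.05,
    post_reward_excl_s: float = 3.0,
    pre_cue_excl_s: float = 1.0,
) -> FiringSummary:
    """Tonic firing summary on ITI spikes only: rate, CV2, burst spike
    fraction, pause count and median pause duration."""
    seq, total, n_spikes = iti_isis(train, events, post_reward_excl_s, pre_cue_excl_s)
    rate = n_spikes / total
    cv2 = compute_cv2(seq) if seq.isis.size >= 2 else None
    if seq.isis.size >= 10:
        bursts = detect_bursts_rgs(seq, alpha)
        pauses = detect_pauses_rgs(seq, alpha)
        burst_fraction = bursts.spike_count() / max(n_spikes, 1)
        pause_durs = [float(seq.isis[b.start_index:b.start_index + b.n_spikes - 1].sum())
                      for b in pauses.bursts]
        pause_count = len(pauses)
        median_pause = float(np.median(pause_durs)) if pause_durs else 0.0
    else:
        burst_fraction, pause_count, median_pause = 0.0, 0, 0.0
    return FiringSummary(
        unit_id=train.unit_id,
        iti_rate_hz=float(rate),
        mean_cv2=cv2,
        burst_fraction=float(burst_fraction),
        pause_count=pause_count,
        median_pause_duration_s=median_pause,
    )
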