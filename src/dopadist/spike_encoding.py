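"""PSTH construction and Poisson-GLM encoding analysis of spike trains.

The encoding model regresses 200-ms spike counts (bins aligned to cue onset
within each trial, tiling the whole session including ITIs) on four binary
regressors — cue, reward, licking, movement — with a log link.  Bins within
0-400 ms of cue/reward onset are coded positive for that event; bins are
lick/movement positive when they overlap a bout by at least 75% of the bin.
A unit is called responsive to a parameter when its Wald p-value is < 0.05;
the dominant parameter is the significant coefficient of largest magnitude.

PSTHs use 40-ms bins over a -1 to +4 s cue-aligned window, z-scored against
the pooled 1-s pre-cue baseline and smoothed with a unit-sum 5-tap Gaussian
kernel (FWHM 70 ms).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .task_synth import SessionEvents, SpikeTrain

__all__ = [
    "PSTH",
    "DesignMatrix",
    "EncodingFit",
    "EncodingClassification",
    "gaussian_kernel_5tap",
    "compute_psth",
    "build_design_matrix",
    "fit_poisson_encoding_glm",
    "classify_encoding",
    "event_window_rate",
]

REGRESSORS = ("cue", "reward", "lick", "movement")


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def gaussian_kernel_5tap(fwhm_s: float = 0.070, bin_s: float = 0.040) -> np.ndarray:
    """5-tap Gaussian smoothing kernel, renormalized to unit sum.

    FWHM 70 ms at 40-ms bins gives sigma ~ 0.74 bins.
    """
    sigma_bins = fwhm_s / (2.0 * np.sqrt(2.0 * np.log(2.0))) / bin_s
    k = np.exp(-0.5 * (np.arange(-2, 3) / sigma_bins) ** 2)
    return k / k.sum()


def _smooth(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve preserving constants at the edges (renormalized taps)."""
    norm = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return np.convolve(x, kernel, mode="same") / norm


@dataclass
class PSTH:
    bin_edges_s: np.ndarray          # event-aligned, length n_bins + 1
    z_trials: np.ndarray | None      # trials x bins, unsmoothed z
    mean_z: np.ndarray | None        # smoothed across-trial mean z
    rate_trials: np.ndarray          # trials x bins, raw rates (Hz)
    baseline_mean_hz: float
    baseline_sd_hz: float
    kernel: np.ndarray
    silent: bool = False             # zero baseline SD; excluded from z-scoring


def compute_psth(
    train: SpikeTrain,
    events: SessionEvents,
    window: tuple[float, float] = (-1.0, 4.0),
    bin_s: float = 0.040,
    baseline_s: float = 1.0,
) -> PSTH:
    """Cue-aligned PSTH z-scored by the pooled 1-s pre-cue baseline."""
    cues = np.asarray(events.cue_onsets_s, float)
    if cues.size < 1:
        raise ValueError("need at least one trial")
    n_bins = int(round((window[1] - window[0]) / bin_s))
    edges = window[0] + bin_s * np.arange(n_bins + 1)
    spikes = np.asarray(train.spike_times_s, float)
    rates = np.empty((cues.size, n_bins))
    for i, c in enumerate(cues):
        counts, _ = np.histogram(spikes - c, bins=edges)
        rates[i] = counts / bin_s

    centers = edges[:-1] + bin_s / 2.0
    baseline_cols = (centers >= -baseline_s) & (centers < 0.0)
    base = rates[:, baseline_cols]
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    kernel = gaussian_kernel_5tap(bin_s=bin_s)
    if sd == 0.0:
        return PSTH(edges, None, None, rates, mu, sd, kernel, silent=True)
    z = (rates - mu) / sd
    mean_z = _smooth(z.mean(axis=0), kernel)
    return PSTH(edges, z, mean_z, rates, mu, sd, kernel)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    bin_starts_s: np.ndarray
    counts: np.ndarray
    regressors: dict[str, np.ndarray]
    bin_s: float = 0.2

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.regressors[k] for k in REGRESSORS])


def _overlap_fraction(starts: np.ndarray, bin_s: float,
                      bouts: list[tuple[float, float]]) -> np.ndarray:
    """Per-bin overlap with the union of bouts, as a fraction of bin_s."""
    total = np.zeros(starts.size)
    ends = starts + bin_s
    for on, off in bouts:
        total += np.clip(np.minimum(ends, off) - np.maximum(starts, on), 0.0, None)
    return np.minimum(total, bin_s) / bin_s


def build_design_matrix(
    train: SpikeTrain,
    events: SessionEvents,
    bin_s: float = 0.2,
    event_window_s: float = 0.4,
    overlap_threshold: float = 0.75,
    pre_cue_s: float = 1.0,
) -> DesignMatrix:
    """200-ms count bins tiling the session, re-aligned to each cue onset.

    Each trial's bins run from 1 s before its cue to the next trial's start
    (the session end for the last trial); a trailing partial bin is dropped.
    """
    events.validate()
    cues = np.asarray(events.cue_onsets_s, float)
    rewards = np.asarray(events.reward_times_s, float)
    for bouts in (events.lick_bouts, events.movement_bouts):
        for on, off in bouts:
            if on < 0 or off > events.session_duration_s:
                raise ValueError("bout outside session bounds")

    starts_list = []
    for k, c in enumerate(cues):
        t0 = c - pre_cue_s
        t1 = (cues[k + 1] - pre_cue_s) if k + 1 < cues.size else events.session_duration_s
        n_bins = int(np.floor((t1 - t0) / bin_s + 1e-9))
        starts_list.append(t0 + bin_s * np.arange(n_bins))
    starts = np.concatenate(starts_list)

    spikes = np.asarray(train.spike_times_s, float)
    # bins are contiguous within a trial; count per bin by searchsorted
    counts = (np.searchsorted(spikes, starts + bin_s) - np.searchsorted(spikes, starts))

    def point_regressor(times: np.ndarray) -> np.ndarray:
        col = np.zeros(starts.size, bool)
        for t in times:
            col |= (starts >= t - 1e-9) & (starts < t + event_window_s - 1e-9)
        return col.astype(float)

    regressors = {
        "cue": point_regressor(cues),
        "reward": point_regressor(rewards),
        "lick": (_overlap_fraction(starts, bin_s, events.lick_bouts)
                 >= overlap_threshold - 1e-9).astype(float),
        "movement": (_overlap_fraction(starts, bin_s, events.movement_bouts)
                     >= overlap_threshold - 1e-9).astype(float),
    }
    return DesignMatrix(starts, counts.astype(int), regressors, bin_s)


# ---------------------------------------------------------------------------
# Poisson GLM
# ---------------------------------------------------------------------------

@dataclass
class EncodingFit:
    intercept: float
    coef: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    deviance: float
    df_resid: int
    gof_p: float
    converged: bool = True


def fit_poisson_encoding_glm(design: DesignMatrix) -> EncodingFit:
    """Maximum-likelihood Poisson regression (log link) of counts on the
    four binary regressors plus an intercept; Wald p-values per coefficient
    and a chi-square deviance goodness-of-fit p."""
    y = np.asarray(design.counts, float)
    if not np.any(y > 0):
        raise ValueError("all-zero spike counts: nothing to fit")
    X = sm.add_constant(design.matrix(), has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit()
    converged = bool(getattr(res, "converged", True)) and np.all(np.isfinite(res.params))
    names = ("const",) + REGRESSORS
    params = dict(zip(names, res.params))
    bse = dict(zip(names, res.bse))
    pvals = dict(zip(names, res.pvalues))
    df_resid = int(res.df_resid)
    gof_p = float(stats.chi2.sf(res.deviance, df_resid)) if df_resid > 0 else 1.0
    return EncodingFit(
        intercept=float(params["const"]),
        coef={k: float(params[k]) for k in REGRESSORS},
        bse={k: float(bse[k]) for k in REGRESSORS},
        pvalues={k: float(pvals[k]) for k in REGRESSORS},
        deviance=float(res.deviance),
        df_resid=df_resid,
        gof_p=gof_p,
        converged=converged,
    )


@dataclass
class EncodingClassification:
    significant: frozenset[str]
    dominant: str
    multiplexing_count: int


def classify_encoding(fit: EncodingFit, alpha: float = 0.05) -> EncodingClassification:
    """Significant set at p < alpha; dominant = largest |coefficient|."""
    if not fit.converged:
        raise ValueError("cannot classify a non-converged fit")
    significant = frozenset(k for k in REGRESSORS if fit.pvalues[k] < alpha)
    if significant:
        dominant = max(significant, key=lambda k: abs(fit.coef[k]))
    else:
        dominant = "none"
    return EncodingClassification(significant, dominant, len(significant))


# ---------------------------------------------------------------------------
# event-window firing and shuffled baseline
# ---------------------------------------------------------------------------

def event_window_rate(
    train: SpikeTrain,
    events: SessionEvents,
    align: str = "reward",
    window: tuple[float, float] = (0.04, 0.24),
    shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    post_reward_excl_s: float = 1.0,
) -> tuple[float, float]:
    """Mean firing rate in an event-locked window and a two-sided percentile
    p against equal-length windows placed at random ITI times (excluding the
    first second after reward)."""
    if shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    rng = rng if rng is not None else np.random.default_rng()
    anchors = np.asarray(events.reward_times_s if align == "reward"
                         else events.cue_onsets_s, float)
    spikes = np.asarray(train.spike_times_s, float)
    w_len = window[1] - window[0]

    def mean_rate(starts: np.ndarray) -> float:
        counts = np.searchsorted(spikes, starts + w_len) - np.searchsorted(spikes, starts)
        return float(counts.mean() / w_len)

    obs = mean_rate(anchors + window[0])

    segs = [(a, b - w_len) for a, b in
            events.iti_segments(post_reward_excl_s=post_reward_excl_s)
            if b - a > w_len]
    if not segs:
        raise ValueError("shuffle window longer than every ITI")
    seg_arr = np.asarray(segs)
    lens = seg_arr[:, 1] - seg_arr[:, 0]
    probs = lens / lens.sum()
    null = np.empty(shuffles)
    n_tr = anchors.size
    for s in range(shuffles):
        which = rng.choice(seg_arr.shape[0], size=n_tr, p=probs)
        starts = rng.uniform(seg_arr[which, 0], seg_arr[which, 1])
        null[s] = mean_rate(starts)
    lo = (np.sum(null <= obs) + 1) / (shuffles + 1)
    hi = (np.sum(null >= obs) + 1) / (shuffles + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    return obs, float(p)
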