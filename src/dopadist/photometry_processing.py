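"""Fiber-photometry processing chain for two-channel recordings.

Order of operations: 5-sample median filter -> zero-phase second-order
Butterworth low-pass (20 Hz) -> zero-phase second-order high-pass
(0.001 Hz, photobleaching correction) -> motion correction by subtracting
the best linear fit of the reference (tdTomato) channel from the activity
(GCaMP) channel -> dF/F against a 0.001 Hz low-pass baseline -> per-trial
sweep extraction normalized to the second before the cue.

All filters are applied forward-backward (zero phase) so event latencies
are preserved; the high-pass removes the DC level, so the dF/F baseline is
computed after restoring the pre-high-pass mean offset (keeping it strictly
positive).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, medfilt, sosfiltfilt

from .task_synth import PhotometryRecording, SessionEvents

__all__ = [
    "ProcessedTrace",
    "TrialSweeps",
    "condition_channel",
    "motion_correct",
    "compute_dff",
    "extract_sweeps",
    "peak_reward_response",
    "process_recording",
]


@dataclass
class ProcessedTrace:
    corrected: np.ndarray
    baseline: np.ndarray
    dff: np.ndarray


@dataclass
class TrialSweeps:
    sweeps: np.ndarray               # trials x samples
    window_s: tuple[float, float]
    fs_hz: float
    kept_trials: np.ndarray          # indices of trials inside trace bounds


def _sos(cutoff_hz: float, fs: float, btype: str, order: int = 2) -> np.ndarray:
    return butter(order, cutoff_hz, btype=btype, fs=fs, output="sos")


def condition_channel(
    trace: np.ndarray,
    fs_hz: float,
    lowpass_hz: float = 20.0,
    highpass_hz: float = 0.001,
    return_offset: bool = False,
):
    """Median (5-point), 20 Hz low-pass, then 0.001 Hz high-pass, all
    zero-phase.  ``return_offset`` also yields the mean removed by the
    high-pass stage (needed to build a positive dF/F baseline later)."""
    x = np.asarray(trace, float)
    if np.any(~np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if x.size < 30:
        raise ValueError("trace shorter than filter warm-up")
    y = medfilt(x, kernel_size=5)
    y = sosfiltfilt(_sos(lowpass_hz, fs_hz, "lowpass"), y)
    offset = float(y.mean())
    y = sosfiltfilt(_sos(highpass_hz, fs_hz, "highpass"), y)
    return (y, offset) if return_offset else y


def motion_correct(activity: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Subtract the ordinary-least-squares fit (slope + intercept) of the
    reference channel from the activity channel.  A constant reference
    degenerates to mean-centering."""
    a = np.asarray(activity, float)
    r = np.asarray(reference, float)
    if a.shape != r.shape:
        raise ValueError("activity and reference must have equal length")
    if np.ptp(r) == 0:
        return a - a.mean()
    X = np.column_stack([np.ones_like(r), r])
    beta, *_ = np.linalg.lstsq(X, a, rcond=None)
    return a - X @ beta


def compute_dff(
    corrected: np.ndarray,
    fs_hz: float,
    offset: float,
    baseline_hz: float = 0.001,
) -> ProcessedTrace:
    """dF/F = corrected / baseline, where the baseline is the 0.001 Hz
    low-pass of the corrected signal with its pre-high-pass mean restored."""
    x = np.asarray(corrected, float)
    baseline = sosfiltfilt(_sos(baseline_hz, fs_hz, "lowpass"), x + offset)
    bad = np.flatnonzero(baseline <= 0)
    if bad.size:
        raise ValueError(f"non-positive dF/F baseline (first at sample {bad[0]})")
    return ProcessedTrace(corrected=x, baseline=baseline, dff=x / baseline)


def extract_sweeps(
    dff: np.ndarray,
    events: SessionEvents,
    fs_hz: float,
    window_s: tuple[float, float] = (-1.0, 4.0),
    norm_s: float = 1.0,
) -> TrialSweeps:
    """Cue-aligned trial sweeps on a common sample grid, each normalized by
    subtracting its mean over the second preceding the cue.  Trials whose
    window leaves the trace are dropped with a warning-free mask."""
    x = np.asarray(dff, float)
    n_samp = int(round((window_s[1] - window_s[0]) * fs_hz))
    offsets = np.arange(n_samp)
    rows, kept = [], []
    for k, c in enumerate(np.asarray(events.cue_onsets_s, float)):
        start = int(round((c + window_s[0]) * fs_hz))
        if start < 0 or start + n_samp > x.size:
            continue
        sweep = x[start + offsets].astype(float)
        pre = sweep[: int(round(norm_s * fs_hz))]
        rows.append(sweep - pre.mean())
        kept.append(k)
    if not rows:
        raise ValueError("no trial window fits inside the trace")
    return TrialSweeps(np.vstack(rows), window_s, fs_hz, np.asarray(kept, int))


def peak_reward_response(
    sweeps: TrialSweeps,
    reward_delay_s: float = 2.0,
    peak_window_s: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Mean over trials of the per-trial peak dF/F in a post-reward window
    (default 0-1 s after reward delivery)."""
    t0 = reward_delay_s + peak_window_s[0] - sweeps.window_s[0]
    t1 = reward_delay_s + peak_window_s[1] - sweeps.window_s[0]
    i0 = int(round(t0 * sweeps.fs_hz))
    i1 = int(round(t1 * sweeps.fs_hz))
    if i1 <= i0 or i1 > sweeps.sweeps.shape[1]:
        raise ValueError("empty or out-of-range peak window")
    return float(sweeps.sweeps[:, i0:i1].max(axis=1).mean())


def process_recording(
    rec: PhotometryRecording,
    window_s: tuple[float, float] = (-1.0, 4.0),
    reward_delay_s: float = 2.0,
) -> tuple[ProcessedTrace, TrialSweeps, float]:
    """Full chain on one recording; returns the processed trace, the
    normalized sweeps, and the mean peak reward response."""
    act, offset = condition_channel(rec.activity, rec.fs_hz, return_offset=True)
    ref = condition_channel(rec.reference, rec.fs_hz)
    corrected = motion_correct(act, ref)
    processed = compute_dff(corrected, rec.fs_hz, offset)
    if rec.events is None:
        raise ValueError("recording carries no event times")
    sweeps = extract_sweeps(processed.dff, rec.events, rec.fs_hz, window_s)
    peak = peak_reward_response(sweeps, reward_delay_s)
    return processed, sweeps, peak
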