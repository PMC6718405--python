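"""Turn raw epochs and pupil traces into per-trial pre-stimulus features.

The recording-side pipeline mirrors standard practice for slow pre-stimulus
activity: a per-block linear detrend of each sensor (no frequency-domain
filtering anywhere, to rule out post-stimulus leakage into the pre-stimulus
window), then a plain arithmetic mean over the 2-s window before stimulus
onset, yielding one brain-state vector per trial.  The pupil side detects
blinks as threshold crossings of the diameter drop relative to a running
baseline, pads and merges them, excludes them from the 2-s pre-stimulus
pupil mean, and can reject trials whose stimulus presentation overlaps a
blink.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EpochSet, PupilTrace

__all__ = [
    "detrend_blocks",
    "average_prestim",
    "detect_blinks",
    "average_pupil_prestim",
    "reject_blink_trials",
]


def detrend_blocks(epochs: EpochSet) -> EpochSet:
    """Remove the per-block, per-sensor linear trend (with intercept).

    For every block, the samples of all its trials are placed on the
    session timeline (using the stored onset times) and an ordinary
    least-squares line is fit per sensor over the block's concatenated
    samples, then subtracted.  A block contributing a single time sample
    has no defined slope and raises ``ValueError``.
    """
    out = epochs.copy()
    n, _, n_samples = out.values.shape
    rel = np.arange(n_samples) / out.sampling_rate
    if out.onsets is not None:
        onsets = out.onsets
    else:
        onsets = (np.arange(n) + 1.0) * out.window
    for b in np.unique(out.block):
        sel = np.flatnonzero(out.block == b)
        t = (onsets[sel, None] - out.window + rel[None, :]).ravel()
        if t.size < 2 or np.ptp(t) == 0.0:
            raise ValueError(f"block {b} has fewer than two distinct samples; slope undefined")
        t0 = t - t.mean()
        denom = np.dot(t0, t0)
        # flatten (trial, time) per sensor: (len(sel)*n_samples, n_sensors)
        y = out.values[sel].transpose(0, 2, 1).reshape(t.size, -1)
        slope = t0 @ y / denom
        intercept = y.mean(axis=0)
        y -= np.outer(t0, slope) + intercept
        out.values[sel] = y.reshape(len(sel), n_samples, -1).transpose(0, 2, 1)
    return out


def average_prestim(epochs: EpochSet, window: float | None = None) -> np.ndarray:
    """Collapse epochs to a (trials x sensors) brain-state matrix.

    Each entry is the arithmetic mean over the last ``window`` seconds of
    the epoch, i.e. the half-open interval ``[onset - window, onset)``.
    ``window`` defaults to the full epoch span and may not exceed it.
    """
    if window is None:
        window = epochs.window
    if window > epochs.window + 1e-12:
        raise ValueError(
            f"averaging window {window} s exceeds epoch span {epochs.window} s"
        )
    n_avg = int(round(window * epochs.sampling_rate))
    if n_avg < 1:
        raise ValueError("averaging window shorter than one sample")
    return epochs.values[:, :, -n_avg:].mean(axis=2)


def detect_blinks(pupil: PupilTrace, drop_threshold: float = 3.6,
                  pad: float = 0.040, baseline_window: float = 0.100) -> np.ndarray:
    """Detect blinks as drops of the pupil diameter below a running baseline.

    A sample is blink-affected when the diameter lies at least
    ``drop_threshold`` measurement units below the median of the preceding
    ``baseline_window`` seconds (the baseline is held fixed across
    consecutive affected samples so long blinks do not swallow their own
    reference).  Each contiguous run is padded by ``pad`` seconds on both
    sides and overlapping intervals are merged.

    Returns an ``(n_blinks, 2)`` array of (onset, offset) times in seconds.
    """
    x = pupil.diameter
    if x.size == 0:
        raise ValueError("empty pupil trace")
    fs = pupil.sampling_rate
    k = max(int(round(baseline_window * fs)), 1)
    # running baseline: median of the preceding k samples (edge-padded)
    padded = np.concatenate((np.full(k, x[0]), x))
    windows = np.lib.stride_tricks.sliding_window_view(padded, k)[: x.size]
    baseline = np.median(windows, axis=1)
    below = (baseline - x) >= drop_threshold
    # hold the pre-blink baseline fixed while inside a blink, so long blinks
    # do not swallow their own reference
    starts = np.flatnonzero(below & ~np.roll(below, 1))
    if below.any() and below[0]:
        starts = np.union1d(starts, [0])
    for s in starts:
        ref = baseline[s]
        i = s
        while i < x.size and ref - x[i] >= drop_threshold:
            below[i] = True
            i += 1
    if not below.any():
        return np.empty((0, 2))

    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    starts, stops = edges[0::2], edges[1::2] - 1
    t = pupil.time
    intervals = np.column_stack((t[starts] - pad, t[stops] + pad))
    merged = [intervals[0]]
    for onset, offset in intervals[1:]:
        if onset <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], offset)
        else:
            merged.append([onset, offset])
    return np.asarray(merged)


def _blink_mask(pupil: PupilTrace, blinks: np.ndarray) -> np.ndarray:
    mask = np.zeros(pupil.diameter.size, dtype=bool)
    t = pupil.time
    for onset, offset in np.atleast_2d(blinks) if len(blinks) else []:
        mask |= (t >= onset) & (t <= offset)
    return mask


def average_pupil_prestim(pupil: PupilTrace, blinks: np.ndarray,
                          window: float = 2.0) -> np.ndarray:
    """Per-trial mean pupil diameter over the pre-stimulus window.

    Samples inside blink intervals are excluded; a trial whose window is
    entirely blink-affected gets ``NaN`` (missingness propagates instead of
    raising).
    """
    mask = _blink_mask(pupil, blinks)
    t = pupil.time
    out = np.full(pupil.n_trials, np.nan)
    for i, onset in enumerate(pupil.onsets):
        sel = (t >= onset - window) & (t < onset) & ~mask
        if sel.any():
            out[i] = pupil.diameter[sel].mean()
    return out


def reject_blink_trials(trials: pd.DataFrame, blinks: np.ndarray,
                        stimulus_duration: float) -> tuple[pd.DataFrame, int]:
    """Drop trials whose stimulus presentation overlaps a blink.

    Only the interval ``[onset, onset + stimulus_duration]`` counts; blinks
    confined to the pre-stimulus period leave the trial in place.  Returns
    the filtered table and the number of rejected trials.
    """
    onsets = trials["prestim_onset"].to_numpy()
    keep = np.ones(len(trials), dtype=bool)
    for onset, offset in np.atleast_2d(blinks) if len(blinks) else []:
        keep &= (onsets + stimulus_duration < onset) | (onsets > offset)
    return trials.loc[keep].copy(), int((~keep).sum())
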